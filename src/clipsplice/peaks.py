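"""Randomization-FDR peak calling on cross-link reads within gene regions.

The false-discovery estimate at coverage height ``h`` is the mean, over
``n_iter`` uniform re-placements of the observed reads inside the gene span,
of the number of positions reaching random coverage ``>= h`` divided by the
number of positions reaching observed coverage ``>= h``.  Peaks are maximal
runs of positions at or above the smallest height whose (monotonized) FDR
falls below ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

_MAX_CELLS = 20_000_000  # chunk randomizations above this many matrix cells


@dataclass
class Peak:
    chrom: str
    strand: str
    start: int
    end: int
    summit: int
    height: int
    fdr: float
    gene_id: Optional[str] = None
    support: tuple[int, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if not self.start <= self.summit < self.end:
            raise ValueError("summit outside peak interval")


def trim_reads(reads: pd.DataFrame, L: int = 10) -> pd.DataFrame:
    """Clip each read's 3' end so length = min(original, L); 5' end unchanged."""
    if L < 1:
        raise ValueError("trim length must be >= 1")
    out = reads.copy()
    plus = out["strand"] == "+"
    out.loc[plus, "end"] = np.minimum(out.loc[plus, "end"], out.loc[plus, "start"] + L)
    out.loc[~plus, "start"] = np.maximum(out.loc[~plus, "start"], out.loc[~plus, "end"] - L)
    return out


def extend_reads(reads: pd.DataFrame, L: int = 10, mode: str = "center") -> pd.DataFrame:
    """Extend 1-nt cross-link points to L-nt reads.

    ``center`` places the point mid-read (summits then coincide with the
    cross-link pile); ``downstream`` extends 3' of the point.
    """
    out = reads.copy()
    if mode == "center":
        mid = (out["start"] + out["end"]) // 2
        out["start"] = np.maximum(mid - L // 2, 0)
        out["end"] = out["start"] + L
    elif mode == "downstream":
        plus = out["strand"] == "+"
        out.loc[plus, "end"] = out.loc[plus, "start"] + L
        out.loc[~plus, "start"] = np.maximum(out.loc[~plus, "end"] - L, 0)
    else:
        raise ValueError(f"unknown extension mode {mode!r}")
    return out


def remove_masked(reads: pd.DataFrame, mask: pd.DataFrame) -> pd.DataFrame:
    """Drop reads overlapping any mask interval by >= 1 nt (strand-agnostic)."""
    if mask is None or len(mask) == 0:
        return reads
    keep = np.ones(len(reads), dtype=bool)
    for chrom, m in mask.groupby("chrom"):
        sel = (reads["chrom"] == chrom).to_numpy()
        if not sel.any():
            continue
        ms = m.sort_values("start")
        mstart = ms["start"].to_numpy()
        mend_cum = np.maximum.accumulate(ms["end"].to_numpy())
        rs = reads.loc[sel, "start"].to_numpy()
        re_ = reads.loc[sel, "end"].to_numpy()
        # last mask interval starting before read end; overlap iff its running
        # max end exceeds read start
        idx = np.searchsorted(mstart, re_, side="left") - 1
        hit = (idx >= 0) & (mend_cum[np.clip(idx, 0, None)] > rs)
        keep[np.flatnonzero(sel)[hit]] = False
    return reads.loc[keep].reset_index(drop=True)


def coverage_profile(
    starts: np.ndarray, ends: np.ndarray, span: tuple[int, int]
) -> np.ndarray:
    """Read coverage over ``span`` (reads clipped to the span)."""
    a, b = span
    cov = np.zeros(b - a, dtype=np.int64)
    s = np.clip(starts - a, 0, b - a)
    e = np.clip(ends - a, 0, b - a)
    np.add.at(cov, s[s < e], 1)
    delta = np.zeros(b - a + 1, dtype=np.int64)
    np.add.at(delta, s[s < e], 1)
    np.add.at(delta, e[s < e], -1)
    return delta[:-1].cumsum()


def _random_exceedance(
    span_len: int,
    read_lengths: np.ndarray,
    hmax: int,
    n_iter: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """For each h in 0..hmax, mean number of positions with random coverage >= h."""
    lens = np.asarray(read_lengths, dtype=np.int64)
    lens = np.minimum(lens, span_len)
    n_reads = len(lens)
    off = np.concatenate([np.arange(l) for l in lens]) if n_reads else np.empty(0, int)
    ridx = np.repeat(np.arange(n_reads), lens)
    high = (span_len - lens + 1).astype(np.float64)
    total = np.zeros(hmax + 1, dtype=np.float64)
    cells = max(len(off), span_len, 1)
    chunk = max(1, int(_MAX_CELLS // cells))
    done = 0
    while done < n_iter:
        m = min(chunk, n_iter - done)
        starts = np.floor(rng.random((m, n_reads)) * high).astype(np.int64)
        pos = starts[:, ridx] + off
        it = np.repeat(np.arange(m), pos.shape[1])
        cov = np.bincount(
            it * span_len + pos.ravel(), minlength=m * span_len
        ).reshape(m, span_len)
        covc = np.minimum(cov, hmax)
        hist = np.bincount(
            (np.arange(m)[:, None] * (hmax + 1) + covc).ravel(),
            minlength=m * (hmax + 1),
        ).reshape(m, hmax + 1)
        total += hist[:, ::-1].cumsum(axis=1)[:, ::-1].sum(axis=0)
        done += m
    return total / n_iter


def randomization_fdr(
    obs_cov: np.ndarray,
    read_lengths: Sequence[int],
    n_iter: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw and monotonized FDR per height 1..max(obs_cov).

    Returns ``(raw, adjusted)`` arrays of length ``max(obs_cov)``; index i is
    height i+1.  ``adjusted`` is non-increasing in height (running max taken
    downward from the top height), values capped at 1 only when assigned to
    peaks, not here.
    """
    rng = rng or np.random.default_rng()
    hmax = int(obs_cov.max())
    if hmax == 0:
        return np.empty(0), np.empty(0)
    obs_exceed = np.array([(obs_cov >= h).sum() for h in range(1, hmax + 1)])
    rand_exceed = _random_exceedance(len(obs_cov), np.asarray(read_lengths), hmax, n_iter, rng)
    raw = rand_exceed[1:] / np.maximum(1, obs_exceed)
    adj = raw.copy()
    for i in range(len(adj) - 2, -1, -1):
        adj[i] = max(adj[i], adj[i + 1])
    return raw, adj


def call_peaks_gene(
    reads: pd.DataFrame,
    gene_span: tuple[int, int],
    *,
    chrom: str,
    strand: str,
    alpha: float = 0.01,
    n_iter: int = 100,
    seed: int = 0,
    gene_id: Optional[str] = None,
) -> list[Peak]:
    """Call peaks on one gene's reads (already trimmed/extended and filtered).

    A gene with zero reads returns an empty list.  Deterministic under seed.
    """
    if len(reads) == 0:
        return []
    a, b = gene_span
    starts = reads["start"].to_numpy()
    ends = reads["end"].to_numpy()
    cov = coverage_profile(starts, ends, gene_span)
    rng = np.random.default_rng(seed)
    lengths = np.minimum(ends, b) - np.maximum(starts, a)
    lengths = lengths[lengths > 0]
    if len(lengths) == 0:
        return []
    _, adj = randomization_fdr(cov, lengths, n_iter=n_iter, rng=rng)
    sig = np.flatnonzero(adj < alpha)
    if len(sig) == 0:
        return []
    h_star = int(sig[0]) + 1
    peaks = []
    above = cov >= h_star
    edges = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    for s, e in zip(edges[::2], edges[1::2]):
        run = cov[s:e]
        summit = int(s + np.argmax(run))
        height = int(run.max())
        peaks.append(
            Peak(
                chrom=chrom,
                strand=strand,
                start=int(a + s),
                end=int(a + e),
                summit=int(a + summit),
                height=height,
                fdr=float(min(1.0, adj[height - 1])),
                gene_id=gene_id,
            )
        )
    return peaks


def subtract_control(peaks: Sequence[Peak], control_peaks: Sequence[Peak]) -> list[Peak]:
    """Remove peaks overlapping any same-strand control peak by >= 1 nt."""
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for c in control_peaks:
        by_key.setdefault((c.chrom, c.strand), []).append((c.start, c.end))
    for v in by_key.values():
        v.sort()
    out = []
    for p in peaks:
        ivs = by_key.get((p.chrom, p.strand), [])
        hit = any(s < p.end and e > p.start for s, e in ivs)
        if not hit:
            out.append(p)
    return out


def _supported_regions(
    peak_sets: Sequence[Sequence[Peak]], k: int
) -> list[tuple[str, str, int, int, tuple[int, ...]]]:
    """Merged regions covered by peaks from >= k distinct sets."""
    by_key: dict[tuple[str, str], list[tuple[int, int, int]]] = {}
    for si, pset in enumerate(peak_sets):
        merged: dict[tuple[str, str], list[list[int]]] = {}
        for p in sorted(pset, key=lambda p: (p.chrom, p.strand, p.start)):
            ivs = merged.setdefault((p.chrom, p.strand), [])
            if ivs and p.start <= ivs[-1][1]:
                ivs[-1][1] = max(ivs[-1][1], p.end)
            else:
                ivs.append([p.start, p.end])
        for key, ivs in merged.items():
            by_key.setdefault(key, []).extend((s, e, si) for s, e in ivs)
    regions = []
    for (chrom, strand), ivs in sorted(by_key.items()):
        events = []
        for s, e, si in ivs:
            events.append((s, 1, si))
            events.append((e, -1, si))
        events.sort()
        depth, seeds, cur = 0, [], None
        for pos, d, _ in events:
            depth += d
            if depth >= k and cur is None:
                cur = pos
            elif depth < k and cur is not None:
                seeds.append((cur, pos))
                cur = None
        # grow each seed to the union of contributing peaks, then re-merge
        grown = []
        for s, e in seeds:
            gs, ge, sets = s, e, set()
            for ps, pe, si in ivs:
                if ps < e and pe > s:
                    gs, ge = min(gs, ps), max(ge, pe)
                    sets.add(si)
            grown.append([gs, ge, sets])
        grown.sort()
        fused: list[list] = []
        for g in grown:
            if fused and g[0] <= fused[-1][1]:
                fused[-1][1] = max(fused[-1][1], g[1])
                fused[-1][2] |= g[2]
            else:
                fused.append(g)
        for gs, ge, sets in fused:
            regions.append((chrom, strand, gs, ge, tuple(sorted(sets))))
    return regions


def consensus_peaks(
    peak_sets: Sequence[Sequence[Peak]],
    all_reads: pd.DataFrame,
    k: int = 2,
    alpha: float = 0.01,
    n_iter: int = 100,
    seed: int = 0,
    gene_spans: Optional[Mapping[tuple[str, str], Sequence[tuple[int, int, str]]]] = None,
    pad: int = 2000,
) -> list[Peak]:
    """Regions present in >= k of the peak sets, re-called on pooled reads.

    Support (>= 1 nt interval overlap between peaks of different sets) defines
    candidate regions; only pooled reads intersecting a region are kept, and
    they are re-called against a randomization span covering the host gene
    (``gene_spans``: (chrom, strand) -> [(start, end, gene_id), ...]).
    Without gene spans the region padded by ``pad`` nt per side is used, so
    the null is never confined to the signal stack itself.
    """
    if k > len(peak_sets):
        raise ValueError(f"k={k} exceeds number of peak sets ({len(peak_sets)})")
    regions = _supported_regions(peak_sets, k)
    out: list[Peak] = []
    for i, (chrom, strand, s, e, sets) in enumerate(regions):
        span, gene_id = (max(0, s - pad), e + pad), None
        if gene_spans is not None:
            for ga, gb, gid in gene_spans.get((chrom, strand), []):
                if ga < e and gb > s:
                    span, gene_id = (min(ga, s), max(gb, e)), gid
                    break
        sel = all_reads[
            (all_reads["chrom"] == chrom)
            & (all_reads["strand"] == strand)
            & (all_reads["start"] < e)
            & (all_reads["end"] > s)
        ]
        called = call_peaks_gene(
            sel, span, chrom=chrom, strand=strand,
            alpha=alpha, n_iter=n_iter, seed=seed + i, gene_id=gene_id,
        )
        out.extend(replace(p, support=sets) for p in called)
    return out
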