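"""Peak annotation, summit association, motif occurrence and metaprofiles."""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data.IUPACData import ambiguous_dna_values

from .annotation import (
    GeneIndex,
    GeneModel,
    TranscriptModel,
    exon_boundaries_transcriptomic,
    genomic_to_transcriptomic,
)
from .peaks import Peak
from .seq import fetch

CATEGORIES = ("CDS_exon", "UTR5", "UTR3", "intron")
_PRECEDENCE = {c: i for i, c in enumerate(("CDS_exon", "UTR5", "UTR3", "intron", "intergenic"))}


@dataclass
class AnnotatedPeak:
    peak: Peak
    category: str  # CDS_exon | UTR5 | UTR3 | intron | intergenic
    gene_id: str = ""
    eif4a3_associated: bool = False


def _transcript_category(pos: int, tx: TranscriptModel, strand: str) -> Optional[str]:
    a, b = tx.span
    if not a <= pos < b:
        return None
    in_exon = any(s <= pos < e for s, e in tx.exons)
    if not in_exon:
        return "intron"
    if tx.cds_start is None:
        return "UTR5"  # no CDS annotated: treat whole exon body as UTR-like
    if tx.cds_start <= pos < tx.cds_end:
        return "CDS_exon"
    before_cds = pos < tx.cds_start
    if strand == "+":
        return "UTR5" if before_cds else "UTR3"
    return "UTR3" if before_cds else "UTR5"


def annotate_peak(
    peak: Peak,
    index: GeneIndex,
    representative: Mapping[str, TranscriptModel],
) -> AnnotatedPeak:
    """Assign one category by summit position.

    The representative transcript is consulted first; when it yields an
    intron (or no hit) other isoforms may upgrade the call to an exonic
    category under the precedence CDS_exon > UTR5 > UTR3 > intron.
    """
    hits = index.at(peak.chrom, peak.strand, peak.summit)
    best = "intergenic"
    best_gene = ""
    for gene in hits:
        cats = []
        rep = representative.get(gene.gene_id)
        if rep is not None:
            c = _transcript_category(peak.summit, rep, gene.strand)
            if c in ("CDS_exon", "UTR5", "UTR3"):
                cats = [c]
        if not cats:
            cats = [
                c
                for t in gene.transcripts
                if (c := _transcript_category(peak.summit, t, gene.strand)) is not None
            ]
        for c in cats:
            if _PRECEDENCE[c] < _PRECEDENCE[best]:
                best, best_gene = c, gene.gene_id
    return AnnotatedPeak(peak, best, best_gene)


def annotate_peaks(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    representative: Mapping[str, TranscriptModel],
) -> list[AnnotatedPeak]:
    index = GeneIndex(genes)
    return [annotate_peak(p, index, representative) for p in peaks]


def category_fractions(annotated: Sequence[AnnotatedPeak]) -> pd.Series:
    """Fractions over the four genic categories (intergenic excluded)."""
    cats = [a.category for a in annotated if a.category != "intergenic"]
    s = pd.Series(cats, dtype=object).value_counts()
    s = s.reindex(CATEGORIES, fill_value=0)
    return s / max(1, s.sum())


def associate_peaks(
    set_a: Sequence[Peak], set_b: Sequence[Peak], tol: int = 10
) -> list[bool]:
    """For each peak in A: is there a same-strand B summit within tol nt?"""
    by_key: dict[tuple[str, str], np.ndarray] = {}
    for p in set_b:
        by_key.setdefault((p.chrom, p.strand), []).append(p.summit)  # type: ignore[attr-defined]
    by_key = {k: np.sort(np.asarray(v)) for k, v in by_key.items()}
    out = []
    for p in set_a:
        summits = by_key.get((p.chrom, p.strand))
        if summits is None or len(summits) == 0:
            out.append(False)
            continue
        i = np.searchsorted(summits, p.summit)
        near = []
        if i < len(summits):
            near.append(summits[i])
        if i > 0:
            near.append(summits[i - 1])
        out.append(any(abs(int(s) - p.summit) <= tol for s in near))
    return out


# ---------------------------------------------------------------------------
# motifs


@dataclass
class MotifSpec:
    name: str
    pattern: str | np.ndarray  # IUPAC string or (L, 4) probability matrix
    window: int = 20
    threshold_frac: float = 0.8  # PWM: fraction of maximal log-odds


def iupac_regex(pattern: str) -> re.Pattern:
    parts = []
    for b in pattern.upper():
        vals = ambiguous_dna_values.get(b, b)
        parts.append(vals if len(vals) == 1 else f"[{vals}]")
    return re.compile("".join(parts))


def _pwm_hit(seq: str, pwm: np.ndarray, threshold_frac: float) -> bool:
    logodds = np.log2(np.maximum(pwm, 1e-9) / 0.25)
    thr = threshold_frac * logodds.max(axis=1).sum()
    L = len(pwm)
    s = seq.upper()
    for i in range(len(s) - L + 1):
        score = 0.0
        for j in range(L):
            k = "ACGT".find(s[i + j])
            score += logodds[j, k] if k >= 0 else 0.0
        if score >= thr:
            return True
    return False


def motif_in_window(seq: str, motif: MotifSpec) -> bool:
    if isinstance(motif.pattern, str):
        return iupac_regex(motif.pattern).search(seq.upper()) is not None
    return _pwm_hit(seq, motif.pattern, motif.threshold_frac)


def summit_window_seq(peak: Peak, fasta, window: int = 20) -> str:
    """Strand-oriented window centered on the summit (clipped at contig ends)."""
    half = window // 2
    return fetch(fasta, peak.chrom, peak.summit - half, peak.summit + window - half, peak.strand)


def motif_fraction(
    annotated: Sequence[AnnotatedPeak],
    motifs: Sequence[MotifSpec],
    fasta,
) -> pd.DataFrame:
    """Fraction of peaks whose summit window contains each motif.

    Reported for all peaks and for the exonic / intronic subsets; empty
    subsets give NaN.
    """
    subsets = {
        "all": list(annotated),
        "exonic": [a for a in annotated if a.category in ("CDS_exon", "UTR5", "UTR3")],
        "intronic": [a for a in annotated if a.category == "intron"],
    }
    rows = []
    for m in motifs:
        for name, subset in subsets.items():
            if not subset:
                frac = float("nan")
            else:
                hits = sum(
                    motif_in_window(summit_window_seq(a.peak, fasta, m.window), m)
                    for a in subset
                )
                frac = hits / len(subset)
            rows.append(dict(motif=m.name, subset=name, fraction=frac, n=len(subset)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# positional metaprofiles


def internal_exons_transcriptomic(
    representative: Mapping[str, TranscriptModel],
    strand_of: Mapping[str, str],
) -> dict[str, list[tuple[int, int]]]:
    """Internal exon intervals in transcript coordinates, per transcript id."""
    out = {}
    for gid, tx in representative.items():
        ivs = exon_boundaries_transcriptomic(tx, strand_of[gid])
        out[tx.transcript_id] = ivs[1:-1]
    return out


def exon_end_profile(
    summits: pd.DataFrame,
    internal_exons: Mapping[str, list[tuple[int, int]]],
    max_dist: int = 100,
    n_random: int = 100,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Summit distance profiles from internal-exon 5' and 3' ends with a null.

    ``summits`` columns: transcript_id, summit (transcript coordinates).
    Only summits falling inside an internal exon are used.  Frequencies are
    normalized by the number of contributing peaks; the null re-draws each
    summit uniformly within its host exon ``n_random`` times and averages.
    """
    rng = np.random.default_rng(seed)
    d5, d3, hosts = [], [], []
    for row in summits.itertuples(index=False):
        for a, b in internal_exons.get(row.transcript_id, []):
            if a <= row.summit < b:
                d5.append(row.summit - a)
                d3.append(b - 1 - row.summit)
                hosts.append((a, b))
                break
    n = len(hosts)
    obs5 = np.zeros(max_dist + 1)
    obs3 = np.zeros(max_dist + 1)
    null5 = np.zeros(max_dist + 1)
    null3 = np.zeros(max_dist + 1)
    for x in d5:
        if x <= max_dist:
            obs5[x] += 1
    for x in d3:
        if x <= max_dist:
            obs3[x] += 1
    for a, b in hosts:
        draws = rng.integers(a, b, n_random)
        for x in draws - a:
            if x <= max_dist:
                null5[x] += 1.0 / n_random
        for x in (b - 1) - draws:
            if x <= max_dist:
                null3[x] += 1.0 / n_random
    scale = 1.0 / max(1, n)
    return {
        "observed_5p": obs5 * scale,
        "observed_3p": obs3 * scale,
        "null_5p": null5 * scale,
        "null_3p": null3 * scale,
        "n_peaks": np.array([n]),
    }


def intron_boundary_histogram(
    annotated: Sequence[AnnotatedPeak],
    intron_of_summit,
) -> tuple[pd.Series, pd.Series]:
    """Distances of intronic summits into the intron from the 5' splice site
    and back from the 3' splice site (strand-aware).

    ``intron_of_summit(peak)`` returns the host IntronInterval or None.
    """
    from5, to3 = [], []
    for a in annotated:
        if a.category != "intron":
            continue
        iv = intron_of_summit(a.peak)
        if iv is None:
            continue
        if iv.strand == "+":
            from5.append(a.peak.summit - iv.start)
            to3.append(iv.end - 1 - a.peak.summit)
        else:
            from5.append(iv.end - 1 - a.peak.summit)
            to3.append(a.peak.summit - iv.start)
    s5 = pd.Series(from5, dtype=int).value_counts().sort_index()
    s3 = pd.Series(to3, dtype=int).value_counts().sort_index()
    return s5, s3


def replicate_correlation(gene_counts: pd.DataFrame, warn_below: float = 0.9) -> pd.DataFrame:
    """Pairwise Pearson r over per-gene read counts (replicates as columns)."""
    if gene_counts.shape[1] < 2:
        raise ValueError("need at least two replicates")
    corr = gene_counts.corr(method="pearson")
    low = (corr.to_numpy()[np.triu_indices(len(corr), 1)] < warn_below).any()
    if low:
        import logging

        logging.getLogger(__name__).warning(
            "replicate Pearson correlation below %.2f", warn_below
        )
    return corr
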