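"""Joining binding with splicing: RNA maps, retention shifts, co-regulation.

Sign convention: an event is *enhanced* when the exon is more skipped upon
depletion (delta psi < 0), i.e. the factor normally enhances inclusion;
*silenced* when delta psi > 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peaks import Peak

GROUPS = ("enhanced", "silenced", "control")

# 50-nt exonic windows flanking each splice site of the event trio
EXONIC_REGIONS = ("C1_5p", "C1_3p", "CA_5p", "CA_3p", "C2_5p", "C2_3p")
INTRONIC_REGIONS = ("intron_up", "intron_down")


@dataclass
class RnaMapProfile:
    group: str
    exonic: dict[str, np.ndarray]  # region -> normalized counts per 5-nt bin
    intronic: dict[str, np.ndarray]  # region -> normalized density over 20 relative-position bins
    n_events: int


def _event_region(ev) -> tuple[int, int]:
    lo = min(x for x in (ev.c1_start, ev.ex_start, ev.c2_start) if x >= 0)
    hi = max(ev.c1_end, ev.ex_end, ev.c2_end)
    return lo, hi


def _summits_by_key(peaks: Sequence[Peak]) -> dict[tuple[str, str], np.ndarray]:
    out: dict[tuple[str, str], list[int]] = {}
    for p in peaks:
        out.setdefault((p.chrom, p.strand), []).append(p.summit)
    return {k: np.sort(np.array(v)) for k, v in out.items()}


def _bin_exonic(d: int, window: int, nbins: int, binw: int) -> Optional[int]:
    if 0 <= d < window:
        return d // binw
    return None


def build_rna_map(
    calls: pd.DataFrame,
    events: pd.DataFrame,
    peaks: Sequence[Peak],
    window: int = 50,
    bin_width: int = 5,
    control_dpsi: float = 5.0,
    control_psi_range: tuple[float, float] = (10.0, 90.0),
    n_intron_bins: int = 20,
) -> dict[str, RnaMapProfile]:
    """Positional summit profiles around regulated vs control cassette exons.

    ``calls`` is a differential table (event_id, delta, accepted, psi_control)
    and ``events`` the cassette coordinate table.  Events enter the enhanced /
    silenced groups when accepted and carrying >= 1 summit in the event
    region; the control pool requires control PSI in ``control_psi_range``,
    |delta| < ``control_dpsi`` and >= 1 summit.
    """
    summits = _summits_by_key(peaks)
    nbins = window // bin_width
    acc = {}
    for g in GROUPS:
        acc[g] = {
            "exonic": {r: np.zeros(nbins) for r in EXONIC_REGIONS},
            "intronic": {r: np.zeros(n_intron_bins) for r in INTRONIC_REGIONS},
            "n": 0,
        }
    cass = events[events["event_type"] == "cassette"].set_index("event_id")
    merged = calls.set_index("event_id")
    for eid in cass.index:
        if eid not in merged.index:
            continue
        ev = cass.loc[eid]
        call = merged.loc[eid]
        lo, hi = _event_region(ev)
        s = summits.get((ev.chrom, ev.strand), np.empty(0, int))
        here = s[(s >= lo) & (s < hi)]
        if len(here) == 0:
            continue
        if call["accepted"]:
            group = "enhanced" if call["delta"] < 0 else "silenced"
        elif (
            abs(call["delta"]) < control_dpsi
            and control_psi_range[0] <= call["psi_control"] <= control_psi_range[1]
        ):
            group = "control"
        else:
            continue
        a = acc[group]
        a["n"] += 1
        plus = ev.strand == "+"
        exon_order = [
            ("C1", ev.c1_start, ev.c1_end),
            ("CA", ev.ex_start, ev.ex_end),
            ("C2", ev.c2_start, ev.c2_end),
        ]
        # genomic intron intervals between consecutive exons, oriented below
        g_exons = sorted([(ev.c1_start, ev.c1_end), (ev.ex_start, ev.ex_end), (ev.c2_start, ev.c2_end)])
        g_introns = [
            (g_exons[0][1], g_exons[1][0]),
            (g_exons[1][1], g_exons[2][0]),
        ]
        for x in here:
            for label, es, ee in exon_order:
                if es <= x < ee:
                    d_start = x - es
                    d_end = ee - 1 - x
                    d5 = d_start if plus else d_end  # distance from exon 5' end
                    d3 = d_end if plus else d_start
                    b = _bin_exonic(d5, window, nbins, bin_width)
                    if b is not None:
                        a["exonic"][f"{label}_5p"][b] += 1
                    b = _bin_exonic(d3, window, nbins, bin_width)
                    if b is not None:
                        a["exonic"][f"{label}_3p"][b] += 1
            for gi, (is_, ie_) in enumerate(g_introns):
                if is_ <= x < ie_ and ie_ > is_:
                    rel = (x - is_) / (ie_ - is_)
                    if not plus:
                        rel = 1.0 - rel
                    # genomic-left intron is the transcriptionally upstream one
                    # on +, downstream on -
                    up = (gi == 0) == plus
                    label = "intron_up" if up else "intron_down"
                    b = min(int(rel * n_intron_bins), n_intron_bins - 1)
                    a["intronic"][label][b] += 1
    out = {}
    for g in GROUPS:
        n = acc[g]["n"]
        scale = 1.0 / max(1, n)
        out[g] = RnaMapProfile(
            group=g,
            exonic={r: v * scale for r, v in acc[g]["exonic"].items()},
            intronic={r: v * scale for r, v in acc[g]["intronic"].items()},
            n_events=n,
        )
    return out


def rna_map_table(profiles: Mapping[str, RnaMapProfile]) -> pd.DataFrame:
    rows = []
    for g, prof in profiles.items():
        for region, vals in prof.exonic.items():
            for b, v in enumerate(vals):
                rows.append(dict(group=g, region=region, bin=b, value=float(v), n_events=prof.n_events))
        for region, vals in prof.intronic.items():
            for b, v in enumerate(vals):
                rows.append(dict(group=g, region=region, bin=b, value=float(v), n_events=prof.n_events))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# intron retention vs CLIP status


def dpir_by_clip_status(
    records: pd.DataFrame,
    change_cutoff: float = 5.0,
) -> dict:
    """One-sided (greater) Mann-Whitney of CLIP+ vs CLIP- delta-pir.

    ``records`` columns: intron_id, dpir, clip_status (CLIP_plus / CLIP_minus
    / neither).  Returns the test, per-group changed fractions and values.
    """
    plus = records.loc[records["clip_status"] == "CLIP_plus", "dpir"].to_numpy()
    minus = records.loc[records["clip_status"] == "CLIP_minus", "dpir"].to_numpy()
    if len(plus) == 0 or len(minus) == 0:
        raise ValueError("both CLIP+ and CLIP- groups must be non-empty")
    # tiny groups get the exact permutation null (matches enumeration oracles)
    method = "exact" if min(len(plus), len(minus)) <= 10 else "auto"
    res = stats.mannwhitneyu(plus, minus, alternative="greater", method=method)
    frac = {}
    for name, vals in (("CLIP_plus", plus), ("CLIP_minus", minus), ("all", records["dpir"].to_numpy())):
        frac[name] = dict(
            n=len(vals),
            frac_up=float(np.mean(vals > change_cutoff)),
            frac_down=float(np.mean(vals < -change_cutoff)),
            median=float(np.median(vals)),
        )
    return dict(p_value=float(res.pvalue), statistic=float(res.statistic), groups=frac)


def clip_enrichment_in_changed_introns(
    changed: Sequence[str],
    clip_plus: Sequence[str],
    universe: Sequence[str],
) -> dict:
    """One-sided Fisher exact test: are changed introns enriched for CLIP+?"""
    uni = set(universe)
    ch = set(changed) & uni
    cp = set(clip_plus) & uni
    if not ch <= uni:
        raise ValueError("changed set must lie within the universe")
    a = len(ch & cp)
    b = len(ch - cp)
    c = len(cp - ch)
    d = len(uni - ch - cp)
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return dict(
        table=[[a, b], [c, d]],
        n_changed=len(ch),
        n_changed_clip_plus=a,
        odds_ratio=float(odds),
        p_value=float(p),
    )


def coregulation_overlap(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    threshold: float = 10.0,
) -> pd.DataFrame:
    """Per-type overlap of |delta| > threshold events between two datasets.

    Only events evaluable in both datasets form the universe; direction of
    change is tracked so co-regulation requires the same sign.
    """
    a = calls_a.set_index("event_id")
    b = calls_b.set_index("event_id")
    common = a.index.intersection(b.index)
    a, b = a.loc[common], b.loc[common]
    rows = []
    for etype in sorted(a["event_type"].unique()):
        sel = a["event_type"] == etype
        for sign, tag in ((1, "up"), (-1, "down")):
            in_a = set(common[sel & (sign * a["delta"] > threshold)])
            in_b = set(common[sel & (sign * b["delta"] > threshold)])
            rows.append(
                dict(
                    event_type=etype,
                    direction=tag,
                    n_universe=int(sel.sum()),
                    overlap=len(in_a & in_b),
                    a_only=len(in_a - in_b),
                    b_only=len(in_b - in_a),
                )
            )
    return pd.DataFrame(rows)
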