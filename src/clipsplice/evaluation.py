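"""End-to-end evaluations against the simulator's planted truth.

Each function runs a full pipeline slice on freshly simulated data and
returns plain numbers (recall, precision, p-values, deviations) so recovery
performance can be scored without reaching into simulator internals.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import derive_introns, genomic_to_transcriptomic
from .binding import exon_end_profile, internal_exons_transcriptomic
from .integrate import build_rna_map, dpir_by_clip_status
from .peaks import (
    call_peaks_gene,
    consensus_peaks,
    coverage_profile,
    extend_reads,
    randomization_fdr,
    subtract_control,
)
from .simulate import (
    GenomeConfig,
    TruthBindingSite,
    TruthSpliceEffect,
    make_genome,
    plant_binding_sites,
    simulate_iclip,
    simulate_splice_counts,
)
from .splicing import compute_psi, differential_table


# ---------------------------------------------------------------------------
# 1. toy-instance FDR vs exhaustive enumeration


def toy_fdr_enumeration(n_iter: int = 100_000, seed: int = 0) -> dict:
    """3-position span, 2 unit reads stacked at position 0.

    The exact FDR table is enumerated over all 9 equiprobable placements and
    compared with the Monte-Carlo estimate.
    """
    cov_obs = np.array([2, 0, 0])
    expected = np.zeros(3)
    for a, b in itertools.product(range(3), repeat=2):
        cov = np.bincount([a, b], minlength=3)
        for h in (1, 2):
            expected[h] += (cov >= h).sum() / 9
    obs_exceed = [(cov_obs >= h).sum() for h in (1, 2)]
    exact = np.array([expected[h] / max(1, obs_exceed[h - 1]) for h in (1, 2)])
    raw, _ = randomization_fdr(
        cov_obs, [1, 1], n_iter=n_iter, rng=np.random.default_rng(seed)
    )
    return dict(
        exact=exact.tolist(),
        monte_carlo=raw.tolist(),
        max_abs_diff=float(np.max(np.abs(raw - exact))),
    )


# ---------------------------------------------------------------------------
# shared helpers


def _call_per_gene(reads, genes, alpha=0.01, n_iter=100, seed=0):
    out = []
    for gi, g in enumerate(genes):
        a, b = g.span
        sel = reads[
            (reads["chrom"] == g.chrom)
            & (reads["strand"] == g.strand)
            & (reads["start"] < b)
            & (reads["end"] > a)
        ]
        out.extend(
            call_peaks_gene(
                sel, (a, b), chrom=g.chrom, strand=g.strand,
                alpha=alpha, n_iter=n_iter, seed=seed + gi, gene_id=g.gene_id,
            )
        )
    return out


def score_peaks_against_sites(peaks, sites, tol: int = 10) -> dict:
    """Recall / precision / summit errors of called peaks vs planted sites."""
    matched, errors, hits = set(), [], 0
    for p in peaks:
        best, bd = None, tol + 1
        for j, s in enumerate(sites):
            if (s.chrom, s.strand) != (p.chrom, p.strand):
                continue
            d = abs(s.summit - p.summit)
            if d < bd:
                bd, best = d, j
        if best is not None and bd <= tol:
            hits += 1
            errors.append(bd)
            matched.add(best)
    return dict(
        recall=len(matched) / max(1, len(sites)),
        precision=hits / max(1, len(peaks)),
        n_peaks=len(peaks),
        n_sites=len(sites),
        median_summit_error=float(np.median(errors)) if errors else float("nan"),
        mean_summit_error=float(np.mean(errors)) if errors else float("nan"),
    )


# ---------------------------------------------------------------------------
# 2. planted-site recovery through the consensus pipeline


def planted_site_recovery(
    n_genes: int = 200,
    n_sites: int = 100,
    strength: float = 30.0,
    background_rate: float = 0.01,
    seed: int = 0,
) -> dict:
    sim = make_genome(GenomeConfig(n_genes=n_genes), seed=seed)
    sites = plant_binding_sites(
        sim, n_sites, ["exon_CDS", "intron_5ss_proximal", "UTR3"],
        strength=strength, seed=seed + 1,
    )
    reps = simulate_iclip(sim, sites, background_rate, 3, seed=seed + 2)
    (ctl,) = simulate_iclip(
        sim, sites, background_rate, 1, control=True, seed=seed + 3
    )
    genes = sorted(sim.genes, key=lambda g: g.gene_id)
    ctl_peaks = _call_per_gene(extend_reads(ctl), genes, seed=seed + 90000)
    sets, pooled = [], []
    for i, r in enumerate(reps):
        er = extend_reads(r)
        pooled.append(er)
        sets.append(subtract_control(_call_per_gene(er, genes, seed=seed + 1000 * i), ctl_peaks))
    spans: dict = {}
    for g in genes:
        a, b = g.span
        spans.setdefault((g.chrom, g.strand), []).append((a, b, g.gene_id))
    common = consensus_peaks(
        sets, pd.concat(pooled, ignore_index=True), k=2, seed=seed + 5, gene_spans=spans
    )
    return score_peaks_against_sites(common, sites)


def replicate_dropout_recovery(
    n_genes: int = 120, n_sites: int = 40, strength: float = 30.0, seed: int = 0
) -> dict:
    """Sites present in 2 of 3 replicates survive consensus; 1-of-3 sites do not."""
    sim = make_genome(GenomeConfig(n_genes=n_genes), seed=seed)
    sites2 = plant_binding_sites(sim, n_sites, "exon_CDS", strength=strength, seed=seed + 1)
    sites1 = plant_binding_sites(sim, n_sites, "UTR3", strength=strength, seed=seed + 2)
    genes = sorted(sim.genes, key=lambda g: g.gene_id)
    site_sets = [sites2 + sites1, sites2, []]
    reps = []
    for i, ss in enumerate(site_sets):
        (r,) = simulate_iclip(
            sim, ss, 0.01, 1, seed=seed + 3 + i, depth_factors=[1.0]
        )
        reps.append(r)
    sets, pooled = [], []
    for i, r in enumerate(reps):
        er = extend_reads(r)
        pooled.append(er)
        sets.append(_call_per_gene(er, genes, seed=seed + 1000 * i))
    spans: dict = {}
    for g in genes:
        a, b = g.span
        spans.setdefault((g.chrom, g.strand), []).append((a, b, g.gene_id))
    common = consensus_peaks(
        sets, pd.concat(pooled, ignore_index=True), k=2, seed=seed + 9, gene_spans=spans
    )
    two = score_peaks_against_sites(common, sites2)
    one = score_peaks_against_sites(common, sites1)
    return dict(recall_2of3=two["recall"], recall_1of3=one["recall"])


# ---------------------------------------------------------------------------
# 3. exon -24 metaprofile


def minus24_metaprofile(
    n_genes: int = 80,
    n_sites: int = 60,
    strength: float = 40.0,
    seed: int = 0,
    max_dist: int = 60,
    n_random: int = 200,
) -> dict:
    """Plant only exon_minus24 sites, call peaks, profile summit distances.

    Returns the mode of the 3'-end distance histogram and the null's maximum
    deviation from its analytic expectation in Monte-Carlo sd units.
    """
    sim = make_genome(GenomeConfig(n_genes=n_genes), seed=seed)
    sites = plant_binding_sites(sim, n_sites, "exon_minus24", strength=strength, seed=seed + 1)
    (reads,) = simulate_iclip(sim, sites, 0.005, 1, seed=seed + 2, depth_factors=[1.0])
    genes = sorted(sim.genes, key=lambda g: g.gene_id)
    peaks = _call_per_gene(extend_reads(reads), genes, seed=seed + 3)
    rep = {g.gene_id: g.transcripts[0] for g in genes}
    strand_of = {g.gene_id: g.strand for g in genes}
    rows = []
    for p in peaks:
        if p.gene_id is None:
            continue
        tx = rep[p.gene_id]
        off = genomic_to_transcriptomic(p.summit, tx, strand_of[p.gene_id])
        if off is not None:
            rows.append(dict(transcript_id=tx.transcript_id, summit=off))
    summits = pd.DataFrame(rows, columns=["transcript_id", "summit"])
    internal = internal_exons_transcriptomic(rep, strand_of)
    prof = exon_end_profile(summits, internal, max_dist=max_dist, n_random=n_random, seed=seed + 4)
    mode = int(np.argmax(prof["observed_3p"]))

    # analytic expectation of the null: summit uniform within its host exon
    hosts = []
    for row in summits.itertuples(index=False):
        for a, b in internal.get(row.transcript_id, []):
            if a <= row.summit < b:
                hosts.append(b - a)
                break
    n = len(hosts)
    mu = np.zeros(max_dist + 1)
    var = np.zeros(max_dist + 1)
    for L in hosts:
        p = np.array([1.0 / L if d < L else 0.0 for d in range(max_dist + 1)])
        mu += p / n
        var += p * (1 - p) / (n_random * n * n)
    sd = np.sqrt(np.maximum(var, 1e-300))
    dev = np.abs(prof["null_3p"] - mu) / sd
    return dict(
        mode_3p_distance=mode,
        mode_in_20_40=bool(20 <= mode <= 40),
        null_max_dev_sd=float(dev.max()),
        n_profiled_peaks=n,
    )


# ---------------------------------------------------------------------------
# 5. estimator consistency and differential operating characteristics


def psi_estimator_consistency(seed: int = 0) -> dict:
    t = TruthSpliceEffect("e", "cassette", 50.0, 0.0)
    df = simulate_splice_counts([t], depth=10**6, n_reps_per_condition=1, seed=seed)
    row = df[df["condition"] == "control"].iloc[0]
    psi = compute_psi(row["inc_up"], row["inc_down"], row["exc"])
    out = dict(psi_error_depth_1e6=float(abs(psi - 50.0)))
    for depth in (100, 1000, 10000):
        t2 = TruthSpliceEffect("e", "cassette", 37.0, 0.0)
        d2 = simulate_splice_counts([t2], depth=depth, n_reps_per_condition=1, seed=seed + depth)
        r2 = d2[d2["condition"] == "control"].iloc[0]
        err = abs(compute_psi(r2["inc_up"], r2["inc_down"], r2["exc"]) - 37.0)
        out[f"psi_error_depth_{depth}"] = float(err)
        out[f"psi_sd_depth_{depth}"] = float(100 * np.sqrt(0.37 * 0.63 / depth))
    return out


def differential_operating_characteristics(
    n_true: int = 200, n_null: int = 200, depth: int = 500, delta: float = 20.0, seed: int = 0
) -> dict:
    truths = [TruthSpliceEffect(f"s{i}", "cassette", 40.0, delta) for i in range(n_true)]
    nulls = [TruthSpliceEffect(f"n{i}", "cassette", 40.0, 0.0) for i in range(n_null)]
    counts = simulate_splice_counts(truths + nulls, depth=depth, seed=seed)
    calls = differential_table(counts, n_draws=2000, seed=seed + 1).set_index("event_id")
    return dict(
        recall=float(calls.loc[[t.event_id for t in truths], "accepted"].mean()),
        false_acceptance=float(calls.loc[[t.event_id for t in nulls], "accepted"].mean()),
    )


# ---------------------------------------------------------------------------
# 6. delta-pir coupling to CLIP status


def dpir_coupling_recovery(
    n_per_group: int = 300,
    delta: float = 10.0,
    penetrance: float = 0.5,
    depth: int = 2000,
    seed: int = 0,
) -> dict:
    """Plant retention increases on CLIP+ introns only; recover via rank test.

    Also runs an uncoupled null 200 times and KS-tests the p-values against
    uniform.
    """
    rng = np.random.default_rng(seed)

    def simulate_group(n, effect_prob):
        truths = []
        for i in range(n):
            d = delta if rng.random() < effect_prob else 0.0
            truths.append(TruthSpliceEffect(f"e{i}", "intron_retention", 8.0, d))
        counts = simulate_splice_counts(
            truths, depth=depth, seed=int(rng.integers(2**31))
        )
        dpirs = []
        for eid, grp in counts.groupby("event_id"):
            lv = {}
            for cond, sub in grp.groupby("condition"):
                b = (sub["e1i"].sum() + sub["ie2"].sum()) / 2
                lv[cond] = 100 * b / (b + sub["e1e2"].sum())
            dpirs.append(lv["kd"] - lv["control"])
        return np.array(dpirs)

    plus = simulate_group(n_per_group, penetrance)
    minus = simulate_group(n_per_group, 0.0)
    rec = pd.DataFrame(
        dict(
            intron_id=[f"x{i}" for i in range(2 * n_per_group)],
            dpir=np.concatenate([plus, minus]),
            clip_status=["CLIP_plus"] * n_per_group + ["CLIP_minus"] * n_per_group,
        )
    )
    res = dpir_by_clip_status(rec)
    null_ps = []
    for _ in range(200):
        a = rng.normal(0, 1.5, n_per_group)
        b = rng.normal(0, 1.5, n_per_group)
        null_ps.append(
            float(stats.mannwhitneyu(a, b, alternative="greater").pvalue)
        )
    ks = stats.kstest(null_ps, "uniform")
    return dict(
        p_value=res["p_value"],
        frac_up_clip_plus=res["groups"]["CLIP_plus"]["frac_up"],
        frac_up_clip_minus=res["groups"]["CLIP_minus"]["frac_up"],
        null_ks_p=float(ks.pvalue),
    )


# ---------------------------------------------------------------------------
# 7. RNA-map recovery


def rna_map_recovery(n_events: int = 30, seed: int = 0) -> dict:
    """Plant 5'ss-proximal upstream-intron sites for enhanced events only.

    Control events get a uniformly placed site so they qualify for the
    control pool; returns the enhanced:control upstream-intron density ratio
    over the first quarter of the intron.
    """
    from .simulate import plant_splice_effects

    sim = make_genome(GenomeConfig(n_genes=6 * n_events // 2), seed=seed)
    events, truths = plant_splice_effects(
        sim, n_cassette=2 * n_events + 10, n_ir=0, delta_choices=[0.0], seed=seed + 1
    )
    rng = np.random.default_rng(seed + 2)
    cass = events[events["event_type"] == "cassette"].reset_index(drop=True)
    idx = rng.permutation(len(cass))
    enhanced_ids = set(cass["event_id"].iloc[idx[:n_events]])
    truths = [
        TruthSpliceEffect(
            t.event_id, t.event_type, t.psi_control,
            -20.0 if t.event_id in enhanced_ids else 0.0,
        )
        for t in truths
    ]
    sites = []
    for ev in cass.itertuples(index=False):
        plus = ev.strand == "+"
        if ev.event_id in enhanced_ids:
            d = int(rng.integers(10, 60))
            pos = ev.c1_end + d if plus else ev.c1_start - 1 - d
        else:
            lo = min(ev.c1_start, ev.c2_start)
            hi = max(ev.c1_end, ev.c2_end)
            pos = int(rng.integers(lo, hi))
        sites.append(
            TruthBindingSite(
                f"s_{ev.event_id}", ev.gene_id, ev.chrom, ev.strand,
                int(pos), 60.0, "planted",
            )
        )
    (reads,) = simulate_iclip(sim, sites, 0.002, 1, seed=seed + 3, depth_factors=[1.0])
    genes = sorted(sim.genes, key=lambda g: g.gene_id)
    peaks = _call_per_gene(extend_reads(reads), genes, seed=seed + 4)
    counts = simulate_splice_counts(truths, depth=500, seed=seed + 5)
    calls = differential_table(counts, n_draws=1000, seed=seed + 6)
    prof = build_rna_map(calls, events, peaks)
    near = slice(0, 5)  # first quarter of 20 relative-position bins
    enh = float(prof["enhanced"].intronic["intron_up"][near].sum())
    ctl = float(prof["control"].intronic["intron_up"][near].sum())
    return dict(
        n_enhanced=prof["enhanced"].n_events,
        n_control=prof["control"].n_events,
        enhanced_near_5ss=enh,
        control_near_5ss=ctl,
        ratio=enh / max(ctl, 1e-9),
    )


# ---------------------------------------------------------------------------
# 8. exact statistic oracles


def _enumerate_ranksum_one_sided(a, b) -> float:
    """P(U >= observed U) over all assignments of the pooled values."""
    pooled = list(a) + list(b)
    n = len(a)

    def u_stat(x, y):
        return sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)

    observed = u_stat(a, b)
    count = total = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        x = [pooled[i] for i in comb]
        y = [pooled[i] for i in range(len(pooled)) if i not in comb]
        total += 1
        if u_stat(x, y) >= observed - 1e-12:
            count += 1
    return count / total


def exact_statistic_checks(seed: int = 0) -> dict:
    out = {}
    # two-sided rank-sum on {1,2,3} vs {10,20,30}: 2/20 by enumeration
    r = stats.mannwhitneyu([1, 2, 3], [10, 20, 30], alternative="two-sided", method="exact")
    out["ranksum_two_sided"] = float(r.pvalue)
    # one-sided Mann-Whitney {6,7,8} vs {0,0,1}
    rec = pd.DataFrame(
        dict(
            intron_id=list("abcdef"),
            dpir=[6, 7, 8, 0, 0, 1],
            clip_status=["CLIP_plus"] * 3 + ["CLIP_minus"] * 3,
        )
    )
    out["mw_one_sided"] = dpir_by_clip_status(rec)["p_value"]
    out["mw_one_sided_enum"] = _enumerate_ranksum_one_sided([6, 7, 8], [0, 0, 1])
    # random small groups vs enumeration
    rng = np.random.default_rng(seed)
    max_diff = 0.0
    for _ in range(20):
        a = rng.choice(100, rng.integers(3, 7), replace=False).tolist()
        b = rng.choice(np.arange(100, 200), rng.integers(3, 7), replace=False).tolist()
        p_enum = _enumerate_ranksum_one_sided(a, b)
        p_pkg = float(stats.mannwhitneyu(a, b, alternative="greater", method="exact").pvalue)
        max_diff = max(max_diff, abs(p_enum - p_pkg))
    out["mw_enum_max_diff"] = max_diff
    # Fisher extreme table
    odds, p = stats.fisher_exact([[10, 0], [0, 10]], alternative="greater")
    out["fisher_10_0"] = float(p)
    out["fisher_10_0_exact"] = 1.0 / 184756.0
    # chi-square closed form
    chi2 = (82 - 53) ** 2 / 53 + (24 - 53) ** 2 / 53
    out["chi2_82_24"] = float(chi2)
    out["chi2_82_24_p"] = float(stats.chi2.sf(chi2, 1))
    return out


# ---------------------------------------------------------------------------
# 9. coordinate round-trip


def coordinate_roundtrip_check(n_genes: int = 20, seed: int = 0) -> dict:
    from .annotation import transcriptomic_to_genomic

    sim = make_genome(GenomeConfig(n_genes=n_genes), seed=seed)
    n_checked, n_fail = 0, 0
    for g in sim.genes:
        t = g.transcripts[0]
        for a, b in t.exons:
            for pos in range(a, b):
                off = genomic_to_transcriptomic(pos, t, g.strand)
                n_checked += 1
                if off is None or transcriptomic_to_genomic(off, t, g.strand) != pos:
                    n_fail += 1
    return dict(n_positions=n_checked, n_failures=n_fail)
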