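"""Read-count based CLIP+/CLIP- intron classification and intron features.

An intron is CLIP+ when, in at least k of the experiments, its read count is
at least fivefold the matched control count (or at least ``min_reads`` when
the control has none).  CLIP- requires count <= control in every experiment.
Introns of genes below the normalized-expression floor are dropped from the
universe before classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import IntronInterval
from .seq import fetch, gc_fraction

DONOR_CONTEXT = (3, 6)  # exonic, intronic nt around the 5' splice site
ACCEPTOR_CONTEXT = (20, 3)  # intronic, exonic nt around the 3' splice site


@dataclass
class ClipStatus:
    status: str  # CLIP_plus | CLIP_minus | neither
    support: int  # experiments meeting the CLIP+ rule


@dataclass
class IntronFeatures:
    length: int
    gc: float
    ss5_score: float
    ss3_score: float


def count_intron_reads(
    reads: pd.DataFrame,
    introns: Sequence[IntronInterval],
    min_overlap: int = 5,
) -> dict[str, int]:
    """Reads per intron, requiring >= min_overlap nt same-strand overlap.

    A read counts toward at most one intron: the largest-overlap one
    (leftmost intron start on ties).
    """
    counts = {iv.intron_id: 0 for iv in introns}
    by_key: dict[tuple[str, str], list[IntronInterval]] = {}
    for iv in introns:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    for v in by_key.values():
        v.sort(key=lambda iv: iv.start)
    for key, sub in reads.groupby(["chrom", "strand"], sort=False):
        ivs = by_key.get(tuple(key), [])
        if not ivs:
            continue
        starts = np.array([iv.start for iv in ivs])
        max_len = max(iv.length for iv in ivs)
        rs = sub["start"].to_numpy()
        re_ = sub["end"].to_numpy()
        lo = np.searchsorted(starts, rs - max_len, side="left")
        hi = np.searchsorted(starts, re_, side="left")
        for j in range(len(sub)):
            best, best_ov = None, 0
            for iv in ivs[lo[j] : hi[j]]:
                ov = min(re_[j], iv.end) - max(rs[j], iv.start)
                if ov > best_ov:
                    best, best_ov = iv, ov
            if best is not None and best_ov >= min_overlap:
                counts[best.intron_id] += 1
    return counts


def size_factors(count_matrix: pd.DataFrame) -> tuple[pd.Series, pd.DataFrame]:
    """Median-of-ratios normalization (genes x samples).

    Genes with a zero in any sample are excluded from the median.  Returns
    (per-sample factors, normalized counts).
    """
    mat = count_matrix.to_numpy(dtype=float)
    nonzero = (mat > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene has nonzero counts in all samples")
    sub = mat[nonzero]
    log_geo = np.log(sub).mean(axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geo[:, None], axis=0))
    fs = pd.Series(factors, index=count_matrix.columns, name="size_factor")
    return fs, count_matrix / factors


def classify_intron(
    counts: Sequence[int],
    controls: Sequence[int],
    fold: float = 5.0,
    min_reads: int = 5,
    k: int = 2,
) -> ClipStatus:
    """Apply the fivefold / min-reads CLIP+ rule and the all-<=-control CLIP- rule."""
    if len(counts) != len(controls):
        raise ValueError("counts and controls must align per experiment")
    support = 0
    for c, ctl in zip(counts, controls):
        if (ctl > 0 and c / ctl >= fold) or (ctl == 0 and c >= min_reads):
            support += 1
    if support >= k:
        return ClipStatus("CLIP_plus", support)
    if all(c <= ctl for c, ctl in zip(counts, controls)):
        return ClipStatus("CLIP_minus", support)
    return ClipStatus("neither", support)


def classify_table(
    intron_counts: pd.DataFrame,
    gene_norm_expr: Mapping[str, float],
    expr_min: float = 1.0,
    fold: float = 5.0,
    min_reads: int = 5,
    k: int = 2,
) -> pd.DataFrame:
    """Classify every intron of sufficiently expressed genes.

    ``intron_counts`` columns: intron_id, gene_id, count_1..count_n,
    control_1..control_n (n experiments, matched controls; a single control
    column is broadcast to all experiments).
    """
    ccols = sorted(c for c in intron_counts.columns if c.startswith("count_"))
    kcols = sorted(c for c in intron_counts.columns if c.startswith("control_"))
    if not kcols:
        raise ValueError("missing control columns")
    if len(kcols) == 1:
        kcols = kcols * len(ccols)
    rows = []
    for rec in intron_counts.itertuples(index=False):
        expr = gene_norm_expr.get(rec.gene_id, 0.0)
        if expr < expr_min:
            continue
        counts = [getattr(rec, c) for c in ccols]
        controls = [getattr(rec, kc) for kc in kcols]
        st = classify_intron(counts, controls, fold=fold, min_reads=min_reads, k=k)
        rows.append(
            dict(intron_id=rec.intron_id, gene_id=rec.gene_id,
                 status=st.status, support=st.support)
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# splice-site scoring (pluggable)


class ConstantScorer:
    """Plug-in contract stub: every site scores the same value."""

    def __init__(self, value: float = 0.0):
        self.value = value

    def score_donor(self, seq: str) -> float:
        return self.value

    def score_acceptor(self, seq: str) -> float:
        return self.value


class PwmSpliceScorer:
    """First-order PWM log2-odds scorer trained on observed splice sites."""

    def __init__(self, donor_pwm: np.ndarray, acceptor_pwm: np.ndarray):
        self.donor_pwm = donor_pwm
        self.acceptor_pwm = acceptor_pwm

    @staticmethod
    def _train_pwm(seqs: Sequence[str], length: int, pseudocount: float = 1.0) -> np.ndarray:
        counts = np.full((length, 4), pseudocount)
        for s in seqs:
            if len(s) != length:
                continue
            for i, b in enumerate(s.upper()):
                j = "ACGT".find(b)
                if j >= 0:
                    counts[i, j] += 1
        return counts / counts.sum(axis=1, keepdims=True)

    @classmethod
    def train(cls, donor_seqs: Sequence[str], acceptor_seqs: Sequence[str]) -> "PwmSpliceScorer":
        d = sum(DONOR_CONTEXT)
        a = sum(ACCEPTOR_CONTEXT)
        return cls(cls._train_pwm(donor_seqs, d), cls._train_pwm(acceptor_seqs, a))

    @staticmethod
    def _score(pwm: np.ndarray, seq: str) -> float:
        score = 0.0
        for i, b in enumerate(seq.upper()[: len(pwm)]):
            j = "ACGT".find(b)
            p = pwm[i, j] if j >= 0 else 0.25
            score += np.log2(max(p, 1e-9) / 0.25)
        return float(score)

    def score_donor(self, seq: str) -> float:
        return self._score(self.donor_pwm, seq)

    def score_acceptor(self, seq: str) -> float:
        return self._score(self.acceptor_pwm, seq)


def splice_site_contexts(intron: IntronInterval, fasta) -> tuple[str, str]:
    """(donor 9-mer, acceptor 23-mer) in transcription orientation."""
    ex_d, in_d = DONOR_CONTEXT
    in_a, ex_a = ACCEPTOR_CONTEXT
    if intron.strand == "+":
        donor = fetch(fasta, intron.chrom, intron.start - ex_d, intron.start + in_d, "+")
        acceptor = fetch(fasta, intron.chrom, intron.end - in_a, intron.end + ex_a, "+")
    else:
        donor = fetch(fasta, intron.chrom, intron.end - in_d, intron.end + ex_d, "-")
        acceptor = fetch(fasta, intron.chrom, intron.start - ex_a, intron.start + in_a, "-")
    return donor, acceptor


def train_scorer_from_introns(introns: Sequence[IntronInterval], fasta) -> PwmSpliceScorer:
    donors, acceptors = [], []
    for iv in introns:
        d, a = splice_site_contexts(iv, fasta)
        donors.append(d)
        acceptors.append(a)
    return PwmSpliceScorer.train(donors, acceptors)


def intron_features(intron: IntronInterval, fasta, scorer) -> IntronFeatures:
    body = fetch(fasta, intron.chrom, intron.start, intron.end, intron.strand)
    donor, acceptor = splice_site_contexts(intron, fasta)
    return IntronFeatures(
        length=intron.length,
        gc=gc_fraction(body),
        ss5_score=scorer.score_donor(donor),
        ss3_score=scorer.score_acceptor(acceptor),
    )


def compare_intron_groups(
    features: pd.DataFrame,
    clip_plus_ids: Sequence[str],
    clip_minus_ids: Sequence[str],
    columns: Sequence[str] = ("length", "gc", "ss5_score", "ss3_score"),
) -> pd.DataFrame:
    """Two-sided Mann-Whitney per feature between CLIP+ and CLIP- introns.

    ``features`` must be indexed by intron_id.
    """
    plus = features.loc[[i for i in clip_plus_ids if i in features.index]]
    minus = features.loc[[i for i in clip_minus_ids if i in features.index]]
    if len(plus) == 0 or len(minus) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for col in columns:
        a, b = plus[col].to_numpy(), minus[col].to_numpy()
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
        rows.append(
            dict(
                feature=col,
                median_clip_plus=float(np.median(a)),
                median_clip_minus=float(np.median(b)),
                direction="higher_in_clip_plus"
                if np.median(a) > np.median(b)
                else "lower_in_clip_plus",
                p_value=float(res.pvalue),
            )
        )
    return pd.DataFrame(rows)
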