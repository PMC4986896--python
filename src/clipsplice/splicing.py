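"""PSI / pir quantification, differential-event acceptance and direction bias.

Differential acceptance follows an -r/-m/-e contract: an event is accepted
when the posterior probability that the true between-condition difference
exceeds m percent is at least r, and every compared sample carries at least
e reads.  The posterior is a Beta on the inclusion (or retention) fraction
with pooled replicate counts and a flat prior.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def compute_psi(inc_up: float, inc_down: float, exc: float) -> float:
    """Percent spliced in: 100 * mean-inclusion / (mean-inclusion + exclusion)."""
    i_bar = (inc_up + inc_down) / 2.0
    tot = i_bar + exc
    if tot == 0:
        return float("nan")
    return 100.0 * i_bar / tot


def compute_pir(
    e1i: float,
    ie2: float,
    e1e2: float,
    min_coverage: int = 0,
    max_balance_ratio: float = 5.0,
) -> tuple[float, bool]:
    """Percent intron retained and a reliability flag.

    pir = 100 * mean-boundary / (mean-boundary + spliced).  The estimate is
    flagged unreliable when total coverage is below ``min_coverage`` or the
    two boundary counts are grossly unbalanced.
    """
    b_bar = (e1i + ie2) / 2.0
    tot = b_bar + e1e2
    if tot == 0:
        return float("nan"), False
    pir = 100.0 * b_bar / tot
    reliable = (e1i + ie2 + e1e2) >= min_coverage
    lo, hi = min(e1i, ie2), max(e1i, ie2)
    if hi > 0 and (lo == 0 or hi / max(lo, 1) > max_balance_ratio) and hi >= 5:
        reliable = False
    return pir, reliable


@dataclass
class DifferentialCall:
    event_id: str
    event_type: str
    psi_control: float  # percent (pir for IR events)
    psi_kd: float
    delta: float  # kd - control
    prob_accept: float  # P(|true difference| >= m)
    accepted: bool
    direction: str
    low_coverage: bool = False


_DIRECTIONS = {
    ("cassette", 1): "more_inclusion",
    ("cassette", -1): "more_skipping",
    ("alt5", 1): "more_inclusion",
    ("alt5", -1): "more_skipping",
    ("alt3", 1): "more_inclusion",
    ("alt3", -1): "more_skipping",
    ("intron_retention", 1): "more_retention",
    ("intron_retention", -1): "less_retention",
}


def _pooled(rows: pd.DataFrame, event_type: str) -> tuple[float, float, np.ndarray]:
    if event_type == "intron_retention":
        sup = (rows["e1i"].sum() + rows["ie2"].sum()) / 2.0
        opp = rows["e1e2"].sum()
        cov = (rows["e1i"] + rows["ie2"] + rows["e1e2"]).to_numpy()
    else:
        sup = (rows["inc_up"].sum() + rows["inc_down"].sum()) / 2.0
        opp = rows["exc"].sum()
        cov = (rows["inc_up"] + rows["inc_down"] + rows["exc"]).to_numpy()
    return float(sup), float(opp), cov


def differential_event(
    event_id: str,
    event_type: str,
    counts_kd: pd.DataFrame,
    counts_control: pd.DataFrame,
    m: float = 10.0,
    r: float = 0.95,
    e: int = 10,
    n_draws: int = 4000,
    rng: Optional[np.random.Generator] = None,
) -> DifferentialCall:
    """Accept/reject one event from replicate count tables of two conditions."""
    rng = rng or np.random.default_rng()
    sup_k, opp_k, cov_k = _pooled(counts_kd, event_type)
    sup_c, opp_c, cov_c = _pooled(counts_control, event_type)
    psi_k = compute_psi(sup_k, sup_k, opp_k)  # sup already averaged; reuse formula
    psi_c = compute_psi(sup_c, sup_c, opp_c)
    low_cov = bool((cov_k < e).any() or (cov_c < e).any())
    draws_k = 100.0 * rng.beta(sup_k + 1.0, opp_k + 1.0, n_draws)
    draws_c = 100.0 * rng.beta(sup_c + 1.0, opp_c + 1.0, n_draws)
    prob = float(np.mean(np.abs(draws_k - draws_c) >= m))
    delta = psi_k - psi_c
    accepted = (not low_cov) and prob >= r and not np.isnan(delta)
    sign = 1 if delta >= 0 else -1
    direction = _DIRECTIONS.get((event_type, sign), "unknown")
    return DifferentialCall(
        event_id=event_id, event_type=event_type,
        psi_control=psi_c, psi_kd=psi_k, delta=delta,
        prob_accept=prob, accepted=accepted, direction=direction,
        low_coverage=low_cov,
    )


def differential_table(
    counts: pd.DataFrame,
    m: float = 10.0,
    r: float = 0.95,
    e: int = 10,
    n_draws: int = 4000,
    seed: int = 0,
) -> pd.DataFrame:
    """Run :func:`differential_event` for every event in a tidy count table.

    Expected columns: event_id, event_type, condition ('control'/'kd'),
    replicate, inc_up, inc_down, exc, e1i, ie2, e1e2.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for eid, grp in counts.groupby("event_id", sort=True):
        etype = grp["event_type"].iloc[0]
        call = differential_event(
            eid, etype,
            grp[grp["condition"] == "kd"],
            grp[grp["condition"] == "control"],
            m=m, r=r, e=e, n_draws=n_draws, rng=rng,
        )
        rows.append(vars(call))
    return pd.DataFrame(rows)


def direction_bias_test(calls: pd.DataFrame) -> pd.DataFrame:
    """Per event type, chi-square goodness of fit of direction counts vs 50:50."""
    rows = []
    for etype, grp in calls[calls["accepted"]].groupby("event_type"):
        counts = grp["direction"].value_counts()
        up = int(counts.iloc[0]) if len(counts) > 0 else 0
        down = int(counts.iloc[1]) if len(counts) > 1 else 0
        if len(counts) == 1:
            up = int(counts.iloc[0])
        n = up + down
        if n == 0:
            continue
        chi2, p = stats.chisquare([up, down])
        rows.append(
            dict(
                event_type=etype,
                direction_major=counts.index[0],
                n_major=up, n_minor=down,
                chi2=float(chi2), p_value=float(p),
            )
        )
    return pd.DataFrame(rows)
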