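"""Human-capital productivity costing and the claims-based HCRU back-calculation.

Indirect costs value lost work time at the average wage: employment rate x
weekly hours x weeks per year x hourly wage x overall work impairment, where
impairment combines WPAI absenteeism (A) and presenteeism (P) by the standard
rule ``A + (1 - A) * P`` (an additive variant is available as a switch).

The back-calculation solves for the mean monthly cost of strata that a claims
analysis could not classify directly: given the overall mean and the means of
the known strata, the pooled unknown-stratum mean follows from the weighted
average identity.  The same pooled value is assigned to every unknown stratum,
which is why the mid-severity strata share one HCRU cost in the base case.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .parameters import (
    SALT_STATES,
    DataError,
    ImpairmentPair,
    ProductivityParams,
    SaltState,
    WEEKS_PER_YEAR,
)

__all__ = [
    "overall_work_impairment",
    "annual_indirect_cost",
    "StrataCostSummary",
    "hcru_backcalc",
    "read_claims_summary",
    "write_claims_summary",
]


def overall_work_impairment(i: ImpairmentPair, additive: bool = False) -> float:
    """Overall proportion of work time lost from absenteeism + presenteeism.

    WPAI combination: absent time is fully lost; presenteeism impairs only
    the time actually at work, giving ``A + (1 - A) * P``.
    """
    a, pres = i.absenteeism, i.presenteeism
    if additive:
        return min(1.0, a + pres)
    return a + (1.0 - a) * pres


def annual_indirect_cost(
    state: SaltState,
    p: ProductivityParams,
    weeks_per_year: float = WEEKS_PER_YEAR,
    additive: bool = False,
) -> float:
    """Annual productivity loss (JPY/year) for one SALT stratum."""
    impair = overall_work_impairment(p.impairment[state], additive=additive)
    return p.pct_employed * p.hours_per_week * weeks_per_year * p.hourly_wage * impair


@dataclass
class StrataCostSummary:
    """Stratified claims-cost summary: overall mean, known stratum means,
    and stratum weights (patient shares)."""

    overall_mean: float
    stratum_means: dict[SaltState, float]  # known strata only
    stratum_weights: dict[SaltState, float]

    def __post_init__(self):
        total = sum(self.stratum_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"stratum weights sum to {total}, not 1")


def hcru_backcalc(
    s: StrataCostSummary, target_strata: Iterable[SaltState]
) -> float:
    """Back-calculate the pooled mean monthly cost of the unknown strata.

    Solves ``overall = sum_known w*m + (sum_target w) * m_target`` for
    ``m_target``.  Every target stratum receives the same pooled value.
    """
    targets = set(target_strata)
    known = {st: m for st, m in s.stratum_means.items() if st not in targets}
    missing = set(s.stratum_weights) - targets - set(known)
    if missing:
        raise DataError(f"no mean for non-target strata: {sorted(x.key for x in missing)}")
    w_target = sum(s.stratum_weights.get(st, 0.0) for st in targets)
    if w_target <= 0:
        raise DataError("target strata have zero total weight")
    known_sum = sum(s.stratum_weights.get(st, 0.0) * m for st, m in known.items())
    m_target = (s.overall_mean - known_sum) / w_target
    if m_target < 0:
        raise DataError(
            f"back-calculated mean is negative ({m_target:.2f}); "
            "summary is infeasible"
        )
    return m_target


def write_claims_summary(s: StrataCostSummary, path: str | Path) -> None:
    rows = [
        {
            "stratum": st.key,
            "weight": s.stratum_weights.get(st, 0.0),
            "mean_cost": s.stratum_means.get(st, ""),
        }
        for st in SALT_STATES
    ]
    rows.append({"stratum": "overall", "weight": 1.0, "mean_cost": s.overall_mean})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_claims_summary(path: str | Path) -> StrataCostSummary:
    df = pd.read_csv(path)
    overall = None
    means: dict[SaltState, float] = {}
    weights: dict[SaltState, float] = {}
    for _, row in df.iterrows():
        if row["stratum"] == "overall":
            overall = float(row["mean_cost"])
            continue
        st = SaltState.from_key(row["stratum"])
        weights[st] = float(row["weight"])
        if pd.notna(row["mean_cost"]) and row["mean_cost"] != "":
            means[st] = float(row["mean_cost"])
    if overall is None:
        raise DataError("claims summary missing the overall row")
    return StrataCostSummary(
        overall_mean=overall, stratum_means=means, stratum_weights=weights
    )
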