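"""Discounted, half-cycle-corrected costing and QALY accumulation.

Converts a pair of cohort traces into per-arm outcome components (drug
acquisition, HCRU, adverse-event management, indirect productivity costs,
QALYs, discounted life-years) and comparative results (incremental costs and
QALYs, ICER, net monetary benefit) under a societal or payer perspective.

Accrual convention: half-cycle correction averages the occupancy at the two
boundaries of each cycle, and the averaged occupancy accrues at the cycle's
midpoint discount factor.  The expected adverse-event cost is a one-off
applied undiscounted at model start (a per-cycle recurrence mode is available
through the run settings).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .cohort import DEAD, CohortTrace
from .parameters import (
    SALT_STATES,
    AdverseEventItem,
    DrugCostSpec,
    ModelParameters,
)
from .productivity import annual_indirect_cost

__all__ = [
    "ArmOutcomes",
    "CEResult",
    "discount_factor",
    "half_cycle_midpoints",
    "cycle_drug_cost",
    "expected_ae_cost",
    "accumulate_outcomes",
    "compare_arms",
    "to_usd",
]

PERSPECTIVES = ("societal", "payer")


def discount_factor(
    annual_rate: float, t_weeks: float, weeks_per_year: float
) -> float:
    """Discount factor ``(1 + r)^(-t/weeks_per_year)`` at time ``t_weeks``."""
    if t_weeks < 0:
        raise ValueError("time must be non-negative")
    if annual_rate < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + annual_rate) ** (-t_weeks / weeks_per_year)


def half_cycle_midpoints(trace: CohortTrace) -> tuple[np.ndarray, np.ndarray]:
    """Effective (boundary-averaged) occupancy and mid-cycle times.

    Returns ``(eff, t_mid)`` where ``eff[t]`` is the mean of the boundary
    occupancies at cycles t and t+1 and ``t_mid[t]`` is the cycle midpoint in
    weeks.
    """
    occ = trace.occupancy
    eff = 0.5 * (occ[:-1] + occ[1:])
    t_mid = 0.5 * (trace.week[:-1] + trace.week[1:])
    return eff, t_mid


def cycle_drug_cost(spec: DrugCostSpec, cycle_weeks: float) -> float:
    """Drug cost (JPY) per on-treatment member-cycle: one 50 mg dose per day,
    scaled by adherence (dispensed-dose proxy)."""
    return spec.unit_price * 7.0 * cycle_weeks * spec.adherence


def expected_ae_cost(items: list[AdverseEventItem], arm: str) -> float:
    """Expected adverse-event management cost per patient (JPY):
    sum of incidence x unit management cost for the given arm."""
    key = "incidence_treated" if arm == "ritlecitinib" else "incidence_untreated"
    return sum(getattr(ae, key) * ae.unit_cost for ae in items)


@dataclass
class ArmOutcomes:
    """Discounted lifetime outcome components for one arm (JPY and QALYs)."""

    arm: str
    perspective: str
    drug_cost: float
    hcru_cost: float
    ae_cost: float
    indirect_cost: float
    qalys: float
    life_years: float

    @property
    def total_cost(self) -> float:
        total = self.drug_cost + self.hcru_cost + self.ae_cost
        if self.perspective == "societal":
            total += self.indirect_cost
        return total


def accumulate_outcomes(
    trace: CohortTrace, p: ModelParameters, perspective: str | None = None
) -> ArmOutcomes:
    """Accumulate discounted costs and QALYs over a cohort trace."""
    st = p.settings
    perspective = perspective or st.perspective
    if perspective not in PERSPECTIVES:
        raise ValueError(f"unknown perspective {perspective!r}")
    cw = float(st.cycle_length_weeks)
    wpy = st.weeks_per_year
    years_per_cycle = cw / wpy
    months_per_cycle = cw / (wpy / 12.0)

    eff, t_mid = half_cycle_midpoints(trace)
    disc = (1.0 + st.annual_discount_rate) ** (-t_mid / wpy)
    salt = eff[:, 0:4] + eff[:, 4:8]          # (T, 4) occupancy by stratum
    on_mass = eff[:, 0:4].sum(axis=1)
    alive = 1.0 - eff[:, DEAD]

    u = p.utilities.as_array()
    qalys = float(np.sum(disc * (salt @ u)) * years_per_cycle)
    life_years = float(np.sum(disc * alive) * years_per_cycle)

    hcru_monthly = np.array([p.hcru[s].total for s in SALT_STATES])
    hcru = float(np.sum(disc * (salt @ hcru_monthly)) * months_per_cycle)

    drug = float(np.sum(disc * on_mass) * cycle_drug_cost(p.drug, cw))

    indirect_annual = np.array(
        [
            annual_indirect_cost(s, p.productivity, wpy, additive=st.wpai_additive)
            for s in SALT_STATES
        ]
    )
    per_cycle_indirect = salt @ indirect_annual * years_per_cycle
    if st.retirement_age is not None:
        working = (0.5 * (trace.age[:-1] + trace.age[1:])) < st.retirement_age
        per_cycle_indirect = per_cycle_indirect * working
    indirect = float(np.sum(disc * per_cycle_indirect))

    ae_per_patient = expected_ae_cost(p.adverse_events, trace.arm)
    if st.ae_cost_recurring:
        # recur at the rate implied by the observation window of the
        # incidences (48 weeks on treatment, 24 weeks untreated)
        window = 48.0 if trace.arm == "ritlecitinib" else 24.0
        ae = float(np.sum(disc * alive) * ae_per_patient * cw / window)
    else:
        ae = ae_per_patient  # one-off at model start, undiscounted

    return ArmOutcomes(
        arm=trace.arm,
        perspective=perspective,
        drug_cost=drug,
        hcru_cost=hcru,
        ae_cost=ae,
        indirect_cost=indirect,
        qalys=qalys,
        life_years=life_years,
    )


@dataclass
class CEResult:
    """Comparative cost-effectiveness result (treated minus untreated)."""

    treated: ArmOutcomes
    untreated: ArmOutcomes
    wtp: float

    @property
    def delta_cost(self) -> float:
        return self.treated.total_cost - self.untreated.total_cost

    @property
    def delta_qaly(self) -> float:
        return self.treated.qalys - self.untreated.qalys

    @property
    def icer(self) -> float:
        """ICER in JPY/QALY; meaningful only when ``dominance`` is ``None``."""
        if self.delta_qaly == 0:
            return math.nan
        return self.delta_cost / self.delta_qaly

    @property
    def dominance(self) -> str | None:
        dc, de = self.delta_cost, self.delta_qaly
        if de == 0:
            return "undefined"
        if dc <= 0 and de > 0:
            return "dominant"
        if dc >= 0 and de < 0:
            return "dominated"
        return None

    @property
    def nmb(self) -> float:
        return self.wtp * self.delta_qaly - self.delta_cost


def compare_arms(a: ArmOutcomes, b: ArmOutcomes, wtp: float) -> CEResult:
    """Compare treated (``a``) against untreated (``b``) at the WTP threshold."""
    return CEResult(treated=a, untreated=b, wtp=wtp)


def to_usd(amount_jpy: float, jpy_per_usd: float) -> float:
    """Constant-rate display conversion from JPY to USD."""
    if jpy_per_usd <= 0:
        raise ValueError("exchange rate must be positive")
    return amount_jpy / jpy_per_usd
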