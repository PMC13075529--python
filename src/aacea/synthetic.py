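"""Synthetic input generators.

The pipeline needs two external inputs that cannot be redistributed: the
official Japanese abridged life table and per-patient claims cost records.
This module generates statistically similar stand-ins:

* :func:`make_life_table` builds a Gompertz-Makeham life table whose default
  parameters are calibrated so the sex-mixed remaining life expectancy at the
  cohort's mean entry age (40.2 years) is Japanese-like (about 46 years;
  female about 48, male about 42.5).  A real MHLW table, if available, plugs
  into the same :func:`aacea.parameters.read_life_table` reader.
* :func:`make_claims` draws claims-like monthly cost records per SALT stratum
  with right-skewed Gamma noise, and :func:`summarize_claims` reduces them to
  the stratified summary consumed by the HCRU back-calculation.

All generators are bit-reproducible given a seed.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .parameters import (
    SALT_STATES,
    LifeTable,
    SaltState,
    remaining_life_expectancy,
)
from .productivity import StrataCostSummary

__all__ = [
    "make_life_table",
    "make_claims",
    "summarize_claims",
    "GOMPERTZ_DEFAULTS",
]

#: Gompertz-Makeham defaults: qx_male(age) = min(1, a + c * exp(b * age)),
#: female rates scaled down by ``sex_ratio_adjust``.  Calibrated once against
#: the life-expectancy targets documented above.
GOMPERTZ_DEFAULTS = {
    "makeham_a": 2.0e-4,
    "gompertz_b": 0.1033,
    "gompertz_c": 1.2e-5,
    "sex_ratio_adjust": 0.54,
}


def make_life_table(
    makeham_a: float = GOMPERTZ_DEFAULTS["makeham_a"],
    gompertz_b: float = GOMPERTZ_DEFAULTS["gompertz_b"],
    gompertz_c: float = GOMPERTZ_DEFAULTS["gompertz_c"],
    sex_ratio_adjust: float = GOMPERTZ_DEFAULTS["sex_ratio_adjust"],
    cap_age: int = 100,
    min_age: int = 0,
) -> LifeTable:
    """Synthetic single-year life table from a Gompertz-Makeham hazard.

    ``qx_male = min(1, a + c*exp(b*age))``; female probabilities are the male
    ones scaled by ``sex_ratio_adjust`` (< 1 means lower female mortality).
    The terminal row at ``cap_age`` carries qx = 1.
    """
    if makeham_a < 0 or gompertz_b < 0 or gompertz_c < 0:
        raise ValueError("hazard parameters must be non-negative")
    if cap_age > 110:
        raise ValueError("cap_age must be <= 110")
    ages = np.arange(min_age, cap_age + 1)
    qm = np.minimum(1.0, makeham_a + gompertz_c * np.exp(gompertz_b * ages))
    qf = np.minimum(1.0, sex_ratio_adjust * qm)
    qm = qm.copy()
    qm[-1] = 1.0
    qf[-1] = 1.0
    return LifeTable(ages=ages, qx_female=qf, qx_male=qm)


def make_claims(
    n: int,
    seed: int,
    stratum_shares: dict[SaltState, float],
    stratum_cost_means: dict[SaltState, float],
    dispersion: float = 1.0,
    cost_kind: str = "non_drug",
) -> pd.DataFrame:
    """Draw claims-like per-patient monthly cost records.

    Strata are drawn from ``stratum_shares``; costs are Gamma with the given
    stratum means and coefficient of variation ``dispersion`` (degenerate at
    the mean when 0).
    """
    total = sum(stratum_shares.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"stratum shares sum to {total}, not 1")
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    rng = np.random.default_rng(seed)
    states = list(stratum_shares)
    probs = np.array([stratum_shares[s] for s in states])
    idx = rng.choice(len(states), size=n, p=probs)
    means = np.array([stratum_cost_means[s] for s in states])[idx]
    if dispersion == 0:
        costs = means
    else:
        shape = 1.0 / dispersion**2
        costs = rng.gamma(shape, means * dispersion**2 / 1.0)
        costs = np.where(means > 0, costs, 0.0)
    return pd.DataFrame(
        {
            "patient_id": [f"p{i:07d}" for i in range(n)],
            "salt_stratum": [states[i].key for i in idx],
            "monthly_cost": costs,
            "cost_kind": cost_kind,
        }
    )


def summarize_claims(records: pd.DataFrame) -> StrataCostSummary:
    """Reduce claims records to stratum weights/means plus the grand mean.

    Empty strata get weight 0 and are excluded from the known means, so the
    reconstruction identity (weighted stratum means = overall mean) holds by
    construction over the observed strata.
    """
    if len(records) == 0:
        raise ValueError("no claims records")
    weights: dict[SaltState, float] = {}
    means: dict[SaltState, float] = {}
    n = len(records)
    for s in SALT_STATES:
        sub = records.loc[records["salt_stratum"] == s.key, "monthly_cost"]
        weights[s] = len(sub) / n
        if len(sub):
            means[s] = float(sub.mean())
    return StrataCostSummary(
        overall_mean=float(records["monthly_cost"].mean()),
        stratum_means=means,
        stratum_weights=weights,
    )
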