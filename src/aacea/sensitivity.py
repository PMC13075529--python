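"""Deterministic and probabilistic sensitivity analysis.

One-way sensitivity analysis (OWSA) sweeps every base-case parameter to its
lower and upper bound (default +/-20%, proportions clipped at 1) and records
the resulting ICER pair per parameter for a tornado diagram.

Probabilistic sensitivity analysis (PSA) redraws all parameters jointly from
moment-matched distributions — Beta for probabilities and utilities, Gamma
for costs (and wages/hours), Dirichlet for each SALT checkpoint distribution
— with standard errors set to 10% of the base-case values, and records the
incremental cost/QALY pair per iteration.  The cost-effectiveness
acceptability curve (CEAC) is the fraction of draws with positive net
monetary benefit across a willingness-to-pay grid.

Parameters are addressed by dotted names (e.g. ``utilities.ge50``,
``hcru.le10.non_drug``, ``checkpoint.ritlecitinib.48.le10``); perturbing one
component of a checkpoint distribution renormalizes the remaining components
proportionally so the shares stay on the simplex.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    SALT_STATES,
    ModelParameters,
    SaltState,
    validate_parameters,
)
from .pipeline import run_base_case

__all__ = [
    "ParameterRange",
    "OwsaEntry",
    "PsaResult",
    "CeacCurve",
    "fit_beta",
    "fit_gamma",
    "fit_dirichlet",
    "get_param",
    "set_param",
    "default_owsa_ranges",
    "owsa_run",
    "sample_parameters",
    "run_psa",
    "ceac",
    "psa_summary",
]


# ---------------------------------------------------------------------------
# Moment-matched distribution fits


def fit_beta(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments Beta fit: returns (alpha, beta)."""
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must be in (0, 1), got {mean}")
    if se <= 0:
        raise ValueError("se must be positive")
    if se * se >= mean * (1.0 - mean):
        raise ValueError(f"infeasible variance {se**2} for mean {mean}")
    nu = mean * (1.0 - mean) / (se * se) - 1.0
    return mean * nu, (1.0 - mean) * nu


def fit_gamma(mean: float, se: float) -> tuple[float, float]:
    """Method-of-moments Gamma fit: returns (shape, scale)."""
    if mean <= 0 or se <= 0:
        raise ValueError("mean and se must be positive")
    shape = (mean / se) ** 2
    return shape, se * se / mean


def fit_dirichlet(
    shares: dict[SaltState, float], se_fraction: float
) -> dict[SaltState, float]:
    """Dirichlet concentrations matching the shares with a relative SE anchor.

    The total concentration is chosen so the largest share's standard
    deviation equals ``se_fraction`` times that share (solving
    ``p(1-p)/(a0+1) = (f p)^2``); component concentrations are
    ``share * a0``.  Zero shares get zero concentration (degenerate at 0).
    """
    if se_fraction <= 0:
        raise ValueError("se_fraction must be positive")
    total = sum(shares.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"shares sum to {total}, not 1")
    p = max(shares.values())
    if p >= 1.0:
        raise ValueError("degenerate shares: simplex interior required")
    if se_fraction**2 >= (1.0 - p) / p:
        raise ValueError(f"infeasible se_fraction {se_fraction} for share {p}")
    a0 = (1.0 - p) / (se_fraction**2 * p) - 1.0
    return {s: x * a0 for s, x in shares.items()}


# ---------------------------------------------------------------------------
# Dotted-name parameter access


def _checkpoint(p: ModelParameters, arm: str, week: str):
    return p.checkpoint(arm, int(week))


def get_param(p: ModelParameters, name: str) -> float:
    parts = name.split(".")
    match parts:
        case ["utilities", key]:
            return p.utilities.values[SaltState.from_key(key)]
        case ["drug", attr]:
            return getattr(p.drug, attr)
        case ["hcru", key, attr]:
            return getattr(p.hcru[SaltState.from_key(key)], attr)
        case ["ae", ae_name, attr]:
            for ae in p.adverse_events:
                if ae.name == ae_name:
                    return getattr(ae, attr)
            raise KeyError(f"unknown adverse event {ae_name!r}")
        case ["productivity", attr]:
            return getattr(p.productivity, attr)
        case ["impairment", key, attr]:
            return getattr(p.productivity.impairment[SaltState.from_key(key)], attr)
        case ["settings", attr]:
            return getattr(p.settings, attr)
        case ["cohort", attr]:
            return getattr(p.cohort, attr)
        case ["checkpoint", arm, week, key]:
            return _checkpoint(p, arm, week).shares[SaltState.from_key(key)]
    raise KeyError(f"unknown parameter name {name!r}")


def set_param(p: ModelParameters, name: str, value: float) -> None:
    """Set a parameter in place; checkpoint shares are renormalized."""
    parts = name.split(".")
    match parts:
        case ["utilities", key]:
            p.utilities.values[SaltState.from_key(key)] = value
        case ["drug", attr]:
            setattr(p.drug, attr, value)
        case ["hcru", key, attr]:
            setattr(p.hcru[SaltState.from_key(key)], attr, value)
        case ["ae", ae_name, attr]:
            for ae in p.adverse_events:
                if ae.name == ae_name:
                    setattr(ae, attr, value)
                    return
            raise KeyError(f"unknown adverse event {ae_name!r}")
        case ["productivity", attr]:
            setattr(p.productivity, attr, value)
        case ["impairment", key, attr]:
            setattr(p.productivity.impairment[SaltState.from_key(key)], attr, value)
        case ["settings", attr]:
            setattr(p.settings, attr, value)
        case ["cohort", attr]:
            setattr(p.cohort, attr, value)
        case ["checkpoint", arm, week, key]:
            cp = _checkpoint(p, arm, week)
            state = SaltState.from_key(key)
            old = cp.shares[state]
            rest = 1.0 - old
            if value < 0 or value > 1:
                raise ValueError(f"share {value} outside [0, 1]")
            if rest <= 0:
                raise ValueError("cannot renormalize a degenerate distribution")
            scale = (1.0 - value) / rest
            for s in SALT_STATES:
                cp.shares[s] = value if s is state else cp.shares[s] * scale
        case _:
            raise KeyError(f"unknown parameter name {name!r}")


# ---------------------------------------------------------------------------
# One-way sensitivity analysis


@dataclass
class ParameterRange:
    name: str
    base: float
    low: float
    high: float
    source: str = "plus-minus-20"

    def __post_init__(self):
        if not self.low <= self.base <= self.high:
            raise ValueError(
                f"{self.name}: need low <= base <= high, got "
                f"{self.low}, {self.base}, {self.high}"
            )


@dataclass
class OwsaEntry:
    name: str
    icer_low: float
    icer_high: float
    error: str | None = None

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


_PROPORTION_PREFIXES = ("utilities", "impairment", "checkpoint")
_PROPORTION_NAMES = {
    "drug.adherence",
    "productivity.pct_employed",
    "settings.discontinuation_cum_48wk",
    "cohort.pct_female",
}


def _is_proportion(name: str) -> bool:
    return (
        name in _PROPORTION_NAMES
        or name.split(".")[0] in _PROPORTION_PREFIXES
        or name.startswith("ae.")
        and name.split(".")[-1].startswith("incidence")
    )


def default_owsa_ranges(
    p: ModelParameters,
    rel: float = 0.2,
    include_drug_cost_inputs: bool = False,
    include_checkpoints: bool = False,
) -> list[ParameterRange]:
    """+/-20% ranges over the uncertain base-case parameters.

    Proportions are clipped at 1; parameters whose base is 0 are skipped
    (a relative range is degenerate there).  The administered NHI drug price
    and the dispensing-adherence factor are fixed administrative inputs, and
    the trial SALT distributions are simplex-valued and assessed jointly in
    the PSA, so both groups are excluded from the default tornado sweep;
    flags re-include them (checkpoint components are perturbed individually
    with proportional renormalization of the rest).
    """
    names: list[str] = []
    names += [f"utilities.{s.key}" for s in SALT_STATES]
    if include_drug_cost_inputs:
        names += ["drug.unit_price", "drug.adherence"]
    names += [f"hcru.{s.key}.{a}" for s in SALT_STATES for a in ("drug", "non_drug")]
    for ae in p.adverse_events:
        names += [
            f"ae.{ae.name}.incidence_treated",
            f"ae.{ae.name}.incidence_untreated",
            f"ae.{ae.name}.unit_cost",
        ]
    names += [
        "productivity.pct_employed",
        "productivity.hours_per_week",
        "productivity.hourly_wage",
    ]
    names += [
        f"impairment.{s.key}.{a}"
        for s in SALT_STATES
        for a in ("absenteeism", "presenteeism")
    ]
    names += ["settings.discontinuation_cum_48wk", "cohort.mean_age",
              "cohort.pct_female"]
    if include_checkpoints:
        for arm, cps in (
            ("ritlecitinib", p.checkpoints_treated),
            ("no_treatment", p.checkpoints_untreated),
        ):
            for cp in cps:
                names += [f"checkpoint.{arm}.{cp.week}.{s.key}" for s in SALT_STATES]

    if len(set(names)) != len(names):
        raise ValueError("duplicate parameter names in OWSA range list")
    ranges = []
    for name in names:
        base = get_param(p, name)
        if base == 0:
            continue
        low, high = base * (1 - rel), base * (1 + rel)
        if _is_proportion(name):
            high = min(high, 1.0)
        ranges.append(ParameterRange(name=name, base=base, low=low, high=high))
    return ranges


def owsa_run(
    p: ModelParameters,
    ranges: list[ParameterRange] | None = None,
    perspective: str | None = None,
) -> list[OwsaEntry]:
    """Recompute the ICER at each parameter's bounds; base restored between
    runs (each run perturbs a fresh copy).  Entries sort by spread."""
    if ranges is None:
        ranges = default_owsa_ranges(p)
    seen = set()
    for r in ranges:
        if r.name in seen:
            raise ValueError(f"duplicate parameter in OWSA ranges: {r.name}")
        seen.add(r.name)
    entries = []
    for r in ranges:
        icers = []
        err = None
        for bound in (r.low, r.high):
            q = p.copy()
            try:
                set_param(q, r.name, bound)
                violations = validate_parameters(q)
                if violations:
                    raise ValueError("; ".join(violations))
                icers.append(run_base_case(q, perspective).icer)
            except (ValueError, KeyError) as exc:
                err = str(exc)
                icers.append(math.nan)
        entries.append(
            OwsaEntry(name=r.name, icer_low=icers[0], icer_high=icers[1], error=err)
        )
    entries.sort(key=lambda e: (-(e.spread) if not math.isnan(e.spread) else 1.0))
    return entries


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis


def _draw_beta(rng, mean: float, se: float) -> float:
    if se <= 0 or mean <= 0.0 or mean >= 1.0:
        return mean
    a, b = fit_beta(mean, se)
    return float(rng.beta(a, b))


def _draw_gamma(rng, mean: float, se: float) -> float:
    if se <= 0 or mean <= 0.0:
        return mean
    shape, scale = fit_gamma(mean, se)
    return float(rng.gamma(shape, scale))


def _draw_dirichlet(rng, shares: dict[SaltState, float], se_fraction: float):
    nonzero = {s: x for s, x in shares.items() if x > 0}
    if len(nonzero) < 2 or se_fraction <= 0:
        return dict(shares)
    conc = fit_dirichlet(nonzero, se_fraction)
    draw = rng.dirichlet([conc[s] for s in nonzero])
    out = {s: 0.0 for s in shares}
    out.update({s: float(x) for s, x in zip(nonzero, draw)})
    return out


def sample_parameters(
    p: ModelParameters, rng: np.random.Generator, se_fraction: float = 0.1
) -> ModelParameters:
    """One joint PSA draw of all parameters (SE = ``se_fraction`` x base).

    Draw order is fixed: utilities, drug, HCRU, adverse events, productivity,
    discontinuation, demographics, then checkpoint distributions — so results
    are bit-reproducible for a given seeded generator.
    """
    q = p.copy()
    for s in SALT_STATES:
        u = p.utilities[s]
        q.utilities.values[s] = _draw_beta(rng, u, se_fraction * u)
    q.drug.unit_price = _draw_gamma(rng, p.drug.unit_price,
                                    se_fraction * p.drug.unit_price)
    q.drug.adherence = _draw_beta(rng, p.drug.adherence,
                                  se_fraction * p.drug.adherence)
    for s in SALT_STATES:
        for attr in ("drug", "non_drug"):
            m = getattr(p.hcru[s], attr)
            setattr(q.hcru[s], attr, _draw_gamma(rng, m, se_fraction * m))
    for ae_p, ae_q in zip(p.adverse_events, q.adverse_events):
        ae_q.incidence_treated = _draw_beta(
            rng, ae_p.incidence_treated, se_fraction * ae_p.incidence_treated
        )
        ae_q.incidence_untreated = _draw_beta(
            rng, ae_p.incidence_untreated, se_fraction * ae_p.incidence_untreated
        )
        ae_q.unit_cost = _draw_gamma(rng, ae_p.unit_cost,
                                     se_fraction * ae_p.unit_cost)
    pr, qr = p.productivity, q.productivity
    qr.pct_employed = _draw_beta(rng, pr.pct_employed,
                                 se_fraction * pr.pct_employed)
    qr.hours_per_week = _draw_gamma(rng, pr.hours_per_week,
                                    se_fraction * pr.hours_per_week)
    qr.hourly_wage = _draw_gamma(rng, pr.hourly_wage,
                                 se_fraction * pr.hourly_wage)
    for s in SALT_STATES:
        pair_p, pair_q = pr.impairment[s], qr.impairment[s]
        pair_q.absenteeism = _draw_beta(
            rng, pair_p.absenteeism, se_fraction * pair_p.absenteeism
        )
        pair_q.presenteeism = _draw_beta(
            rng, pair_p.presenteeism, se_fraction * pair_p.presenteeism
        )
    q.settings.discontinuation_cum_48wk = _draw_beta(
        rng,
        p.settings.discontinuation_cum_48wk,
        se_fraction * p.settings.discontinuation_cum_48wk,
    )
    q.cohort.pct_female = _draw_beta(rng, p.cohort.pct_female,
                                     se_fraction * p.cohort.pct_female)
    q.cohort.mean_age = _draw_gamma(rng, p.cohort.mean_age,
                                    se_fraction * p.cohort.mean_age)
    for cps_p, cps_q in (
        (p.checkpoints_treated, q.checkpoints_treated),
        (p.checkpoints_untreated, q.checkpoints_untreated),
    ):
        for cp_p, cp_q in zip(cps_p, cps_q):
            cp_q.shares = _draw_dirichlet(rng, cp_p.shares, se_fraction)
    return q


@dataclass
class PsaResult:
    """Sampled incremental (cost, QALY) pairs from a PSA run."""

    draws: np.ndarray  # (n_iter, 2): delta_cost, delta_qaly
    seed: int
    n_iter: int
    se_fraction: float = 0.1

    @property
    def delta_cost(self) -> np.ndarray:
        return self.draws[:, 0]

    @property
    def delta_qaly(self) -> np.ndarray:
        return self.draws[:, 1]


def run_psa(
    p: ModelParameters,
    n_iter: int,
    seed: int,
    se_fraction: float = 0.1,
    perspective: str | None = None,
) -> PsaResult:
    """Joint PSA: redraw all parameters per iteration, rebuild both arms."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    draws = np.empty((n_iter, 2))
    for i in range(n_iter):
        q = sample_parameters(p, rng, se_fraction)
        res = run_base_case(q, perspective)
        draws[i, 0] = res.delta_cost
        draws[i, 1] = res.delta_qaly
    return PsaResult(draws=draws, seed=seed, n_iter=n_iter,
                     se_fraction=se_fraction)


@dataclass
class CeacCurve:
    wtp: np.ndarray
    probability: np.ndarray


def ceac(r: PsaResult, wtp_grid) -> CeacCurve:
    """Probability of positive net monetary benefit across a WTP grid."""
    wtp = np.asarray(wtp_grid, dtype=float)
    if r.draws.shape[0] == 0:
        raise ValueError("PSA result has no draws")
    nmb = wtp[:, None] * r.delta_qaly[None, :] - r.delta_cost[None, :]
    return CeacCurve(wtp=wtp, probability=(nmb > 0).mean(axis=1))


def psa_summary(r: PsaResult, wtp: float) -> dict:
    """Expected ICER (ratio of mean increments) and P(cost-effective) at WTP."""
    mean_dc = float(r.delta_cost.mean())
    mean_de = float(r.delta_qaly.mean())
    prob = float(((wtp * r.delta_qaly - r.delta_cost) > 0).mean())
    return {
        "mean_delta_cost": mean_dc,
        "mean_delta_qaly": mean_de,
        "mean_icer": mean_dc / mean_de if mean_de != 0 else math.nan,
        "prob_cost_effective": prob,
        "wtp": wtp,
    }
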