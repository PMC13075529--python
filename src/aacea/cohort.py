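"""Markov cohort engine.

Simulates per-cycle occupancy of the modelled cohort over states
(SALT stratum x on/off treatment) plus an absorbing Dead state, on a 12-week
cycle grid.  The trial phase (weeks 0-48) imposes the observed
cross-sectional SALT distributions directly; the extrapolation phase applies

* a constant per-cycle discontinuation hazard for continuing responders,
  derived from the cumulative 48-week discontinuation rate,
* one-step SALT worsening on treatment exit,
* gradual off-treatment worsening (one category per worsening interval;
  default one cycle, calibrated to the model's printed two-year outputs),
* permanent spontaneous remission for untreated patients reaching SALT <= 10
  by week 24, and
* uniform background mortality from the life table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    SALT_STATES,
    ConfigError,
    LifeTable,
    ModelParameters,
    SaltState,
    mixed_cycle_mortality,
)

__all__ = [
    "CohortTrace",
    "per_cycle_probability",
    "worsen_state",
    "build_trial_phase_occupancy",
    "week48_response_split",
    "simulate_arm",
    "ARMS",
]

ARMS = ("ritlecitinib", "no_treatment")

# occupancy vector layout: 0-3 on-treatment by SALT, 4-7 off-treatment, 8 dead
N_STATES = 9
ON = {s: int(s) for s in SALT_STATES}
OFF = {s: 4 + int(s) for s in SALT_STATES}
DEAD = 8


def per_cycle_probability(
    cum_prob: float, duration_weeks: float, cycle_weeks: float
) -> float:
    """Convert a cumulative probability over a duration to a per-cycle one.

    Assumes a constant hazard: ``1 - (1 - cum_prob)**(cycle/duration)``.
    Compounding the result over ``duration/cycle`` cycles recovers
    ``cum_prob`` exactly.
    """
    if not 0.0 <= cum_prob < 1.0:
        raise ValueError(f"cum_prob must be in [0, 1), got {cum_prob}")
    if duration_weeks <= 0 or cycle_weeks <= 0:
        raise ValueError("durations must be positive")
    return 1.0 - (1.0 - cum_prob) ** (cycle_weeks / duration_weeks)


def worsen_state(s: SaltState) -> SaltState:
    """One-step SALT worsening; the worst stratum (>=50) is a fixed point."""
    return SaltState(min(int(s) + 1, int(SaltState.GE50)))


def week48_response_split(dist) -> tuple[float, float]:
    """Split the week-48 treated distribution into continuers/discontinuers.

    Patients at SALT <= 20 at week 48 (responders) continue treatment;
    everyone else discontinues.
    """
    continuing = dist.shares[SaltState.LE10] + dist.shares[SaltState.S11_20]
    return continuing, 1.0 - continuing


def build_trial_phase_occupancy(p: ModelParameters, arm: str) -> np.ndarray:
    """Among-alive occupancy at the five trial-phase cycle boundaries.

    Returns an array of shape (5, 9) for boundaries at weeks 0, 12, 24, 36,
    48.  Week 0 places the whole cohort in SALT >= 50 with the arm's initial
    treatment status.  The week-34 checkpoint is assigned to the week-36
    boundary.  The untreated arm holds its week-24 distribution at weeks 36
    and 48.  The treated week-48 boundary is post-split: responders
    (SALT <= 20) remain on treatment, discontinuers are moved one SALT step
    worse into the off-treatment pool.
    """
    if arm not in ARMS:
        raise ConfigError(f"unknown arm {arm!r}")
    occ = np.zeros((5, N_STATES))
    if arm == "ritlecitinib":
        occ[0, ON[SaltState.GE50]] = 1.0
        for k, week in ((1, 12), (2, 24), (3, 34)):
            cp = p.checkpoint(arm, week)
            for s in SALT_STATES:
                occ[k, ON[s]] = cp.shares[s]
        wk48 = p.checkpoint(arm, 48)
        occ[4, ON[SaltState.LE10]] = wk48.shares[SaltState.LE10]
        occ[4, ON[SaltState.S11_20]] = wk48.shares[SaltState.S11_20]
        # discontinuers worsen one step on exit: 21-49 -> >=50, >=50 stays
        occ[4, OFF[SaltState.GE50]] = (
            wk48.shares[SaltState.S21_49] + wk48.shares[SaltState.GE50]
        )
    else:
        occ[0, OFF[SaltState.GE50]] = 1.0
        wk12 = p.checkpoint(arm, 12)
        wk24 = p.checkpoint(arm, 24)
        for s in SALT_STATES:
            occ[1, OFF[s]] = wk12.shares[s]
            for k in (2, 3, 4):
                occ[k, OFF[s]] = wk24.shares[s]
    return occ


@dataclass
class CohortTrace:
    """Per-cycle cohort occupancy for one arm.

    ``occupancy`` has one row per cycle boundary (week = 12 * index) over the
    nine model states; rows sum to 1.  ``age`` is the cohort mean age at each
    boundary.
    """

    arm: str
    occupancy: np.ndarray  # (T+1, 9)
    week: np.ndarray
    age: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        return 1.0 - self.occupancy[:, DEAD]

    @property
    def on_treatment(self) -> np.ndarray:
        return self.occupancy[:, 0:4].sum(axis=1)

    def salt_occupancy(self) -> np.ndarray:
        """Occupancy by SALT stratum (on + off treatment), shape (T+1, 4)."""
        return self.occupancy[:, 0:4] + self.occupancy[:, 4:8]

    def salt_share(
        self, states, week: float, among_alive: bool = True
    ) -> float:
        """Share in the given SALT strata at the end boundary of the cycle
        covering ``week`` (conditional on being alive by default)."""
        states = [states] if isinstance(states, SaltState) else list(states)
        cycle_weeks = self.week[1] - self.week[0]
        idx = min(int(np.ceil(week / cycle_weeks)), self.n_cycles)
        salt = self.salt_occupancy()[idx]
        total = sum(salt[int(s)] for s in states)
        if among_alive:
            alive = self.alive[idx]
            return float(total / alive) if alive > 0 else float("nan")
        return float(total)

    def to_frame(self):
        import pandas as pd

        cols = {f"on_{s.key}": self.occupancy[:, ON[s]] for s in SALT_STATES}
        cols.update({f"off_{s.key}": self.occupancy[:, OFF[s]] for s in SALT_STATES})
        cols["dead"] = self.occupancy[:, DEAD]
        cols["alive"] = self.alive
        return pd.DataFrame({"week": self.week, "age": self.age, **cols})


def simulate_arm(
    p: ModelParameters,
    arm: str,
    life_table: LifeTable | None = None,
    alive_floor: float = 1e-6,
) -> CohortTrace:
    """Run the cohort simulation for one arm until extinction or the cap age.

    ``life_table`` overrides ``p.life_table``; ``None`` for both disables
    background mortality (useful for among-alive share checks, which are
    mortality-invariant anyway because mortality is uniform across states).
    """
    st = p.settings
    lt = life_table if life_table is not None else p.life_table
    cw = float(st.cycle_length_weeks)
    wpy = st.weeks_per_year
    frac = cw / wpy
    d = per_cycle_probability(st.discontinuation_cum_48wk, 48.0, cw)
    p_w = min(1.0, cw / st.worsening_interval_weeks)
    cap_age = st.cap_age_years

    # Precompute the sex-mixed annual qx indexed by integer age.
    if lt is not None:
        qmix = lt.mixed_qx(p.cohort.pct_female)
        lt_min = lt.min_age
        lt_len = len(qmix)
    else:
        qmix = None

    def q_cycle(age: float) -> float:
        if qmix is None:
            return 0.0
        idx = int(age) - lt_min
        if idx >= lt_len:
            return 1.0
        q = qmix[max(idx, 0)]
        return 1.0 - (1.0 - q) ** frac

    trial = build_trial_phase_occupancy(p, arm)
    rows = [trial[0].copy()]
    age0 = p.cohort.mean_age
    surv = 1.0
    for k in range(1, 5):
        surv *= 1.0 - q_cycle(age0 + (k - 1) * frac)
        row = trial[k] * surv
        row[DEAD] = 1.0 - surv
        rows.append(row)

    treated = arm == "ritlecitinib"
    start_cycle_untreated = max(4, int(np.ceil(st.untreated_worsening_start_week / cw)))
    v = rows[-1].copy()
    t = 4
    while True:
        alive = 1.0 - v[DEAD]
        age = age0 + t * frac
        if alive < alive_floor or age >= cap_age:
            break
        nv = v.copy()
        if treated:
            # continuing responders leave treatment at the constant hazard,
            # worsening one SALT step on exit
            for s in SALT_STATES:
                leaving = nv[ON[s]] * d
                if leaving > 0.0:
                    nv[ON[s]] -= leaving
                    nv[OFF[worsen_state(s)]] += leaving
        worsening_active = treated or t >= start_cycle_untreated
        if worsening_active and p_w > 0.0:
            if not st.worsen_new_discontinuers_same_cycle and treated:
                # shelter this cycle's exits from the natural worsening step
                sheltered = v.copy()
                exits = nv - sheltered
            else:
                exits = None
            # worst-first so mass advances at most one category per cycle;
            # off-treatment <=10 is spontaneous remission and never worsens
            for s in (SaltState.S21_49, SaltState.S11_20):
                pool = nv[OFF[s]] - (exits[OFF[s]] if exits is not None else 0.0)
                move = pool * p_w
                nv[OFF[s]] -= move
                nv[OFF[worsen_state(s)]] += move
        q = q_cycle(age)
        if q > 0.0:
            nv[:DEAD] *= 1.0 - q
            nv[DEAD] = 1.0 - nv[:DEAD].sum()
        rows.append(nv)
        v = nv
        t += 1

    occ = np.vstack(rows)
    weeks = np.arange(occ.shape[0]) * cw
    ages = age0 + weeks / wpy
    return CohortTrace(arm=arm, occupancy=occ, week=weeks, age=ages)
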