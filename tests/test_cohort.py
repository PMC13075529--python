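"""Cohort-engine dynamics: trial phase, extrapolation, mortality."""

import math

import numpy as np
import pytest

from aacea import (
    SaltState,
    make_life_table,
    per_cycle_probability,
    simulate_arm,
    week48_response_split,
    worsen_state,
)
from aacea.cohort import DEAD, OFF, ON, build_trial_phase_occupancy


class TestPerCycleProbability:
    def test_zero_cumulative(self):
        assert per_cycle_probability(0.0, 48, 12) == 0.0

    def test_identity_duration(self):
        assert per_cycle_probability(0.3, 24, 24) == pytest.approx(0.3)

    def test_discontinuation_rate(self):
        # 13.1% over 48 weeks -> 1 - 0.869^(1/4) per 12-week cycle
        assert per_cycle_probability(0.131, 48, 12) == pytest.approx(
            0.0344941, abs=1e-6
        )

    def test_compounding_inverse(self):
        q = per_cycle_probability(0.42, 60, 12)
        assert 1 - (1 - q) ** 5 == pytest.approx(0.42, abs=1e-12)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            per_cycle_probability(1.0, 48, 12)


class TestWorsenState:
    def test_one_step(self):
        assert worsen_state(SaltState.LE10) is SaltState.S11_20
        assert worsen_state(SaltState.S11_20) is SaltState.S21_49

    def test_worst_state_fixed_point(self):
        assert worsen_state(SaltState.GE50) is SaltState.GE50

    def test_three_steps_from_best_reach_worst(self):
        s = SaltState.LE10
        for _ in range(3):
            s = worsen_state(s)
        assert s is SaltState.GE50


class TestTrialPhase:
    def test_week0_all_worst_state(self, base_params_frozen):
        for arm, col in (("ritlecitinib", ON), ("no_treatment", OFF)):
            occ = build_trial_phase_occupancy(base_params_frozen, arm)
            assert occ[0, col[SaltState.GE50]] == 1.0
            assert occ[0].sum() == 1.0

    def test_week12_treated_matches_checkpoint(self, base_params_frozen):
        occ = build_trial_phase_occupancy(base_params_frozen, "ritlecitinib")
        assert occ[1, ON[SaltState.GE50]] == 0.833
        assert occ[1, ON[SaltState.S21_49]] == 0.103
        assert occ[1, ON[SaltState.S11_20]] == 0.008
        assert occ[1, ON[SaltState.LE10]] == 0.056

    def test_untreated_holds_week24_distribution(self, base_params_frozen):
        occ = build_trial_phase_occupancy(base_params_frozen, "no_treatment")
        assert occ[2, OFF[SaltState.LE10]] == 0.015
        np.testing.assert_array_equal(occ[2], occ[3])
        np.testing.assert_array_equal(occ[2], occ[4])

    def test_week48_split(self, base_params_frozen):
        cont, disc = week48_response_split(
            base_params_frozen.checkpoint("ritlecitinib", 48)
        )
        assert cont == pytest.approx(0.355 + 0.136)
        assert disc == pytest.approx(1 - 0.491)
        occ = build_trial_phase_occupancy(base_params_frozen, "ritlecitinib")
        # discontinuers worsened one step into the off-treatment pool
        assert occ[4, OFF[SaltState.GE50]] == pytest.approx(0.364 + 0.145)
        assert occ[4, 0:4].sum() == pytest.approx(0.491)

    @pytest.mark.parametrize("shares, expected", [
        ({SaltState.LE10: 0, SaltState.S11_20: 0, SaltState.S21_49: 0,
          SaltState.GE50: 1.0}, 0.0),
        ({SaltState.LE10: 1.0, SaltState.S11_20: 0, SaltState.S21_49: 0,
          SaltState.GE50: 0}, 1.0),
    ])
    def test_split_extremes(self, base_params_frozen, shares, expected):
        from aacea.parameters import CheckpointDistribution

        cont, _ = week48_response_split(
            CheckpointDistribution(week=48, shares=shares)
        )
        assert cont == expected


def _roll_forward_oracle(p, n_cycles):
    """Independent spreadsheet-style roll-forward of the treated arm after
    week 48 (zero mortality): exits at the constant hazard with one-step
    worsening, then off-treatment worsening including same-cycle exits."""
    d = 1 - (1 - p.settings.discontinuation_cum_48wk) ** (
        p.settings.cycle_length_weeks / 48
    )
    p_w = min(1.0, p.settings.cycle_length_weeks
              / p.settings.worsening_interval_weeks)
    wk48 = p.checkpoint("ritlecitinib", 48).shares
    on = {SaltState.LE10: wk48[SaltState.LE10],
          SaltState.S11_20: wk48[SaltState.S11_20]}
    off = {s: 0.0 for s in SaltState}
    off[SaltState.GE50] = wk48[SaltState.S21_49] + wk48[SaltState.GE50]
    for _ in range(n_cycles):
        for s in list(on):
            ex = on[s] * d
            on[s] -= ex
            off[worsen_state(s)] += ex
        for s in (SaltState.S21_49, SaltState.S11_20):
            move = off[s] * p_w
            off[s] -= move
            off[worsen_state(s)] += move
    return on, off


class TestSimulateArm:
    def test_cycle1_among_alive_matches_week12(self, base_params_frozen):
        tr = simulate_arm(base_params_frozen, "ritlecitinib")
        alive = tr.alive[1]
        shares = tr.salt_occupancy()[1] / alive
        assert shares[int(SaltState.GE50)] == pytest.approx(0.833, abs=1e-12)
        assert shares[int(SaltState.LE10)] == pytest.approx(0.056, abs=1e-12)

    def test_simplex_conservation(self, base_params_frozen):
        for arm in ("ritlecitinib", "no_treatment"):
            tr = simulate_arm(base_params_frozen, arm)
            np.testing.assert_allclose(tr.occupancy.sum(axis=1), 1.0,
                                       atol=1e-9)
            assert (tr.occupancy >= -1e-15).all()
            assert (np.diff(tr.alive) <= 1e-12).all()

    def test_frozen_dynamics_after_week48(self, params):
        # no mortality, no worsening, no discontinuation: occupancy constant
        params.life_table = None
        params.settings.discontinuation_cum_48wk = 0.0
        params.settings.worsening_interval_weeks = 1e12
        tr = simulate_arm(params, "ritlecitinib")
        for t in range(5, tr.n_cycles + 1):
            np.testing.assert_allclose(tr.occupancy[t], tr.occupancy[4],
                                       atol=1e-12)

    def test_no_mortality_keeps_everyone_alive(self, params):
        params.life_table = None
        tr = simulate_arm(params, "no_treatment")
        np.testing.assert_allclose(tr.alive, 1.0, atol=1e-12)

    def test_certain_mortality_kills_in_one_cycle(self, params):
        params.life_table = make_life_table(makeham_a=1.0, gompertz_b=0.0,
                                            gompertz_c=0.0,
                                            sex_ratio_adjust=1.0)
        tr = simulate_arm(params, "ritlecitinib")
        assert tr.alive[1] == pytest.approx(0.0, abs=1e-12)

    def test_matches_roll_forward_oracle_at_week108(self, params):
        params.life_table = None
        tr = simulate_arm(params, "ritlecitinib")
        on, off = _roll_forward_oracle(params, 5)  # boundaries 4 -> 9
        occ = tr.occupancy[9]
        for s in (SaltState.LE10, SaltState.S11_20):
            assert occ[ON[s]] == pytest.approx(on[s], abs=1e-9)
        for s in SaltState:
            assert occ[OFF[s]] == pytest.approx(off[s], abs=1e-9)
        le20 = tr.salt_share([SaltState.LE10, SaltState.S11_20], week=104)
        oracle_le20 = (on[SaltState.LE10] + on[SaltState.S11_20]
                       + off[SaltState.LE10] + off[SaltState.S11_20])
        assert le20 == pytest.approx(oracle_le20, abs=1e-9)

    def test_on_treatment_pool_closed_form(self, base_params_frozen):
        # pool(t) = continuing * survival(t) * (1-d)^(t-4) for t >= 4
        p = base_params_frozen
        tr = simulate_arm(p, "ritlecitinib")
        d = per_cycle_probability(p.settings.discontinuation_cum_48wk, 48,
                                  p.settings.cycle_length_weeks)
        cont, _ = week48_response_split(p.checkpoint("ritlecitinib", 48))
        for t in range(4, min(tr.n_cycles, 60)):
            expected = cont * tr.alive[t] * (1 - d) ** (t - 4)
            assert tr.on_treatment[t] == pytest.approx(expected, rel=1e-9)

    def test_among_alive_shares_mortality_invariant(self, params):
        # uniform mortality cancels out of conditional SALT shares
        light = params.copy()
        light.life_table = make_life_table()
        heavy = params.copy()
        heavy.life_table = make_life_table(makeham_a=0.02)
        for arm in ("ritlecitinib", "no_treatment"):
            a = simulate_arm(light, arm)
            b = simulate_arm(heavy, arm)
            n = min(a.n_cycles, b.n_cycles, 100)
            sa = a.salt_occupancy()[:n] / a.alive[:n, None]
            sb = b.salt_occupancy()[:n] / b.alive[:n, None]
            np.testing.assert_allclose(sa, sb, atol=1e-9)

    def test_spontaneous_remission_is_permanent(self, base_params_frozen):
        tr = simulate_arm(base_params_frozen, "no_treatment")
        le10 = tr.occupancy[:, OFF[SaltState.LE10]]
        among_alive = le10 / tr.alive
        assert (np.diff(among_alive[2:]) >= -1e-12).all()
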