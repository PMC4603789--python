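"""Hazard recovery from landmark survival, competing-risk split,
arm blending, annual discretization, and intervention scenarios."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcstates.hazards import (
    PiecewiseHazard,
    Scenario,
    SurvivalSummary,
    TreatmentArm,
    annual_transition_probs,
    apply_scenario,
    apply_scenarios,
    arm_hazard,
    blend_arms,
    build_hazard_profile,
    decompose_competing_risks,
    hazard_from_survival,
)
from pcstates.states import State

fractions = st.floats(min_value=1e-3, max_value=1.0)


def _arm(os5, os10, pfs5, pfs10, weight=1.0, label="arm", hormonal=False):
    return TreatmentArm(
        label=label,
        weight=weight,
        hormonal=hormonal,
        survival=SurvivalSummary(os5=os5, os10=os10, pfs5=pfs5, pfs10=pfs10),
    )


class TestHazardFromSurvival:
    @pytest.mark.parametrize(
        "s5, s10, expected",
        [
            # nmCRPC overall survival: near-total 10-year mortality
            # produces an extreme second-segment rate (~1.03/yr).
            ((0.350), (0.002), (0.20996442489973557, 1.0329571947847027)),
            # localized watchful waiting, overall survival
            ((0.910), (0.690), (0.018862135894248257, 0.05535060038391813)),
            ((1.0), (1.0), (0.0, 0.0)),  # no events, zero hazard
        ],
    )
    def test_closed_form(self, s5, s10, expected):
        h1, h2 = hazard_from_survival(s5, s10)
        assert h1 == pytest.approx(expected[0], abs=1e-12)
        assert h2 == pytest.approx(expected[1], abs=1e-12)

    def test_reintegrates_to_landmarks(self):
        # numerical re-integration of the piecewise survival curve
        s5, s10 = 0.350, 0.002
        h1, h2 = hazard_from_survival(s5, s10)
        grid = np.linspace(0, 10, 100001)
        rate = np.where(grid[:-1] < 5.0, h1, h2)
        cumhaz = np.concatenate([[0.0], np.cumsum(rate * np.diff(grid))])
        surv = np.exp(-cumhaz)
        assert surv[np.searchsorted(grid, 5.0)] == pytest.approx(s5, rel=1e-4)
        assert surv[-1] == pytest.approx(s10, rel=1e-3)

    @pytest.mark.parametrize(
        "s5, s10, match",
        [
            (0.0, 0.0, "5-year"),
            (0.5, 0.0, "10-year"),
            (1.2, 0.5, "5-year"),
            (0.4, 0.6, "non-increasing"),
        ],
    )
    def test_invalid_landmarks_rejected(self, s5, s10, match):
        with pytest.raises(ValueError, match=match):
            hazard_from_survival(s5, s10)

    @given(s5=fractions, ratio=st.floats(min_value=1e-3, max_value=1.0))
    @settings(max_examples=200, derandomize=True)
    def test_round_trip_property(self, s5, ratio):
        s10 = s5 * ratio
        h1, h2 = hazard_from_survival(s5, s10)
        assert math.exp(-5 * h1) == pytest.approx(s5, rel=1e-12)
        assert math.exp(-5 * h1 - 5 * h2) == pytest.approx(s10, rel=1e-12)

    @given(s5=fractions, ratio=st.floats(min_value=1e-3, max_value=1.0),
           bump=st.floats(min_value=1.0, max_value=2.0))
    @settings(max_examples=100, derandomize=True)
    def test_monotonicity_in_landmarks(self, s5, ratio, bump):
        # raising a survival landmark never raises any derived hazard
        s10 = s5 * ratio
        h1, h2 = hazard_from_survival(s5, s10)
        h1b, _ = hazard_from_survival(min(s5 * bump, 1.0), min(s10, min(s5 * bump, 1.0)))
        assert h1b <= h1 + 1e-12
        _, h2b = hazard_from_survival(s5, min(s10 * bump, s5))
        assert h2b <= h2 + 1e-12


class TestCompetingRisks:
    @pytest.mark.parametrize(
        "h_pfs, h_os, expected",
        [
            # nmCRPC first segment: PFS event rate minus death rate
            ((0.3028255465259551), (0.20996442489973557),
             (0.09286112162621954, 0.20996442489973557)),
            # localized radiation-only first segment
            ((0.26941472959332186), (0.023306763251190302),
             (0.24610796634213156, 0.023306763251190302)),
            ((0.1), (0.1), (0.0, 0.1)),  # all PFS events are deaths
            ((0.05), (0.2), (0.0, 0.2)),  # crossed curves clamp at zero
        ],
    )
    def test_decomposition(self, h_pfs, h_os, expected):
        assert decompose_competing_risks(h_pfs, h_os) == pytest.approx(expected, abs=1e-12)

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            decompose_competing_risks(-0.1, 0.1)


class TestBlending:
    def test_single_arm_identity(self):
        arm = _arm(0.9, 0.8, 0.7, 0.6)
        assert blend_arms([arm]) == arm_hazard(arm)

    def test_equal_weight_midpoint(self):
        a = PiecewiseHazard(progression=(0, 0, 0), death=(0.02, 0.02, 0.02))
        b = PiecewiseHazard(progression=(0, 0, 0), death=(0.04, 0.04, 0.04))
        arms = [
            _arm(math.exp(-5 * 0.02), math.exp(-10 * 0.02), 1.0, 1.0, weight=0.5),
            _arm(math.exp(-5 * 0.04), math.exp(-10 * 0.04), 1.0, 1.0, weight=0.5),
        ]
        blended = blend_arms(arms)
        assert blended.death[0] == pytest.approx(0.03, abs=1e-12)
        for arm, single in zip(arms, (a, b)):
            assert arm_hazard(arm).death[0] == pytest.approx(single.death[0], abs=1e-12)

    def test_localized_arms_blend_to_mean_death_hazard(self):
        from pcstates.config import load_rate_table

        arms = load_rate_table()[State.LOCALIZED]
        blended = blend_arms(arms)
        mean_h1 = np.mean([hazard_from_survival(a.survival.os5, a.survival.os10)[0] for a in arms])
        assert blended.death[0] == pytest.approx(mean_h1, abs=1e-12)

    def test_blend_within_arm_envelope(self):
        arms = [
            _arm(0.9, 0.7, 0.6, 0.4, weight=0.3),
            _arm(0.7, 0.5, 0.5, 0.2, weight=0.7),
        ]
        blended = blend_arms(arms)
        singles = [arm_hazard(a) for a in arms]
        for i in range(3):
            for risk in ("progression", "death"):
                vals = [getattr(h, risk)[i] for h in singles]
                assert min(vals) - 1e-12 <= getattr(blended, risk)[i] <= max(vals) + 1e-12

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            blend_arms([_arm(0.9, 0.8, 0.7, 0.6, weight=0.4)])


class TestAnnualProbs:
    def test_competing_risk_closed_form(self):
        hz = PiecewiseHazard(
            progression=(0.09286112162621954,) * 3, death=(0.20996442489973557,) * 3
        )
        p_prog, p_die, p_stay = annual_transition_probs(hz, tenure=2)
        assert p_prog == pytest.approx(0.08011878480792044, abs=1e-12)
        assert p_die == pytest.approx(0.18115325640338734, abs=1e-12)
        assert p_prog + p_die + p_stay == pytest.approx(1.0, abs=1e-12)

    def test_matches_monte_carlo_exponential_clocks(self):
        # independent verification: competing exponential clocks sampled
        # directly, agreement within 3 binomial SE at n = 10^6
        h_p, h_d = 0.09286112162621954, 0.20996442489973557
        hz = PiecewiseHazard(progression=(h_p,) * 3, death=(h_d,) * 3)
        p_prog, p_die, _ = annual_transition_probs(hz, tenure=0)
        rng = np.random.default_rng(20150101)
        n = 1_000_000
        t_prog = rng.exponential(1.0 / h_p, n)
        t_die = rng.exponential(1.0 / h_d, n)
        first = np.minimum(t_prog, t_die)
        mc_prog = ((first < 1.0) & (t_prog < t_die)).mean()
        mc_die = ((first < 1.0) & (t_die <= t_prog)).mean()
        for mc, p in ((mc_prog, p_prog), (mc_die, p_die)):
            se = math.sqrt(p * (1 - p) / n)
            assert abs(mc - p) < 3 * se

    def test_zero_hazards_stay(self):
        hz = PiecewiseHazard(progression=(0, 0, 0), death=(0, 0, 0))
        assert annual_transition_probs(hz, 0) == (0.0, 0.0, 1.0)

    def test_single_risk_reduces_to_exponential(self):
        h = 0.37
        hz = PiecewiseHazard(progression=(0, 0, 0), death=(h, h, h))
        p_prog, p_die, _ = annual_transition_probs(hz, 1)
        assert p_prog == 0.0
        assert p_die == pytest.approx(1 - math.exp(-h), abs=1e-12)

    def test_tenure_selects_segment(self):
        hz = PiecewiseHazard(progression=(0.1, 0.2, 0.3), death=(0, 0, 0))
        assert hz.rates_at(4.9)[0] == 0.1
        assert hz.rates_at(5.0)[0] == 0.2
        assert hz.rates_at(10.0)[0] == 0.3
        assert hz.rates_at(25.0)[0] == 0.3


@pytest.fixture(scope="module")
def profile():
    return {
        State.NMCRPC: PiecewiseHazard(progression=(0.1, 0.2, 0.2), death=(0.2, 1.0, 1.0)),
        State.MCRPC_SYMPTOMATIC: PiecewiseHazard(progression=(0.9, 0.9, 0.9), death=(0.6, 0.7, 0.7)),
    }


class TestScenarios:

    def test_identity_without_improvement(self, profile):
        sc = Scenario(name="null", states={State.NMCRPC}, introduction_year=2015)
        assert apply_scenario(profile, sc, 2016) == dict(profile)

    def test_pfs_improvement_scales_progression_only(self, profile):
        sc = Scenario(name="nm", states={State.NMCRPC}, pfs_improvement=0.25,
                      introduction_year=2015)
        out = apply_scenario(profile, sc, 2016)
        assert out[State.NMCRPC].progression[0] == pytest.approx(0.1 * 0.8, abs=1e-15)
        assert out[State.NMCRPC].death == profile[State.NMCRPC].death
        assert out[State.MCRPC_SYMPTOMATIC] == profile[State.MCRPC_SYMPTOMATIC]
        # untouched before the introduction year
        assert apply_scenario(profile, sc, 2014) == dict(profile)
        # original never mutated
        assert profile[State.NMCRPC].progression[0] == 0.1

    def test_combined_scenario_stacks_disjoint_targets(self, profile):
        nm = Scenario(name="nm", states={State.NMCRPC}, pfs_improvement=0.25,
                      introduction_year=2015)
        m = Scenario(name="m", states={State.MCRPC_SYMPTOMATIC}, os_improvement=0.25,
                     introduction_year=2015)
        out = apply_scenarios(profile, [nm, m], 2016)
        assert out[State.NMCRPC].progression[0] == pytest.approx(0.08, abs=1e-15)
        assert out[State.MCRPC_SYMPTOMATIC].death[0] == pytest.approx(0.6 * 0.8, abs=1e-15)

    def test_hazard_scale_semantics(self, profile):
        sc = Scenario(name="nm", states={State.NMCRPC}, pfs_improvement=0.25,
                      introduction_year=2015, semantics="hazard_scale")
        out = apply_scenario(profile, sc, 2016)
        assert out[State.NMCRPC].progression[0] == pytest.approx(0.075, abs=1e-15)

    def test_unknown_target_state_rejected(self, profile):
        sc = Scenario(name="bad", states={State.LOCALIZED}, pfs_improvement=0.1)
        with pytest.raises(KeyError):
            apply_scenario(profile, sc, 2016)

    @pytest.mark.parametrize("imp_a, imp_b", [(0.5, 0.25), (0.25, 0.0)])
    def test_larger_pfs_gain_never_raises_progression_prob(self, profile, imp_a, imp_b):
        out = {}
        for imp in (imp_a, imp_b):
            sc = Scenario(name="nm", states={State.NMCRPC}, pfs_improvement=imp,
                          introduction_year=2015)
            out[imp] = apply_scenario(profile, sc, 2016)[State.NMCRPC]
        for tenure in (0, 5, 10, 20):
            pa = annual_transition_probs(out[imp_a], tenure)[0]
            pb = annual_transition_probs(out[imp_b], tenure)[0]
            assert pa <= pb + 1e-15


class TestProfileBuild:
    def test_terminal_state_progression_zeroed(self):
        from pcstates.config import load_rate_table

        profile = build_hazard_profile(load_rate_table())
        assert profile[State.MCRPC_POSTCHEMO].progression == (0.0, 0.0, 0.0)
        assert profile[State.MCRPC_POSTCHEMO].death[0] > 0.8  # 5-yr OS 0.016

    def test_crossed_curves_clamp_progression(self):
        # nmCRPC: printed 10-yr PFS (0.081) exceeds 10-yr OS (0.002),
        # so the second-segment progression hazard clamps at zero.
        from pcstates.config import load_rate_table

        profile = build_hazard_profile(load_rate_table())
        assert profile[State.NMCRPC].progression[1] == 0.0
        assert profile[State.NMCRPC].death[1] == pytest.approx(1.0329571947847027, abs=1e-12)

    def test_max_hazard_cap(self):
        from pcstates.config import load_rate_table

        profile = build_hazard_profile(load_rate_table(), max_hazard=0.5)
        assert profile[State.NMCRPC].death[1] == 0.5
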