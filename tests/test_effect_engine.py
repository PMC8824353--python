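"""Scenario -> hazard trajectory -> LE gain, checked against an
independent brute-force life table written here (plain loops, no numpy)."""

import math

import pytest

from foodspan import (
    CurvePoint,
    DietChangeScenario,
    DietProfile,
    DoseResponseCurve,
    FoodGroup,
    MortalitySchedule,
    combined_hr,
    gain_in_le,
    hazard_trajectory,
    per_group_gains,
    preset_diet,
    ramp_fraction,
)
from foodspan.food_model import EnergyGateError

G = FoodGroup


def brute_force_le(rates, start_idx):
    """Independent oracle: plain-Python period life table over a rate list.

    rates[i] is the mortality rate at age start+i; the last entry closes
    the table as an open interval contributing survivors/rate.
    """
    l, years = 1.0, 0.0
    for m in rates[start_idx:-1]:
        q = min(m / (1 + 0.5 * m), 1.0)
        years += l * (1 - q) + l * q * 0.5
        l *= 1 - q
    years += l / rates[-1]
    return years


def single_curve_set(group=G.LEGUMES, hr_plateau=0.8, dose1=200.0):
    """One active curve; every other group neutral-like via unchanged intake."""
    pts = (
        CurvePoint(0.0, 1.0, 1.0, 1.0),
        CurvePoint(dose1, hr_plateau, hr_plateau, hr_plateau),
    )
    curves = {group: DoseResponseCurve(group, pts)}
    for g in (G.WHITE_MEAT, G.ADDED_OILS):
        curves[g] = DoseResponseCurve(g, (), neutral=True)
    return curves


class TestRamp:
    def test_twenty_percent_after_two_years(self):
        assert ramp_fraction(2, 10) == pytest.approx(0.2)

    def test_zero_at_onset_and_saturation(self):
        assert ramp_fraction(0, 10) == 0.0
        assert ramp_fraction(37, 10) == 1.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            ramp_fraction(-1, 10)


class TestHazardTrajectory:
    def test_null_effect(self):
        traj = hazard_trajectory(1.0, 20, 10, 110)
        assert all(v == 1.0 for v in traj.values())

    def test_first_year_midpoint(self):
        traj = hazard_trajectory(0.8, 20, 10, 110)
        assert traj[20] == pytest.approx(1 + 0.05 * (-0.2))  # t = 0.5 -> f = 0.05

    def test_post_saturation(self):
        traj = hazard_trajectory(0.8, 20, 10, 110)
        assert traj[40] == pytest.approx(0.8)
        assert traj[30] == pytest.approx(0.8)  # t = 10.5 >= T

    def test_covers_change_age_through_max_age(self):
        traj = hazard_trajectory(0.9, 60, 10, 110)
        assert set(traj) == set(range(60, 111))


class TestCombinedHr:
    def test_identical_diets(self, curves, tw):
        assert combined_hr(curves, tw, tw) == pytest.approx(1.0)

    def test_product_rule(self):
        curves = single_curve_set(G.LEGUMES, 0.9)
        curves.update(single_curve_set(G.NUTS, 0.9, dose1=25.0))
        tw = preset_diet("TW")
        target = tw.replace("t", legumes=200, nuts=25)
        assert combined_hr(curves, tw, target) == pytest.approx(0.81)

    def test_all_neutral_gives_unity(self, tw, od):
        curves = {g: DoseResponseCurve(g, (), neutral=True) for g in FoodGroup}
        assert combined_hr(curves, tw, od) == pytest.approx(1.0)

    def test_missing_curve_for_changed_group_rejected(self, tw, od):
        with pytest.raises(KeyError, match="legumes"):
            combined_hr({}, tw, od, groups=[G.LEGUMES])


class TestGain:
    def test_null_change_zero_gain(self, schedule, curves, densities, tw):
        sc = DietChangeScenario(tw, tw, change_age=20)
        est = gain_in_le(sc, schedule, curves, densities)
        assert est.gain == 0.0

    def test_matches_brute_force_oracle_instant_effect(self, densities):
        """Constant-rate schedule, near-instant ramp: the engine's gain must
        match two brute-force life tables computed independently."""
        m0, hr = 0.01, 0.8
        max_age = 300
        sched = MortalitySchedule("f", "t", max_age, {a: m0 for a in range(max_age + 1)})
        curves = single_curve_set(G.LEGUMES, hr)
        tw = preset_diet("TW")
        target = tw.replace("t", legumes=200)
        T = 1e-9  # effectively instant
        sc = DietChangeScenario(tw, target, change_age=20, time_to_full_effect=T)
        est = gain_in_le(sc, sched, curves, densities)
        base_rates = [m0] * (max_age + 1)
        mod_rates = [m0] * 20 + [m0 * hr] * (max_age + 1 - 20)
        expected = brute_force_le(mod_rates, 20) - brute_force_le(base_rates, 20)
        assert est.gain == pytest.approx(expected, abs=1e-9)

    def test_matches_brute_force_oracle_with_ramp(self, schedule, densities):
        curves = single_curve_set(G.LEGUMES, 0.85)
        tw = preset_diet("TW")
        target = tw.replace("t", legumes=200)
        sc = DietChangeScenario(tw, target, change_age=40, time_to_full_effect=10)
        est = gain_in_le(sc, schedule, curves, densities)
        rates = [schedule.m[a] for a in range(0, schedule.max_age + 1)]
        mod = list(rates)
        for a in range(40, schedule.max_age + 1):
            f = min((a - 40 + 0.5) / 10, 1.0)
            mod[a] = rates[a] * (1 + f * (0.85 - 1))
        expected = brute_force_le(mod, 40) - brute_force_le(rates, 40)
        assert est.gain == pytest.approx(expected, abs=1e-9)

    def test_energy_gate_refusal(self, schedule, curves, densities, tw):
        tiny = DietProfile("tiny", {g: 0.0 for g in FoodGroup})
        sc = DietChangeScenario(tw, tiny, change_age=20)
        with pytest.raises(EnergyGateError, match="estimates not reported"):
            gain_in_le(sc, schedule, curves, densities)

    @pytest.mark.parametrize("pair", [(5, 10), (10, 30), (30, 50)])
    def test_gain_decreases_with_longer_time_to_effect(
        self, schedule, curves, densities, tw, od, pair
    ):
        t_fast, t_slow = pair
        gains = []
        for T in (t_fast, t_slow):
            sc = DietChangeScenario(tw, od, change_age=60, time_to_full_effect=T)
            gains.append(gain_in_le(sc, schedule, curves, densities).gain)
        assert gains[0] > gains[1] > 0

    def test_gain_decreases_with_change_age(self, schedule, curves, densities, tw, od):
        gains = []
        for age in (20, 40, 60, 80):
            sc = DietChangeScenario(tw, od, change_age=age)
            gains.append(gain_in_le(sc, schedule, curves, densities).gain)
        assert gains == sorted(gains, reverse=True)
        assert gains[-1] > 0

    def test_reciprocal_swap_scales_rates_after_saturation(self, schedule, curves, tw, od):
        """Swapping baseline and target gives the reciprocal combined HR, so
        the two modified rate arrays are reciprocal-scaled once the ramp
        saturates (assertable on rates, not on LE)."""
        h_fwd = combined_hr(curves, tw, od)
        h_bwd = combined_hr(curves, od, tw)
        assert h_fwd * h_bwd == pytest.approx(1.0)
        fwd = hazard_trajectory(h_fwd, 20, 10, 110)
        bwd = hazard_trajectory(h_bwd, 20, 10, 110)
        for a in range(31, 111):  # ramp saturated
            assert fwd[a] * bwd[a] == pytest.approx(h_fwd * h_bwd)


class TestPerGroup:
    def test_null_change_all_zeros(self, schedule, curves, densities, tw):
        sc = DietChangeScenario(tw, tw, change_age=20)
        gains = per_group_gains(sc, schedule, curves, densities)
        assert all(v == 0.0 for v in gains.values())

    def test_neutral_groups_report_zero(self, schedule, curves, densities, tw, od):
        sc = DietChangeScenario(tw, od, change_age=20)
        gains = per_group_gains(sc, schedule, curves, densities)
        assert gains[G.WHITE_MEAT] == 0.0
        assert gains[G.ADDED_OILS] == 0.0

    def test_single_group_change_equals_total(self, schedule, curves, densities, tw):
        target = tw.replace("t", legumes=200)
        sc = DietChangeScenario(tw, target, change_age=20)
        gains = per_group_gains(sc, schedule, curves, densities)
        total = gain_in_le(sc, schedule, curves, densities).gain
        assert gains[G.LEGUMES] == pytest.approx(total)
        assert sum(v for g, v in gains.items() if g is not G.LEGUMES) == 0.0

    def test_near_additivity(self, schedule, curves, densities, tw, od):
        """Per-group gains nearly but not exactly sum to the joint total."""
        sc = DietChangeScenario(tw, od, change_age=20)
        gains = per_group_gains(sc, schedule, curves, densities)
        total = gain_in_le(sc, schedule, curves, densities).gain
        s = sum(gains.values())
        assert s != total  # life-table gains are not additive
        assert abs(s - total) / total < 0.10
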