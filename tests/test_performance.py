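"""Race predictions: carbohydrate budget, the wall, fueling, pacing."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq

from runfuel import (
    DomainError,
    FuelingPlan,
    PlanError,
    RacePlan,
    RunnerProfile,
    cho_energy_required,
    delta_muscle_glycogen,
    distance_to_wall,
    intensity_from_speed,
    min_leg_fraction,
    pacing_penalty,
    predict,
    required_exogenous_cho,
    resolve_intensity,
    specific_reserve,
)

MARATHON = 42.195
PLAN_342 = RacePlan(distance=MARATHON, finish_time=3.7)


class TestRacePlan:
    def test_exactly_one_target_required(self):
        with pytest.raises(PlanError):
            RacePlan(distance=MARATHON)
        with pytest.raises(PlanError):
            RacePlan(distance=MARATHON, finish_time=3.7, speed=12.0)

    def test_resolution_order_time_then_speed_then_intensity(self, partition):
        runner = RunnerProfile(vo2max=55.0)
        by_time = resolve_intensity(runner, PLAN_342, partition)
        by_speed = resolve_intensity(
            runner, RacePlan(distance=MARATHON, speed=MARATHON / 3.7), partition
        )
        by_i = resolve_intensity(
            runner, RacePlan(distance=MARATHON, intensity=by_time), partition
        )
        assert by_time == pytest.approx(by_speed, rel=1e-12)
        assert by_i == pytest.approx(by_time, rel=1e-12)


class TestChoEnergyRequired:
    def test_fig2_walkthrough_vo2max55(self, partition):
        runner = RunnerProfile(mass=75.0, vo2max=55.0)
        total, per_kg = cho_energy_required(runner, PLAN_342, partition)
        assert per_kg == pytest.approx(20.0, abs=2.0)
        assert total == pytest.approx(1500.0, abs=150.0)

    def test_zero_when_no_carbohydrate_burned(self):
        from runfuel.partition import PartitionAnchor, fit_partition

        fat_only = fit_partition(
            [PartitionAnchor(i, 0.0) for i in (0.3, 0.6, 0.9)]
        )
        runner = RunnerProfile(vo2max=55.0)
        total, _ = cho_energy_required(runner, PLAN_342, fat_only)
        assert total == 0.0

    def test_linear_in_distance(self, partition):
        runner = RunnerProfile(vo2max=55.0)
        _, per_kg_1 = cho_energy_required(
            runner, RacePlan(distance=10.0, intensity=0.7), partition
        )
        _, per_kg_2 = cho_energy_required(
            runner, RacePlan(distance=20.0, intensity=0.7), partition
        )
        assert per_kg_2 == pytest.approx(2 * per_kg_1, rel=1e-12)


class TestDistanceToWall:
    def test_typical_male_brackets_mile_21(self, partition, fig3_male):
        # typical male build, liver maxed: the wall falls around mile 21
        # (33.8 km) across the 80-95% intensity range
        d_lo = distance_to_wall(fig3_male, 0.95, partition)
        d_hi = distance_to_wall(fig3_male, 0.80, partition)
        assert d_lo <= 33.8 <= d_hi

    def test_easy_pace_outlasts_marathon_for_all_builds(self, partition):
        for legs in (0.15, 0.20, 0.25):
            for dens_kcal in (80.0, 112.0, 144.0):
                profile = RunnerProfile(
                    leg_muscle_fraction=legs,
                    muscle_glycogen_density=dens_kcal / 0.72,
                    liver_glycogen_density=500.0,
                )
                assert distance_to_wall(profile, 0.55, partition) > MARATHON

    def test_decreasing_in_intensity(self, partition, fig3_male):
        grid = np.linspace(0.5, 1.0, 40)
        vals = [distance_to_wall(fig3_male, float(i), partition) for i in grid]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_linear_in_glycogen_densities(self, partition):
        base = RunnerProfile(
            muscle_glycogen_density=80.0, liver_glycogen_density=200.0
        )
        doubled = RunnerProfile(
            muscle_glycogen_density=160.0, liver_glycogen_density=400.0
        )
        assert distance_to_wall(doubled, 0.8, partition) == pytest.approx(
            2 * distance_to_wall(base, 0.8, partition), rel=1e-12
        )

    def test_mass_invariant(self, partition):
        light = RunnerProfile(mass=50.0)
        heavy = RunnerProfile(mass=90.0)
        assert distance_to_wall(light, 0.8, partition) == pytest.approx(
            distance_to_wall(heavy, 0.8, partition)
        )

    def test_infinite_when_fat_only(self):
        from runfuel.partition import PartitionAnchor, fit_partition

        fat_only = fit_partition([PartitionAnchor(i, 0.0) for i in (0.3, 0.6, 0.9)])
        assert distance_to_wall(RunnerProfile(), 0.8, fat_only) == math.inf

    def test_intensity_recoverable_by_root_finding(self, partition, fig3_male):
        # parameter recovery: invert d_wall(i) for a synthetic runner
        i_star = 0.82
        target = distance_to_wall(fig3_male, i_star, partition)
        recovered = brentq(
            lambda i: distance_to_wall(fig3_male, i, partition) - target,
            0.5,
            1.0,
            xtol=1e-12,
        )
        assert recovered == pytest.approx(i_star, abs=1e-6)


class TestMinLegFraction:
    def test_vo2max55_maximal_loading(self, partition):
        frac = min_leg_fraction(RunnerProfile(vo2max=55.0), PLAN_342, 144.0, partition)
        assert frac * 100 == pytest.approx(7.5, abs=1.0)

    def test_vo2max45_maximal_loading(self, partition):
        frac = min_leg_fraction(RunnerProfile(vo2max=45.0), PLAN_342, 144.0, partition)
        assert frac * 100 == pytest.approx(12.5, abs=1.5)

    def test_floor_at_zero_when_liver_suffices(self, partition):
        frac = min_leg_fraction(
            RunnerProfile(vo2max=55.0),
            RacePlan(distance=5.0, intensity=0.6),
            144.0,
            partition,
        )
        assert frac == 0.0


class TestDeltaMuscleGlycogen:
    def test_fueling_monotonically_reduces_depletion(self, partition, typical_male):
        unfueled = delta_muscle_glycogen(typical_male, PLAN_342, None, partition)
        fueled = delta_muscle_glycogen(
            typical_male, PLAN_342, FuelingPlan(100.0), partition
        )
        assert unfueled.kcal_per_kg > fueled.kcal_per_kg

    def test_station_schedule_offset(self, partition):
        # 20 g at each of 4, 8, ..., 28 km over a 30-km race: 140 g total,
        # reducing depletion by 140*4/(M*f_legs) kcal/kg vs unfueled
        runner = RunnerProfile(mass=70.0, vo2max=55.0)
        plan = RacePlan(distance=30.0, intensity=0.75)
        fueling = FuelingPlan.every(20.0, 4.0, 30.0)
        assert fueling.total_exogenous_cho_g == pytest.approx(140.0)
        unfueled = delta_muscle_glycogen(runner, plan, None, partition)
        fueled = delta_muscle_glycogen(runner, plan, fueling, partition)
        expected_offset = 140.0 * 4.0 / (70.0 * 0.214)
        assert unfueled.kcal_per_kg - fueled.kcal_per_kg == pytest.approx(
            expected_offset, rel=1e-12
        )

    def test_depletion_beyond_store_flagged(self, partition):
        runner = RunnerProfile(vo2max=45.0, muscle_glycogen_density=110.0)
        plan = RacePlan(distance=MARATHON, finish_time=3.7)
        result = delta_muscle_glycogen(runner, plan, None, partition)
        assert result.exceeds_stored
        # consistent with hitting the wall mid-race
        i = resolve_intensity(runner, plan, partition)
        assert distance_to_wall(runner, i, partition) < MARATHON

    def test_zero_leg_fraction_rejected(self, partition):
        runner = RunnerProfile(leg_muscle_fraction=0.0)
        with pytest.raises(DomainError):
            delta_muscle_glycogen(runner, PLAN_342, None, partition)

    def test_schedule_must_sum_to_total(self):
        with pytest.raises(PlanError):
            FuelingPlan(50.0, ((10.0, 20.0), (20.0, 20.0)))


class TestRequiredExogenous:
    def test_zero_when_wall_beyond_distance(self, partition):
        runner = RunnerProfile(vo2max=55.0, muscle_glycogen_density=200.0,
                               liver_glycogen_density=500.0)
        plan = RacePlan(distance=MARATHON, intensity=0.6)
        i = resolve_intensity(runner, plan, partition)
        assert distance_to_wall(runner, i, partition) >= MARATHON
        assert required_exogenous_cho(runner, plan, partition) == 0.0

    def test_deficit_oracle(self, partition):
        # independent hand evaluation of the deficit for a depleting plan
        runner = RunnerProfile(mass=75.0, vo2max=45.0)
        i = resolve_intensity(runner, PLAN_342, partition)
        per_kg = MARATHON * partition.f_cho(i)
        deficit_kcal = 75.0 * (per_kg - specific_reserve(runner))
        assert deficit_kcal > 0
        assert required_exogenous_cho(runner, PLAN_342, partition) == pytest.approx(
            deficit_kcal / 4.0, rel=1e-12
        )

    def test_scales_linearly_with_mass(self, partition):
        g60 = required_exogenous_cho(
            RunnerProfile(mass=60.0, vo2max=45.0), PLAN_342, partition
        )
        g120 = required_exogenous_cho(
            RunnerProfile(mass=120.0, vo2max=45.0), PLAN_342, partition
        )
        assert g120 == pytest.approx(2 * g60, rel=1e-12)

    def test_boundary_consistency_with_wall(self, partition):
        # exactly at the wall the required intake crosses zero
        runner = RunnerProfile(vo2max=55.0)
        i_wall = brentq(
            lambda i: distance_to_wall(runner, i, partition) - MARATHON, 0.4, 1.0
        )
        at_wall = RacePlan(distance=MARATHON, intensity=i_wall)
        assert required_exogenous_cho(runner, at_wall, partition) == pytest.approx(
            0.0, abs=1e-6
        )
        slower = RacePlan(distance=MARATHON, intensity=i_wall - 1e-3)
        faster = RacePlan(distance=MARATHON, intensity=i_wall + 1e-3)
        assert required_exogenous_cho(runner, slower, partition) == 0.0
        assert required_exogenous_cho(runner, faster, partition) > 0.0


def _feasible_split(rng, mean_speed):
    """Random (fraction, v_lo, v_hi) averaging (time-weighted) to mean_speed."""
    v_lo = mean_speed * rng.uniform(0.7, 0.999)
    v_hi = mean_speed * rng.uniform(1.001, 1.2)
    # fraction of distance at v_lo implied by the same-finish-time constraint
    frac = (1.0 / mean_speed - 1.0 / v_hi) / (1.0 / v_lo - 1.0 / v_hi)
    return (frac, v_lo, v_hi)


class TestPacingPenalty:
    def test_degenerate_split_costs_nothing(self, partition, typical_male):
        v = 11.0
        assert pacing_penalty(
            typical_male, MARATHON, v, (0.5, v, v), partition
        ) == pytest.approx(0.0, abs=1e-9)

    def test_any_proper_split_costs_extra(self, partition, typical_male):
        v = 11.0
        penalty = pacing_penalty(
            typical_male, MARATHON, v, _feasible_split(np.random.default_rng(7), v),
            partition,
        )
        assert penalty > 0

    def test_penalty_grows_with_split_width(self, partition, typical_male):
        v = 11.0
        penalties = []
        for dv in (0.25, 0.5, 1.0, 1.5):
            v_lo = v - dv
            frac = 0.5  # half the distance slow; solve v_hi for feasibility
            inv_hi = (1.0 / v - frac / v_lo) / (1.0 - frac)
            penalties.append(
                pacing_penalty(
                    typical_male, MARATHON, v, (frac, v_lo, 1.0 / inv_hi), partition
                )
            )
        assert all(a < b for a, b in zip(penalties, penalties[1:]))

    def test_jensen_property_random_splits(self, partition, typical_male):
        rng = np.random.default_rng(1234)
        v = 11.0
        for _ in range(1000):
            penalty = pacing_penalty(
                typical_male, MARATHON, v, _feasible_split(rng, v), partition
            )
            assert penalty >= 0

    def test_infeasible_split_rejected(self, partition, typical_male):
        with pytest.raises(PlanError):
            pacing_penalty(typical_male, MARATHON, 11.0, (0.5, 10.0, 10.5), partition)


class TestPredict:
    def test_wall_flag_consistency(self, partition):
        runner = RunnerProfile(mass=75.0, vo2max=45.0)
        result = predict(runner, PLAN_342, partition=partition)
        assert result.will_hit_wall == (result.distance_to_wall_km < MARATHON)
        assert result.min_exogenous_cho_g > 0

    def test_no_wall_means_no_fuel_needed(self, partition):
        runner = RunnerProfile(vo2max=55.0, muscle_glycogen_density=200.0,
                               liver_glycogen_density=500.0)
        result = predict(runner, RacePlan(distance=MARATHON, intensity=0.6),
                         partition=partition)
        assert not result.will_hit_wall
        assert result.min_exogenous_cho_g == 0.0

    def test_error_bounds_attached_on_request(self, partition):
        result = predict(RunnerProfile(), PLAN_342, partition=partition,
                         with_errors=True)
        assert result.error_bounds is not None
        assert set(result.error_bounds) == {
            "power", "vo2max_estimate", "v_max", "E_cho", "d_wall"
        }
        frame = result.to_frame()
        assert "relerr_bound_d_wall" in frame.columns
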