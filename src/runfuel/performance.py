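"""Headline race predictions: carbohydrate budget, the wall, and fueling.

The central quantities, for a runner of mass ``M`` running distance ``d`` at
relative aerobic intensity ``i``:

* carbohydrate energy required: ``E_cho = C · M · d · f_cho(i)``;
* distance to the wall: ``d_w = (specific glycogen reserve) / (C · f_cho(i))``
  — the ratio of glycogen energy stored per kg body mass to carbohydrate
  energy burned per kg per km;
* minimum midrace carbohydrate: the deficit ``E_cho − M · (specific
  reserve)``, floored at zero and converted to grams at 4 kcal/g;
* maximal post-race change in muscle glycogen density (attributing all
  carbohydrate burned, net of intake, to leg-muscle glycogen):
  ``(C · d · f_cho(i) − E_exo/M) / f_legs`` in kcal per kg of leg muscle.

Because ``f_cho`` is increasing and convex in intensity, any deviation from
an even pace — at fixed mean pace — burns strictly more carbohydrate than a
constant effort: fuel economy is maximized at constant exertion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .energetics import intensity_from_speed, max_aerobic_speed
from .errors import DomainError, PlanError
from .partition import SubstratePartition, default_partition
from .reserves import RunnerProfile, density_kcal_per_kg, specific_reserve
from .stoichiometry import DEFAULT, Stoichiometry


@dataclass(frozen=True)
class RacePlan:
    """A race described by distance and exactly one pacing target.

    ``finish_time`` in hours, ``speed`` in km/h, ``intensity`` as a fraction
    of VO2max. The target is resolved to a relative intensity for a given
    runner in the order finish_time → speed → intensity.
    """

    distance: float
    finish_time: float | None = None
    speed: float | None = None
    intensity: float | None = None

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise PlanError("distance must be positive")
        targets = [
            t for t in (self.finish_time, self.speed, self.intensity) if t is not None
        ]
        if len(targets) != 1:
            raise PlanError(
                "exactly one of finish_time, speed, intensity must be given"
            )
        if targets[0] <= 0:
            raise PlanError("the pacing target must be positive")

    def resolved_speed(self) -> float | None:
        """Speed in km/h if determined by the plan alone (time or speed target)."""
        if self.speed is not None:
            return self.speed
        if self.finish_time is not None:
            return self.distance / self.finish_time
        return None


def resolve_intensity(
    profile: RunnerProfile,
    plan: RacePlan,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> float:
    """Relative aerobic intensity implied by a race plan for this runner."""
    v = plan.resolved_speed()
    if v is not None:
        return intensity_from_speed(v, profile.vo2max, partition, stoich)
    i = plan.intensity
    if not 0 < i <= 1:
        raise DomainError("planned intensity must lie in (0, 1]")
    return i


@dataclass(frozen=True)
class FuelingPlan:
    """Exogenous carbohydrate intake during a race.

    ``schedule`` is an optional list of (distance km, grams) stations; when
    given it must sum to ``total_exogenous_cho_g``. Absorption timing is not
    modelled (carbohydrate should in practice be taken ~30 min before it is
    needed).
    """

    total_exogenous_cho_g: float = 0.0
    schedule: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.total_exogenous_cho_g < 0:
            raise PlanError("exogenous carbohydrate must be nonnegative")
        if self.schedule is not None:
            total = sum(g for _, g in self.schedule)
            if not math.isclose(total, self.total_exogenous_cho_g, rel_tol=1e-9, abs_tol=1e-9):
                raise PlanError(
                    f"schedule sums to {total} g, not {self.total_exogenous_cho_g} g"
                )

    @classmethod
    def every(cls, grams: float, interval_km: float, distance: float) -> "FuelingPlan":
        """Fixed-dose stations every ``interval_km`` over ``distance`` km."""
        stations = tuple(
            (k * interval_km, grams)
            for k in range(1, int(math.floor(distance / interval_km)) + 1)
            if k * interval_km < distance
        )
        return cls(sum(g for _, g in stations), stations)


@dataclass(frozen=True)
class DeltaGlycogen:
    """Maximal post-race change in leg-muscle glycogen density."""

    kcal_per_kg: float
    mmol_per_kg: float
    exceeds_stored: bool  # True: runner would have hit the wall mid-race


@dataclass(frozen=True)
class PredictionResult:
    """Bundle of race predictions for one runner and plan.

    ``min_exogenous_cho_g`` is zero exactly when the runner does not hit the
    wall; ``will_hit_wall`` is equivalent to ``distance_to_wall_km`` being
    shorter than the planned distance. ``error_bounds``, when attached,
    carries the first-order relative error bound per quantity implied by the
    relative uncertainty of the substrate-partition curve.
    """

    intensity: float
    speed_kmh: float
    cho_energy_kcal: float
    cho_energy_per_kg: float
    distance_to_wall_km: float
    will_hit_wall: bool
    min_exogenous_cho_g: float
    delta_muscle_glycogen: DeltaGlycogen
    error_bounds: dict[str, float] | None = field(default=None, compare=False)

    def to_frame(self):
        """Single-row DataFrame with unit-annotated column names."""
        import pandas as pd

        row = {
            "intensity_frac_vo2max": self.intensity,
            "speed_kmh": self.speed_kmh,
            "cho_energy_kcal": self.cho_energy_kcal,
            "cho_energy_kcal_per_kg": self.cho_energy_per_kg,
            "distance_to_wall_km": self.distance_to_wall_km,
            "will_hit_wall": self.will_hit_wall,
            "min_exogenous_cho_g": self.min_exogenous_cho_g,
            "delta_muscle_glycogen_kcal_per_kg": self.delta_muscle_glycogen.kcal_per_kg,
            "delta_muscle_glycogen_mmol_per_kg": self.delta_muscle_glycogen.mmol_per_kg,
            "depletion_exceeds_store": self.delta_muscle_glycogen.exceeds_stored,
        }
        if self.error_bounds:
            for k, v in self.error_bounds.items():
                row[f"relerr_bound_{k}"] = v
        return pd.DataFrame([row])


def cho_energy_required(
    profile: RunnerProfile,
    plan: RacePlan,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> tuple[float, float]:
    """(kcal, kcal per kg body mass) of carbohydrate needed for the plan.

    ``E_cho = C · M · d · f_cho(i)``; linear in distance and mass, set by
    pace only through the carbohydrate fraction.
    """
    partition = partition or default_partition()
    i = resolve_intensity(profile, plan, partition, stoich)
    per_kg = stoich.running_cost * plan.distance * partition.f_cho(i)
    return per_kg * profile.mass, per_kg


def distance_to_wall(
    profile: RunnerProfile,
    intensity: float,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> float:
    """Distance (km) runnable before glycogen reserves are exhausted.

    Returns ``inf`` when ``f_cho(i) == 0`` (no carbohydrate is being burned,
    so glycogen is never the limit). Independent of body mass at fixed
    tissue fractions and densities.
    """
    partition = partition or default_partition()
    if not 0 < intensity <= 1:
        raise DomainError("intensity must lie in (0, 1]")
    f = partition.f_cho(intensity)
    reserve = specific_reserve(profile, stoich)
    if f == 0.0:
        return math.inf
    return reserve / (stoich.running_cost * f)


def min_leg_fraction(
    profile: RunnerProfile,
    plan: RacePlan,
    muscle_density_kcal_per_kg: float = 144.0,
    partition: SubstratePartition | None = None,
    liver_fraction: float = 0.025,
    liver_density_kcal_per_kg: float = 360.0,
    stoich: Stoichiometry = DEFAULT,
) -> float:
    """Smallest leg-muscle mass fraction that avoids the wall for this plan.

    Solves ``liver term + f_legs · muscle density = E_cho per kg`` for the
    leg fraction, with the liver contribution fixed (defaults: 2.5 % of body
    mass at the 360 kcal/kg physiologic maximum) and muscle glycogen loaded
    at ``muscle_density_kcal_per_kg`` (default 144, supercompensation).
    Floored at zero when liver glycogen alone suffices.
    """
    _, per_kg = cho_energy_required(profile, plan, partition, stoich)
    liver_term = liver_fraction * liver_density_kcal_per_kg
    return max(0.0, (per_kg - liver_term) / muscle_density_kcal_per_kg)


def delta_muscle_glycogen(
    profile: RunnerProfile,
    plan: RacePlan,
    fueling: FuelingPlan | None = None,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> DeltaGlycogen:
    """Maximal change in leg-muscle glycogen density over the race.

    Attributes all carbohydrate oxidised, net of exogenous intake, to
    leg-muscle glycogen — an upper bound on true depletion. The raw value is
    returned un-clipped; ``exceeds_stored`` flags predictions beyond the
    stored density (the runner would have hit the wall mid-race).
    """
    if profile.leg_muscle_fraction <= 0:
        raise DomainError("leg muscle fraction must be positive")
    fueling = fueling or FuelingPlan(0.0)
    _, per_kg = cho_energy_required(profile, plan, partition, stoich)
    exo_kcal_per_kg = fueling.total_exogenous_cho_g * stoich.cho_energy_density / profile.mass
    kcal_per_kg_muscle = (per_kg - exo_kcal_per_kg) / profile.leg_muscle_fraction
    stored = density_kcal_per_kg(profile.muscle_glycogen_density, stoich)
    return DeltaGlycogen(
        kcal_per_kg=kcal_per_kg_muscle,
        mmol_per_kg=kcal_per_kg_muscle / stoich.energy_per_mmol_glycosyl,
        exceeds_stored=kcal_per_kg_muscle > stored,
    )


def required_exogenous_cho(
    profile: RunnerProfile,
    plan: RacePlan,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> float:
    """Minimum grams of midrace carbohydrate needed to avoid the wall.

    The energy deficit between carbohydrate required and glycogen stored,
    converted at 4 kcal/g; exactly zero whenever the distance to the wall
    covers the planned distance.
    """
    total, _ = cho_energy_required(profile, plan, partition, stoich)
    stored = profile.mass * specific_reserve(profile, stoich)
    return max(0.0, total - stored) / stoich.cho_energy_density


def pacing_penalty(
    profile: RunnerProfile,
    distance: float,
    mean_speed: float,
    split: tuple[float, float, float],
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> float:
    """Extra carbohydrate energy (kcal) burned by a two-speed strategy.

    ``split`` is ``(fraction of distance at speed_lo, speed_lo, speed_hi)``.
    The strategy must average — time-weighted, i.e. same finish time — to
    ``mean_speed`` over ``distance``; both speeds must be aerobic. Because
    ``f_cho`` is increasing and convex in speed, the penalty is strictly
    positive whenever the two speeds differ: constant exertion is the
    carbohydrate-optimal pacing at any fixed finish time.
    """
    partition = partition or default_partition()
    frac, v_lo, v_hi = split
    if not 0 < frac < 1:
        raise PlanError("split fraction must lie strictly between 0 and 1")
    if v_lo <= 0 or v_hi <= 0:
        raise PlanError("split speeds must be positive")
    # same finish time: d/mean == frac*d/v_lo + (1-frac)*d/v_hi
    implied_inv = frac / v_lo + (1.0 - frac) / v_hi
    if not math.isclose(implied_inv, 1.0 / mean_speed, rel_tol=1e-6):
        raise PlanError(
            "two-speed strategy does not average (time-weighted) to the mean speed"
        )
    i_lo = intensity_from_speed(v_lo, profile.vo2max, partition, stoich)
    i_hi = intensity_from_speed(v_hi, profile.vo2max, partition, stoich)
    i_mean = intensity_from_speed(mean_speed, profile.vo2max, partition, stoich)
    cmd = stoich.running_cost * profile.mass * distance
    split_kcal = cmd * (frac * partition.f_cho(i_lo) + (1.0 - frac) * partition.f_cho(i_hi))
    even_kcal = cmd * partition.f_cho(i_mean)
    return split_kcal - even_kcal


def predict(
    profile: RunnerProfile,
    plan: RacePlan,
    fueling: FuelingPlan | None = None,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
    with_errors: bool = False,
    delta_f_rel: float = 0.055,
) -> PredictionResult:
    """Full race prediction for one runner and plan.

    Resolves the plan to a relative intensity, then reports the carbohydrate
    budget, distance to the wall, minimum midrace carbohydrate and maximal
    muscle-glycogen depletion. With ``with_errors=True``, first-order
    relative error bounds driven by ``delta_f_rel`` (the relative
    uncertainty in the substrate-partition curve, default its 5.5 %
    worst case) are attached.
    """
    partition = partition or default_partition()
    i = resolve_intensity(profile, plan, partition, stoich)
    v = plan.resolved_speed()
    if v is None:
        v = i * max_aerobic_speed(profile.vo2max, partition, stoich)
    total, per_kg = cho_energy_required(profile, plan, partition, stoich)
    d_wall = distance_to_wall(profile, i, partition, stoich)
    will_hit = d_wall < plan.distance
    bounds = None
    if with_errors:
        from .sensitivity import propagate

        bounds = propagate(partition, i, delta_f_rel, stoich).bounds
    return PredictionResult(
        intensity=i,
        speed_kmh=v,
        cho_energy_kcal=total,
        cho_energy_per_kg=per_kg,
        distance_to_wall_km=d_wall,
        will_hit_wall=will_hit,
        min_exogenous_cho_g=required_exogenous_cho(profile, plan, partition, stoich),
        delta_muscle_glycogen=delta_muscle_glycogen(
            profile, plan, fueling, partition, stoich
        ),
        error_bounds=bounds,
    )
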