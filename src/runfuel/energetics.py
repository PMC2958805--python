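"""Conversions among speed, power, oxygen uptake, intensity and VO2max.

The chain of identities used throughout:

* Net cost of level running is ``C ≈ 1 kcal·kg⁻¹·km⁻¹`` independent of
  speed, so power is ``P = C · v · M`` and the energy for a race is
  ``E = C · M · d`` — distance, not pace, sets the total bill.
* Aerobic power also follows from oxygen uptake: ``VO2max · i`` (ml O2 per
  kg per min) converted to moles of O2 and multiplied by the energy yield
  per mole of O2 of the current fuel mixture, ``rho(i)``, which interpolates
  between the pure-fat and pure-carbohydrate constants according to
  ``f_cho(i)``.
* Equating the two at ``i = 1`` gives the maximum aerobic speed
  ``v_max = VO2max · rho(1) / (C · V_molar)`` (unit conversions elided);
  relative intensity at a given speed is then ``i = v / v_max``. By
  convention the mixture term in ``v_max`` is evaluated at ``i = 1``, which
  makes the ``i = v / v_max`` identification exactly self-consistent.

Fractional maximum heart rate ``h`` is identified one-to-one with ``i``,
which lets VO2max be estimated from a single submaximal treadmill
observation (speed, heart rate, age).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .errors import ConfigError, DomainError, SupraAerobicError
from .partition import SubstratePartition, default_partition
from .stoichiometry import DEFAULT, MILE_KM, Stoichiometry

#: ml O2 per kg per min  ->  mol O2 per kg per hour conversion numerator
_ML_MIN_TO_L_H = 60.0 / 1000.0


@dataclass(frozen=True)
class HrObservation:
    """A single submaximal treadmill observation used to estimate VO2max.

    ``speed`` in km/h, ``hr`` in beats per minute, ``age`` in years.
    ``hr_max_override`` bypasses the age formula when the runner's true
    maximum heart rate is known.
    """

    speed: float
    hr: float
    age: float
    hr_max_override: float | None = None
    hr_max_formula: Literal["tanaka", "fox"] = "tanaka"

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise DomainError("speed must be positive")
        if self.hr <= 0:
            raise DomainError("heart rate must be positive")

    @property
    def hr_max(self) -> float:
        if self.hr_max_override is not None:
            return self.hr_max_override
        return hr_max(self.age, self.hr_max_formula)

    @property
    def hr_fraction(self) -> float:
        """Fractional maximum heart rate ``h = hr / hr_max``."""
        return self.hr / self.hr_max


def mixture_energy_per_mol_o2(
    partition: SubstratePartition | None = None,
    i: float = 1.0,
    stoich: Stoichiometry = DEFAULT,
) -> float:
    """Energy yield of the fuel mixture at intensity ``i``, kcal per mole O2.

    Convex combination of the pure-substrate constants weighted by
    ``f_cho(i)``; always lies between the fat and carbohydrate limits.
    """
    partition = partition or default_partition()
    f = partition.f_cho(i)
    return f * stoich.energy_per_mol_o2_cho + (1.0 - f) * stoich.energy_per_mol_o2_fat


def aerobic_power(
    vo2max: float,
    i: float,
    mass: float,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> float:
    """Whole-body aerobic power in kcal per hour.

    Oxygen uptake ``vo2max * i`` (ml·kg⁻¹·min⁻¹) is converted to moles of O2
    per hour at STP and multiplied by the mixture energy per mole O2 and by
    body mass.
    """
    if vo2max <= 0 or mass <= 0:
        raise DomainError("vo2max and mass must be positive")
    if not 0 < i <= 1:
        raise DomainError("intensity must lie in (0, 1]")
    mol_o2_per_kg_h = vo2max * i * _ML_MIN_TO_L_H / stoich.molar_volume
    return mol_o2_per_kg_h * mixture_energy_per_mol_o2(partition, i, stoich) * mass


def power_from_speed(speed: float, mass: float, stoich: Stoichiometry = DEFAULT) -> float:
    """Metabolic power ``P = C · v · M`` in kcal/h for speed in km/h."""
    if speed <= 0 or mass <= 0:
        raise DomainError("speed and mass must be positive")
    return stoich.running_cost * speed * mass


def speed_from_power(power: float, mass: float, stoich: Stoichiometry = DEFAULT) -> float:
    """Running speed in km/h sustaining metabolic power ``power`` (kcal/h)."""
    if power <= 0 or mass <= 0:
        raise DomainError("power and mass must be positive")
    return power / (stoich.running_cost * mass)


def total_race_energy(mass: float, distance: float, stoich: Stoichiometry = DEFAULT) -> float:
    """Total metabolic energy ``C · M · d`` (kcal) to run ``distance`` km.

    Independent of pace: running faster costs more power for proportionately
    less time.
    """
    if mass <= 0 or distance < 0:
        raise DomainError("mass must be positive and distance nonnegative")
    return stoich.running_cost * mass * distance


def hr_max(age: float, formula: Literal["tanaka", "fox"] = "tanaka") -> float:
    """Age-predicted maximum heart rate in beats per minute.

    ``tanaka``: 207 − 0.7·age (active adults); ``fox``: 220 − age.
    """
    if not 0 < age < 120:
        raise DomainError("age must lie in (0, 120)")
    if formula == "tanaka":
        return 207.0 - 0.7 * age
    if formula == "fox":
        return 220.0 - age
    raise ConfigError(f"unknown maximum-heart-rate formula {formula!r}")


def estimate_vo2max(
    obs: HrObservation,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> float:
    """Estimate VO2max (ml·kg⁻¹·min⁻¹) from one submaximal observation.

    The fractional maximum heart rate ``h`` proxies relative intensity. The
    oxygen uptake implied by running at the observed speed — power per kg
    ``C·v`` divided by the mixture energy yield at intensity ``h``, converted
    to gas volume — is divided by ``h`` to extrapolate to maximum.
    Multiplying the result by body mass gives total VO2max in ml/min.
    """
    partition = partition or default_partition()
    h = obs.hr_fraction
    if not 0 < h <= 1:
        raise DomainError(
            f"fractional heart rate {h:.3f} outside (0, 1]; check hr and hr_max"
        )
    rho = mixture_energy_per_mol_o2(partition, h, stoich)
    # kcal/kg/h -> mol O2/kg/h -> ml O2/kg/min
    vo2_ml_kg_min = (
        stoich.running_cost * obs.speed / rho * stoich.molar_volume * 1000.0 / 60.0
    )
    return vo2_ml_kg_min / h


def max_aerobic_speed(
    vo2max: float,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> float:
    """Maximum aerobically sustainable running speed in km/h.

    Speed at which the cost of running equals aerobic power at ``i = 1``;
    body mass cancels. The fuel-mixture term is evaluated at ``i = 1``
    (see module docstring), so ``i = v / v_max`` is exactly self-consistent.
    """
    if vo2max <= 0:
        raise DomainError("vo2max must be positive")
    rho_max = mixture_energy_per_mol_o2(partition, 1.0, stoich)
    return vo2max * _ML_MIN_TO_L_H / stoich.molar_volume * rho_max / stoich.running_cost


def intensity_from_speed(
    speed: float,
    vo2max: float,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> float:
    """Relative aerobic intensity ``i = v / v_max`` for a given speed (km/h)."""
    if speed <= 0:
        raise DomainError("speed must be positive")
    v_max = max_aerobic_speed(vo2max, partition, stoich)
    if speed > v_max * (1.0 + 1e-12):
        raise SupraAerobicError(
            f"speed {speed:.3f} km/h exceeds the maximum aerobic speed "
            f"{v_max:.3f} km/h for VO2max {vo2max:g}"
        )
    return min(speed / v_max, 1.0)


# -- pace formatting ----------------------------------------------------


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def pace_format(speed: float, stoich: Stoichiometry = DEFAULT) -> str:
    """Mile pace string ``M:SS`` for a speed in km/h (half-up to the second)."""
    if speed <= 0:
        raise DomainError("speed must be positive")
    seconds = _round_half_up(3600.0 * stoich.mile / speed)
    return f"{seconds // 60}:{seconds % 60:02d}"


def marathon_time(speed: float, stoich: Stoichiometry = DEFAULT) -> str:
    """Marathon finish time ``H:MM:SS`` at constant speed in km/h."""
    if speed <= 0:
        raise DomainError("speed must be positive")
    seconds = _round_half_up(3600.0 * stoich.marathon_distance / speed)
    h, rem = divmod(seconds, 3600)
    m, s = divmod(rem, 60)
    return f"{h}:{m:02d}:{s:02d}"


def parse_hms(text: str) -> float:
    """Parse ``H:MM:SS`` or ``H:MM`` into hours (float)."""
    parts = text.split(":")
    if not 2 <= len(parts) <= 3:
        raise ConfigError(f"cannot parse time {text!r}; expected H:MM[:SS]")
    nums = [float(p) for p in parts]
    while len(nums) < 3:
        nums.append(0.0)
    h, m, s = nums
    return h + m / 60.0 + s / 3600.0
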