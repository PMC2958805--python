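"""Physiologic fuel reservoirs: liver and muscle glycogen, plasma glucose, fat.

Reservoir accounting converts glycogen densities (mmol of glycosyl residues
per kg of tissue) to grams of carbohydrate at 180 g/mol and to energy at
4 kcal/g. Typical and maximal densities:

* liver: ~270 mmol/kg typical, ~500 mmol/kg maximum (≈194 and 360 kcal/kg);
  liver mass is tightly regulated at ~2.5 % of body mass;
* leg muscle: ~110 mmol/kg typical in trained runners, ~200 mmol/kg after
  glycogen-loading supercompensation (≈80 and 144 kcal/kg); leg muscle is
  ~14.0–27.5 % of body mass in men, 18.0–22.5 % in women;
* plasma glucose: a few grams in total — negligible as a reservoir and
  excluded from the specific-reserve sum;
* adipose fat: energetically enormous (even the leanest runner carries fat
  for several marathons) but rate-limited, hence never the binding
  constraint modelled here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, asdict
from pathlib import Path
from typing import Literal

import yaml

from .errors import ConfigError, DomainError
from .stoichiometry import DEFAULT, Stoichiometry


@dataclass
class RunnerProfile:
    """Anthropometric and physiologic parameters of one runner.

    Glycogen densities are in mmol glycosyl residues per kg tissue; tissue
    fractions are fractions of total body mass. Defaults describe a typical
    trained male runner.
    """

    mass: float = 70.0                     # kg
    vo2max: float = 55.0                   # ml·kg⁻¹·min⁻¹
    sex: Literal["male", "female"] = "male"
    age: float = 30.0                      # years
    leg_muscle_fraction: float = 0.214
    liver_fraction: float = 0.025
    muscle_glycogen_density: float = 110.0  # mmol/kg
    liver_glycogen_density: float = 270.0   # mmol/kg
    nonessential_fat_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.mass <= 0 or self.vo2max <= 0:
            raise DomainError("mass and vo2max must be positive")
        for name in ("leg_muscle_fraction", "liver_fraction", "nonessential_fat_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise DomainError(f"{name}={v} must lie in [0, 1)")
        if self.muscle_glycogen_density < 0 or self.muscle_glycogen_density > 200.0:
            raise DomainError(
                "muscle glycogen density outside physiologic range [0, 200] mmol/kg"
            )
        if self.liver_glycogen_density < 0 or self.liver_glycogen_density > 500.0:
            raise DomainError(
                "liver glycogen density outside physiologic range [0, 500] mmol/kg"
            )
        if self.leg_muscle_fraction and not 0.10 <= self.leg_muscle_fraction <= 0.35:
            warnings.warn(
                f"leg muscle fraction {self.leg_muscle_fraction} outside the "
                "usual adult range [0.10, 0.35]",
                stacklevel=2,
            )


@dataclass(frozen=True)
class ReserveSummary:
    """Carbohydrate reservoirs of one runner, in grams and kcal."""

    liver_cho_g: float
    muscle_cho_g: float
    plasma_cho_g: float
    liver_kcal: float
    muscle_kcal: float
    plasma_kcal: float
    specific_reserve: float  # kcal per kg body mass, plasma excluded

    @property
    def total_kcal(self) -> float:
        return self.liver_kcal + self.muscle_kcal + self.plasma_kcal

    def to_frame(self):
        """Single-row DataFrame with unit-annotated columns."""
        import pandas as pd

        d = asdict(self)
        d["total_kcal"] = self.total_kcal
        return pd.DataFrame([d])


def glycogen_mass(tissue_mass: float, density: float, stoich: Stoichiometry = DEFAULT) -> float:
    """Grams of stored carbohydrate in ``tissue_mass`` kg at ``density`` mmol/kg."""
    if tissue_mass < 0 or density < 0:
        raise DomainError("tissue mass and density must be nonnegative")
    return tissue_mass * density * stoich.glucose_molar_mass / 1000.0


def glycogen_energy(grams: float, stoich: Stoichiometry = DEFAULT) -> float:
    """kcal of energy in ``grams`` of carbohydrate (4 kcal/g convention)."""
    if grams < 0:
        raise DomainError("carbohydrate mass must be nonnegative")
    return grams * stoich.cho_energy_density


def leg_muscle_reserve(
    profile: RunnerProfile, stoich: Stoichiometry = DEFAULT
) -> tuple[float, float]:
    """(grams, kcal) of glycogen stored in the leg muscles."""
    g = glycogen_mass(
        profile.mass * profile.leg_muscle_fraction,
        profile.muscle_glycogen_density,
        stoich,
    )
    return g, glycogen_energy(g, stoich)


def liver_reserve(
    profile: RunnerProfile, stoich: Stoichiometry = DEFAULT
) -> tuple[float, float]:
    """(grams, kcal) of glycogen stored in the liver."""
    g = glycogen_mass(
        profile.mass * profile.liver_fraction, profile.liver_glycogen_density, stoich
    )
    return g, glycogen_energy(g, stoich)


def plasma_reserve(
    blood_volume_l: float, glucose_mM: float, stoich: Stoichiometry = DEFAULT
) -> float:
    """kcal of glucose circulating in plasma (always a few tens of kcal at most)."""
    if blood_volume_l < 0 or glucose_mM < 0:
        raise DomainError("volume and concentration must be nonnegative")
    grams = blood_volume_l * glucose_mM * stoich.glucose_molar_mass / 1000.0
    return glycogen_energy(grams, stoich)


def density_kcal_per_kg(density_mmol: float, stoich: Stoichiometry = DEFAULT) -> float:
    """Convert a glycogen density from mmol/kg to kcal per kg of tissue."""
    return density_mmol * stoich.energy_per_mmol_glycosyl


def specific_reserve(profile: RunnerProfile, stoich: Stoichiometry = DEFAULT) -> float:
    """Glycogen energy per kg body mass (kcal/kg), plasma glucose excluded.

    Sum of liver and leg-muscle glycogen energy densities weighted by their
    tissue fractions of body mass; this is the numerator of the
    distance-to-the-wall ratio.
    """
    liver = profile.liver_fraction * density_kcal_per_kg(
        profile.liver_glycogen_density, stoich
    )
    muscle = profile.leg_muscle_fraction * density_kcal_per_kg(
        profile.muscle_glycogen_density, stoich
    )
    return liver + muscle


def summarize_reserves(
    profile: RunnerProfile,
    blood_volume_l: float = 5.0,
    glucose_mM: float = 5.0,
    stoich: Stoichiometry = DEFAULT,
) -> ReserveSummary:
    """Full reservoir summary for one runner."""
    liver_g, liver_kcal = liver_reserve(profile, stoich)
    muscle_g, muscle_kcal = leg_muscle_reserve(profile, stoich)
    plasma_kcal = plasma_reserve(blood_volume_l, glucose_mM, stoich)
    return ReserveSummary(
        liver_cho_g=liver_g,
        muscle_cho_g=muscle_g,
        plasma_cho_g=plasma_kcal / stoich.cho_energy_density,
        liver_kcal=liver_kcal,
        muscle_kcal=muscle_kcal,
        plasma_kcal=plasma_kcal,
        specific_reserve=specific_reserve(profile, stoich),
    )


def fat_reserve_distance(
    nonessential_fat_fraction: float, stoich: Stoichiometry = DEFAULT
) -> float:
    """Distance (km) runnable on nonessential fat alone; mass-independent.

    ``fraction × fat energy density (kcal/kg fat) / C``. Even at the extreme
    lower limit of nonessential body fat this exceeds four marathons — the
    point being that fat quantity never limits endurance, carbohydrate does.
    """
    if not 0.0 <= nonessential_fat_fraction < 1.0:
        raise DomainError("fat fraction must lie in [0, 1)")
    kcal_per_kg_body = nonessential_fat_fraction * stoich.fat_energy_density * 1000.0
    return kcal_per_kg_body / stoich.running_cost


# -- profile configuration IO -------------------------------------------

_PROFILE_FIELDS = {f.name for f in fields(RunnerProfile)}


def load_profile(path: str | Path) -> RunnerProfile:
    """Read a runner profile from a flat YAML key-value file.

    Keys match :class:`RunnerProfile` field names (SI units as documented
    there); unknown keys are a configuration error.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"profile file {path} must contain a flat mapping")
    unknown = set(data) - _PROFILE_FIELDS
    if unknown:
        raise ConfigError(f"unknown profile keys: {sorted(unknown)}")
    try:
        return RunnerProfile(**data)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def save_profile(profile: RunnerProfile, path: str | Path) -> None:
    """Write a runner profile as a flat YAML mapping."""
    with open(path, "w") as fh:
        yaml.safe_dump(asdict(profile), fh, sort_keys=False)
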