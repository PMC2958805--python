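"""Fixed physical and physiologic conversion constants.

The model runs on a small set of stoichiometric constants. Two conventions
coexist deliberately and are kept together in one record:

* **Oxidative stoichiometry** (used wherever oxygen uptake is converted to
  power): energy liberated per mole of respired O2, from the standard
  combustion enthalpies of representative substrates — glucose
  (686 kcal/mol, 6 mol O2 per mol) and palmitate (2398 kcal/mol, 23 mol O2
  per mol). Carbohydrate yields more energy per unit oxygen than fat, which
  is why it is the preferred fuel at high aerobic intensity.

* **Reservoir accounting** (used wherever stored glycogen is counted):
  glycosyl residues at the free-glucose molar mass of 180 g/mol and a
  carbohydrate energy density of 4 kcal/g. The 180 g/mol convention (rather
  than 162 g/mol for anhydro-glucose) is required for the standard reservoir
  arithmetic (e.g. a 1.8-kg liver at 270 mmol/kg holding ~88 g, ~350 kcal)
  to come out right, and is therefore used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

#: kilometres per statute mile
MILE_KM = 1.609344


@dataclass(frozen=True)
class Stoichiometry:
    """Bundle of conversion constants used across the model.

    Attributes
    ----------
    energy_per_mol_o2_cho : float
        kcal liberated per mole O2 when oxidising carbohydrate
        (glucose: 686 kcal/mol over 6 mol O2).
    energy_per_mol_o2_fat : float
        kcal per mole O2 for fat (palmitate: 2398 kcal/mol over 23 mol O2).
    molar_volume : float
        Litres of gas per mole at standard temperature and pressure.
    running_cost : float
        Net metabolic cost of level running, kcal per kg body mass per km.
        Speed-independent over the aerobic range; basal metabolism is
        deliberately neglected (error below ~1 %).
    cho_energy_density : float
        kcal per gram of carbohydrate (reservoir-accounting convention).
    fat_energy_density : float
        kcal per gram of fat.
    glucose_molar_mass : float
        grams per mole; glycosyl residues counted at free-glucose mass.
    marathon_distance : float
        km (26 miles 385 yards).
    """

    energy_per_mol_o2_cho: float = 686.0 / 6.0    # ~114.3 kcal/mol O2
    energy_per_mol_o2_fat: float = 2398.0 / 23.0  # ~104.3 kcal/mol O2
    molar_volume: float = 22.4                    # L/mol at STP
    running_cost: float = 1.0                     # kcal·kg⁻¹·km⁻¹
    cho_energy_density: float = 4.0               # kcal/g
    fat_energy_density: float = 9.4               # kcal/g
    glucose_molar_mass: float = 180.0             # g/mol
    marathon_distance: float = 42.195             # km
    mile: float = MILE_KM                         # km

    def __post_init__(self) -> None:
        if not (self.energy_per_mol_o2_cho > self.energy_per_mol_o2_fat > 0):
            raise ValueError(
                "carbohydrate must yield more energy per mole O2 than fat"
            )
        if self.running_cost <= 0:
            raise ValueError("running cost must be positive")

    @property
    def energy_per_mmol_glycosyl(self) -> float:
        """kcal per mmol of glycosyl residues (0.18 g/mmol × 4 kcal/g)."""
        return self.glucose_molar_mass / 1000.0 * self.cho_energy_density


#: Default constants used throughout the package.
DEFAULT = Stoichiometry()
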