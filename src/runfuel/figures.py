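"""Numeric tables behind the model's standard figures.

Each function regenerates, as a tidy DataFrame, the quantitative content of
one standard view of the model:

* the fitted substrate-partition curve against intensity;
* marathon carbohydrate cost (kcal per kg body mass) against speed for a
  set of aerobic capacities, with the leg-muscle-fraction storage
  thresholds at typical (80 kcal/kg) and supercompensated (144 kcal/kg)
  muscle glycogen loading;
* distance to the wall against intensity for a grid of builds;
* the VO2max estimate against fractional maximum heart rate for a ladder
  of treadmill speeds.

Tables are pure functions of the packaged constants, hence byte-identical
across runs; plotting, where wanted, is a thin layer over these tables.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .energetics import (
    estimate_vo2max,
    HrObservation,
    marathon_time,
    max_aerobic_speed,
)
from .partition import SubstratePartition, default_partition
from .reserves import RunnerProfile
from .performance import distance_to_wall
from .stoichiometry import DEFAULT, MILE_KM, Stoichiometry

logger = logging.getLogger(__name__)

#: Typical and supercompensated muscle glycogen loading, kcal per kg muscle.
TYPICAL_MUSCLE_KCAL = 80.0
MAX_MUSCLE_KCAL = 144.0
#: Fixed liver contribution: 2.5 % of body mass at the 360 kcal/kg maximum.
LIVER_TERM_KCAL_PER_KG = 0.025 * 360.0


def partition_table(
    partition: SubstratePartition | None = None,
    intensities: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Fitted carbohydrate/fat fractions on an intensity grid."""
    partition = partition or default_partition()
    if intensities is None:
        intensities = np.round(np.arange(0.25, 1.0001, 0.01), 4)
    i = np.asarray(intensities, dtype=float)
    f = partition.f_cho(i)
    return pd.DataFrame(
        {"intensity": i, "f_cho": f, "f_fat": 1.0 - f}
    )


def marathon_cost_table(
    vo2max_values: Iterable[float],
    speeds_kmh: Sequence[float] | None = None,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> pd.DataFrame:
    """Marathon carbohydrate cost per kg body mass across paces.

    One row per (vo2max, speed); supra-aerobic speeds for a given capacity
    are skipped with a log note. Columns include the minimum leg-muscle
    fractions needed to store the required carbohydrate at typical and
    maximal muscle glycogen loading.
    """
    partition = partition or default_partition()
    if speeds_kmh is None:
        speeds_kmh = np.round(np.arange(7.0, 20.01, 0.25), 4)
    rows = []
    for vo2 in vo2max_values:
        v_max = max_aerobic_speed(vo2, partition, stoich)
        for v in speeds_kmh:
            if v > v_max:
                logger.info(
                    "skipping supra-aerobic speed %.2f km/h for VO2max %g "
                    "(max aerobic %.2f km/h)", v, vo2, v_max,
                )
                continue
            i = v / v_max
            per_kg = stoich.running_cost * stoich.marathon_distance * partition.f_cho(i)
            rows.append(
                {
                    "vo2max": vo2,
                    "speed_kmh": v,
                    "finish_time": marathon_time(v, stoich),
                    "intensity": i,
                    "cho_kcal_per_kg": per_kg,
                    "min_leg_fraction_typical": max(
                        0.0, (per_kg - LIVER_TERM_KCAL_PER_KG) / TYPICAL_MUSCLE_KCAL
                    ),
                    "min_leg_fraction_loaded": max(
                        0.0, (per_kg - LIVER_TERM_KCAL_PER_KG) / MAX_MUSCLE_KCAL
                    ),
                }
            )
    return pd.DataFrame(rows)


def wall_distance_table(
    intensities: Sequence[float] | None = None,
    muscle_densities_kcal: Sequence[float] = (80.0, 96.0, 112.0, 128.0, 144.0),
    leg_fractions: Sequence[float] = (0.15, 0.175, 0.214, 0.25),
    stoich: Stoichiometry = DEFAULT,
    partition: SubstratePartition | None = None,
) -> pd.DataFrame:
    """Distance to the wall across intensity for a grid of builds.

    Liver fixed at 2.5 % of body mass, maximally loaded (360 kcal/kg);
    muscle densities given in kcal per kg muscle. ``hits_wall_marathon``
    marks builds whose wall falls inside the marathon distance.
    """
    partition = partition or default_partition()
    if intensities is None:
        intensities = np.round(np.arange(0.55, 1.0001, 0.01), 4)
    per_mmol = stoich.energy_per_mmol_glycosyl
    rows = []
    for dens_kcal in muscle_densities_kcal:
        for legs in leg_fractions:
            profile = RunnerProfile(
                leg_muscle_fraction=legs,
                muscle_glycogen_density=dens_kcal / per_mmol,
                liver_glycogen_density=500.0,  # 360 kcal/kg
            )
            for i in intensities:
                d_w = distance_to_wall(profile, float(i), partition, stoich)
                rows.append(
                    {
                        "intensity": float(i),
                        "muscle_kcal_per_kg": dens_kcal,
                        "leg_fraction": legs,
                        "d_wall_km": d_w,
                        "hits_wall_marathon": d_w < stoich.marathon_distance,
                    }
                )
    return pd.DataFrame(rows)


def vo2max_estimate_table(
    speeds_mph: Sequence[float] = tuple(range(4, 14)),
    hr_fractions: Sequence[float] | None = None,
    partition: SubstratePartition | None = None,
    stoich: Stoichiometry = DEFAULT,
) -> pd.DataFrame:
    """VO2max estimates against fractional maximum heart rate, per speed."""
    partition = partition or default_partition()
    if hr_fractions is None:
        hr_fractions = np.round(np.arange(0.50, 1.0001, 0.01), 4)
    rows = []
    for mph in speeds_mph:
        v = mph * MILE_KM
        for h in hr_fractions:
            obs = HrObservation(speed=v, hr=float(h) * 100.0, age=30.0, hr_max_override=100.0)
            rows.append(
                {
                    "speed_mph": mph,
                    "speed_kmh": v,
                    "hr_fraction": float(h),
                    "vo2max_estimate": estimate_vo2max(obs, partition, stoich),
                }
            )
    return pd.DataFrame(rows)


def write_figure_tables(outdir, partition: SubstratePartition | None = None) -> list[str]:
    """Write the four standard tables as CSV files; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = {
        "fig1_partition.csv": partition_table(partition),
        "fig2_marathon_cost.csv": marathon_cost_table((40.0, 45.0, 50.0, 55.0, 60.0, 65.0), partition=partition),
        "fig3_wall_distance.csv": wall_distance_table(partition=partition),
        "fig4_vo2max_estimate.csv": vo2max_estimate_table(partition=partition),
    }
    paths = []
    for name, df in tables.items():
        path = outdir / name
        df.to_csv(path, index=False)
        paths.append(str(path))
    return paths


def plot_partition(partition: SubstratePartition | None = None, ax=None):
    """Quick matplotlib view of the fitted partition curve (optional extra)."""
    import matplotlib.pyplot as plt

    table = partition_table(partition)
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(table["intensity"], table["f_cho"], label="carbohydrate")
    ax.plot(table["intensity"], table["f_fat"], label="fat")
    ax.set_xlabel("intensity (fraction of VO2max)")
    ax.set_ylabel("fraction of energy expenditure")
    ax.legend()
    return ax
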