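"""Substrate partitioning: fraction of aerobic energy drawn from carbohydrate.

The fraction of whole-body energy expenditure supplied by carbohydrate
oxidation, ``f_cho``, rises with relative aerobic intensity ``i`` (fraction
of VO2max); fat supplies the complement ``f_fat = 1 - f_cho`` exactly. The
dependence is represented by a quadratic ``f_cho(i) = a + b*i + c*i**2``
fitted through measured anchor points (three intensities in the packaged
default table, giving exact interpolation), clamped to [0, 1] on evaluation.

The fitted quadratic is convex and increasing over the anchored domain; both
properties carry physiological meaning downstream — convexity is what makes
uneven pacing burn extra carbohydrate at a fixed mean pace.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError, FitDegeneracyError, UndefinedPartitionError

_ANCHOR_RESOURCE = "substrate_anchors.tsv"


@dataclass(frozen=True)
class PartitionAnchor:
    """One measured anchor of the substrate-partition curve.

    Parameters
    ----------
    intensity : float
        Relative aerobic intensity, fraction of VO2max, in (0, 1].
    f_cho : float
        Fraction of energy expenditure from carbohydrate, in [0, 1].
    se_fat, se_cho : float
        Standard errors of the underlying whole-body fat and carbohydrate
        oxidation rates (same units as ``x_fat``/``x_cho``).
    x_fat, x_cho : float
        Whole-body oxidation rates at this intensity (energy per unit time,
        e.g. cal·kg⁻¹·min⁻¹); needed only for error propagation.
    """

    intensity: float
    f_cho: float
    se_fat: float = 0.0
    se_cho: float = 0.0
    x_fat: float = float("nan")
    x_cho: float = float("nan")

    def __post_init__(self) -> None:
        if not 0.0 < self.intensity <= 1.0:
            raise DomainError(f"anchor intensity {self.intensity} not in (0, 1]")
        if not 0.0 <= self.f_cho <= 1.0:
            raise DomainError(f"anchor f_cho {self.f_cho} not in [0, 1]")


@dataclass(frozen=True)
class SubstratePartition:
    """Fitted quadratic substrate-partition curve.

    ``coefficients`` are (a, b, c) of ``f_cho(i) = a + b*i + c*i**2`` in
    increasing-power order; evaluation clamps to ``clamp_bounds`` (always
    [0, 1]). ``fit_domain`` is the intensity interval covered by the anchors;
    evaluation outside it (still within (0, 1]) extrapolates with the same
    quadratic, emitting a warning below the lower edge where the curve is
    unconstrained by data.
    """

    coefficients: tuple[float, float, float]
    fit_domain: tuple[float, float]
    clamp_bounds: tuple[float, float] = (0.0, 1.0)
    anchors: tuple[PartitionAnchor, ...] = field(default=(), compare=False)

    # -- evaluation -----------------------------------------------------

    def _raw(self, i):
        a, b, c = self.coefficients
        arr = np.asarray(i, dtype=float)
        return a + b * arr + c * arr**2

    def f_cho(self, i):
        """Carbohydrate fraction of energy expenditure at intensity ``i``.

        ``i`` may be a scalar or array; all values must lie in (0, 1]
        (supra-aerobic intensities are outside the model). The quadratic
        value is clamped to [0, 1].
        """
        arr = np.asarray(i, dtype=float)
        if np.any(arr <= 0.0) or np.any(arr > 1.0):
            raise DomainError(
                "intensity must lie in (0, 1]; the anaerobic regime is out of scope"
            )
        if np.any(arr < self.fit_domain[0]):
            warnings.warn(
                f"intensity below the anchored domain [{self.fit_domain[0]}, "
                f"{self.fit_domain[1]}]; quadratic extrapolation is unconstrained "
                "by data there",
                stacklevel=2,
            )
        lo, hi = self.clamp_bounds
        out = np.clip(self._raw(arr), lo, hi)
        return float(out) if np.isscalar(i) or arr.ndim == 0 else out

    def f_fat(self, i):
        """Fat fraction of energy expenditure: exactly ``1 - f_cho(i)``."""
        return 1.0 - self.f_cho(i)

    __call__ = f_cho

    # -- derived objects ------------------------------------------------

    def scaled(self, factor: float) -> "SubstratePartition":
        """Partition with the raw quadratic scaled by ``factor``.

        Used by the sensitivity machinery to model a uniform relative error
        in ``f_cho`` (coefficients scale linearly, so the raw curve does too).
        """
        a, b, c = self.coefficients
        return SubstratePartition(
            coefficients=(a * factor, b * factor, c * factor),
            fit_domain=self.fit_domain,
            clamp_bounds=self.clamp_bounds,
            anchors=self.anchors,
        )


def fit_partition(anchors: Iterable[PartitionAnchor]) -> SubstratePartition:
    """Fit the quadratic carbohydrate-fraction curve through anchor points.

    With exactly three anchors the quadratic interpolates them exactly
    (Vandermonde solve); with more, an ordinary least-squares fit is used.
    The fat fraction is defined as the exact complement, so
    ``f_cho + f_fat = 1`` holds identically.

    Raises
    ------
    FitDegeneracyError
        If fewer than three anchors are given or intensities repeat.
    """
    pts = tuple(anchors)
    if len(pts) < 3:
        raise FitDegeneracyError("at least 3 anchors are required for a quadratic fit")
    x = np.array([p.intensity for p in pts], dtype=float)
    y = np.array([p.f_cho for p in pts], dtype=float)
    if len(np.unique(x)) != len(x):
        raise FitDegeneracyError("anchor intensities must be distinct")
    V = np.vander(x, 3, increasing=True)
    if len(pts) == 3:
        coef = np.linalg.solve(V, y)
    else:
        coef, *_ = np.linalg.lstsq(V, y, rcond=None)
    return SubstratePartition(
        coefficients=tuple(float(c) for c in coef),
        fit_domain=(float(x.min()), float(x.max())),
        anchors=pts,
    )


def partition_error(
    partition: SubstratePartition,
    i: float,
    se_fat: float,
    se_cho: float,
    x_fat: float,
    x_cho: float,
) -> float:
    """Relative error ``|δf/f|`` in the carbohydrate fraction at intensity ``i``.

    ``f_cho`` is measured as ``x_cho / (x_fat + x_cho)`` from independent
    determinations of the whole-body fat and carbohydrate oxidation rates, so
    their standard errors contribute independently. Partial differentiation
    gives the weights ``∂f/∂x_cho = x_fat/S²`` and ``∂f/∂x_fat = -x_cho/S²``
    with ``S = x_fat + x_cho``; the two contributions combine in quadrature.

    Raises
    ------
    UndefinedPartitionError
        If the total oxidation rate is zero (partition undefined).
    """
    if not (x_fat > 0.0 and x_cho > 0.0):
        raise UndefinedPartitionError(
            "whole-body oxidation rates must be positive to define the partition"
        )
    # validates the intensity domain even though f derives from the rates
    partition.f_cho(i)
    total = x_fat + x_cho
    f = x_cho / total
    delta_f = math.hypot(x_fat * se_cho, x_cho * se_fat) / total**2
    return abs(delta_f / f)


def load_default_anchors() -> tuple[PartitionAnchor, ...]:
    """Load the packaged substrate-partition anchor table.

    The table (see ``data/substrate_anchors.tsv``, provenance in its header)
    carries three anchors at 25 %, 65 % and 85 % VO2max with whole-body
    oxidation rates and their standard errors.
    """
    text = (
        resources.files("runfuel.data").joinpath(_ANCHOR_RESOURCE).read_text()
    )
    rows: list[PartitionAnchor] = []
    header: Sequence[str] | None = None
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if header is None:
            header = fields
            continue
        rec = dict(zip(header, (float(v) for v in fields)))
        rows.append(
            PartitionAnchor(
                intensity=rec["intensity"],
                f_cho=rec["f_cho"],
                se_fat=rec["se_fat"],
                se_cho=rec["se_cho"],
                x_fat=rec["x_fat"],
                x_cho=rec["x_cho"],
            )
        )
    return tuple(rows)


_default_partition: SubstratePartition | None = None


def default_partition() -> SubstratePartition:
    """The partition fitted through the packaged anchors (cached)."""
    global _default_partition
    if _default_partition is None:
        _default_partition = fit_partition(load_default_anchors())
    return _default_partition
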