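"""First-order error propagation through the fuel-metabolism model.

The substrate-partition curve ``f_cho`` is the model's single empirical
ingredient, so every derived quantity inherits its uncertainty. Because each
headline quantity depends on ``f_cho`` (or its inverse) to first order,
logarithmic differentiation bounds the induced relative errors:

* Power, the VO2max estimate and the maximum aerobic speed depend on ``f``
  only through the mixture energy per mole O2,
  ``rho(i) = rho_fat + (rho_cho − rho_fat) · f(i)``, whose logarithmic
  sensitivity is ``f · (rho_cho − rho_fat) / rho(i) < 1`` — relative errors
  in ``f`` propagate as *smaller* relative errors in these quantities.
* The carbohydrate energy budget is proportional to ``f`` and the distance
  to the wall to ``1/f``, so both carry the relative error of ``f``
  unchanged (the latter with opposite sign).

Bounds are linearized (first order); the finite-difference verifier
re-evaluates a quantity with the fitted curve scaled by ``1 + ε`` and
reports the observed relative change for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .errors import DomainError
from .partition import SubstratePartition, default_partition
from .stoichiometry import DEFAULT, Stoichiometry

#: Quantities whose relative error is strictly damped relative to |δf/f|.
DAMPED = ("power", "vo2max_estimate", "v_max")
#: Quantities that carry |δf/f| exactly at first order.
CARRIED = ("E_cho", "d_wall")


@dataclass(frozen=True)
class ErrorBudget:
    """First-order relative error bounds implied by ``|δf/f| = delta_f_rel``.

    ``bounds`` maps quantity names (``power``, ``vo2max_estimate``,
    ``v_max``, ``E_cho``, ``d_wall``) to bounded relative errors
    (magnitudes). The first three are strictly below ``delta_f_rel``; the
    last two equal it.
    """

    delta_f_rel: float
    intensity: float
    bounds: dict[str, float]


def _rho_sensitivity(
    partition: SubstratePartition, i: float, stoich: Stoichiometry
) -> float:
    """Logarithmic sensitivity of the mixture energy term to f at intensity i."""
    f = partition.f_cho(i)
    spread = stoich.energy_per_mol_o2_cho - stoich.energy_per_mol_o2_fat
    rho = stoich.energy_per_mol_o2_fat + spread * f
    return f * spread / rho


def propagate(
    partition: SubstratePartition | None = None,
    i: float = 0.75,
    delta_f_rel: float = 0.055,
    stoich: Stoichiometry = DEFAULT,
) -> ErrorBudget:
    """Propagate a relative error in ``f_cho`` to the derived quantities.

    ``delta_f_rel`` is ``|δf/f|`` (default 5.5 %, the worst case of the
    packaged anchor table). Power and the VO2max estimate are evaluated at
    intensity ``i``; the maximum aerobic speed depends on ``f`` at ``i = 1``.
    """
    partition = partition or default_partition()
    if not abs(delta_f_rel) < 1:
        raise DomainError("|delta_f_rel| must be below 1 for a meaningful bound")
    mag = abs(delta_f_rel)
    bounds = {
        "power": _rho_sensitivity(partition, i, stoich) * mag,
        "vo2max_estimate": _rho_sensitivity(partition, i, stoich) * mag,
        "v_max": _rho_sensitivity(partition, 1.0, stoich) * mag,
        "E_cho": mag,
        "d_wall": mag,
    }
    return ErrorBudget(delta_f_rel=delta_f_rel, intensity=i, bounds=bounds)


def verify_by_perturbation(
    evaluator: Callable[[SubstratePartition], float],
    partition: SubstratePartition | None = None,
    epsilon: float = 1e-4,
) -> float:
    """Observed relative change of a quantity when ``f_cho`` scales by 1+ε.

    ``evaluator`` maps a partition to the quantity of interest; the return
    value is ``(Q(f·(1+ε)) − Q(f)) / Q(f)``, signed. To first order it must
    respect the analytic bound for that quantity.
    """
    partition = partition or default_partition()
    if not 0 < abs(epsilon) <= 1e-3:
        raise DomainError("epsilon must be small (|ε| ≤ 1e-3) for a first-order check")
    base = evaluator(partition)
    if base == 0:
        raise DomainError("quantity evaluates to zero; relative change undefined")
    bumped = evaluator(partition.scaled(1.0 + epsilon))
    return (bumped - base) / base
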