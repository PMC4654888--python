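"""Steady-state flux balance analysis and product-yield computation.

Solves max/min c·v subject to S·v = 0 and bound constraints with
scipy's HiGHS interface (deterministic dual simplex).  Yields are
computed with the glucose exchange pinned at a fixed uptake rate, the
convention used for theoretical-yield calculations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .core import MetabolicModel, UnknownIdError

__all__ = [
    "PHB_MONOMER_MASS",
    "GLUCOSE_MASS",
    "FluxDistribution",
    "YieldResult",
    "InfeasibleModelError",
    "solve_fba",
    "compute_yield",
    "apply_knockout",
    "flux_ranges",
]

#: molar mass of the PHB repeat unit C4H6O2, g/mol
PHB_MONOMER_MASS = 86.09
#: molar mass of glucose, g/mol
GLUCOSE_MASS = 180.16

_STATUS = {0: "optimal", 1: "iteration_limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


class InfeasibleModelError(RuntimeError):
    """Raised when a computation requires an optimum but the LP has none."""

    def __init__(self, status: str, message: str = ""):
        self.status = status
        super().__init__(message or f"linear program terminated with status {status!r}")


@dataclass
class FluxDistribution:
    """A steady-state flux vector (mmol/gDCW/h) with solver status."""

    fluxes: dict[str, float]
    objective_value: float
    status: str

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]


@dataclass
class YieldResult:
    """Molar and mass yield of a product on glucose."""

    mol_yield: float
    substrate_uptake: float
    solution: FluxDistribution = field(repr=False, default=None)
    monomer_mass: float = PHB_MONOMER_MASS
    glucose_mass: float = GLUCOSE_MASS

    @property
    def mass_yield(self) -> float:
        return self.mol_yield * self.monomer_mass / self.glucose_mass


def _solve(model: MetabolicModel, c: np.ndarray, extra_ub=None):
    """Run HiGHS on S·v = 0, bounds, optional A_ub v <= b_ub; minimize c·v."""
    S, _, _ = model.stoichiometric_matrix()
    bounds = [(r.lower_bound, r.upper_bound) for r in model.reactions]
    kwargs = {}
    if extra_ub is not None:
        kwargs["A_ub"], kwargs["b_ub"] = extra_ub
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=bounds,
        method="highs-ds",
        **kwargs,
    )
    return res


def solve_fba(
    model: MetabolicModel, objective: str, sense: str = "max"
) -> FluxDistribution:
    """Maximize (or minimize) the flux of one reaction at steady state.

    The zero flux vector is feasible whenever every bound interval contains
    0, so a producible-from-nothing objective reports ``optimal`` with
    objective 0 rather than infeasibility.
    """
    if sense not in ("max", "min"):
        raise ValueError(f"sense must be 'max' or 'min', got {sense!r}")
    ids = model.reaction_ids
    if objective not in ids:
        raise UnknownIdError(f"unknown objective reaction {objective!r}")
    c = np.zeros(len(ids))
    c[ids.index(objective)] = -1.0 if sense == "max" else 1.0
    res = _solve(model, c)
    status = _STATUS.get(res.status, "numerical")
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=float("nan"), status=status)
    fluxes = {rid: float(v) for rid, v in zip(ids, res.x)}
    obj = fluxes[objective]
    return FluxDistribution(fluxes=fluxes, objective_value=obj, status="optimal")


def compute_yield(
    model: MetabolicModel,
    product: str = "EX_phb",
    glucose_uptake: float = 10.0,
    glucose_exchange: str = "EX_glc",
) -> YieldResult:
    """Maximal molar product yield at a fixed glucose uptake.

    Pins the glucose exchange at ``-glucose_uptake`` (uptake is negative
    flux), maximizes the product exchange and reports
    ``mol_yield = v_product / glucose_uptake``.  Raises
    :class:`InfeasibleModelError` if no steady state exists — never a
    silent zero.
    """
    if glucose_uptake <= 0:
        raise ValueError("glucose_uptake must be positive")
    m = model.copy()
    glc = m.reaction(glucose_exchange)  # raises UnknownIdError
    m.reaction(product)
    glc.lower_bound = glc.upper_bound = -float(glucose_uptake)
    sol = solve_fba(m, product, "max")
    if sol.status != "optimal":
        raise InfeasibleModelError(
            sol.status,
            f"no optimal steady state at glucose uptake {glucose_uptake} "
            f"(status {sol.status!r})",
        )
    return YieldResult(
        mol_yield=sol.objective_value / glucose_uptake,
        substrate_uptake=glucose_uptake,
        solution=sol,
    )


def apply_knockout(model: MetabolicModel, reaction_ids) -> MetabolicModel:
    """Return a copy with the given reactions' bounds closed to [0, 0]."""
    if isinstance(reaction_ids, str):
        reaction_ids = [reaction_ids]
    unknown = [rid for rid in reaction_ids if not model.has_reaction(rid)]
    if unknown:
        raise UnknownIdError(
            f"unknown reaction id(s) in knockout: {', '.join(sorted(unknown))}"
        )
    m = model.copy()
    for rid in reaction_ids:
        r = m.reaction(rid)
        r.lower_bound = 0.0
        r.upper_bound = 0.0
    return m


def flux_ranges(
    model: MetabolicModel,
    objective: str,
    fraction: float = 1.0,
    reactions=None,
) -> dict[str, tuple[float, float]]:
    """Flux variability: min/max of each reaction at near-optimal objective.

    Constrains ``v_objective >= fraction * optimum`` (for a maximization
    objective) and reports ``(min, max)`` per reaction.  With fraction 1.0
    this diagnoses which fluxes are required at the optimum.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    base = solve_fba(model, objective, "max")
    if base.status != "optimal":
        raise InfeasibleModelError(base.status)
    ids = model.reaction_ids
    n = len(ids)
    obj_col = ids.index(objective)
    row = np.zeros((1, n))
    row[0, obj_col] = -1.0  # -v_obj <= -fraction * optimum
    rhs = np.array([-fraction * base.objective_value])
    # loosen by LP reporting tolerance so the optimal face itself is feasible
    rhs += 1e-9 * max(1.0, abs(base.objective_value))
    targets = list(reactions) if reactions is not None else ids
    out: dict[str, tuple[float, float]] = {}
    for rid in targets:
        if rid not in ids:
            raise UnknownIdError(f"unknown reaction id {rid!r}")
        j = ids.index(rid)
        lo_hi = []
        for sign in (1.0, -1.0):
            c = np.zeros(n)
            c[j] = sign
            res = _solve(model, c, extra_ub=(row, rhs))
            status = _STATUS.get(res.status, "numerical")
            if status != "optimal":
                raise InfeasibleModelError(
                    status, f"flux range of {rid!r} at fraction {fraction}: {status}"
                )
            lo_hi.append(float(res.x[j]))
        out[rid] = (lo_hi[0], lo_hi[1])
    return out
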