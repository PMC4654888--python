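"""Net (lumped) overall reactions from flux-weighted stoichiometry sums.

A pathway carrying a steady flux can be collapsed into one overall
equation: each metabolite's net coefficient is the flux-weighted sum of
the member reactions' coefficients, and every *internal* metabolite of the
pathway must cancel exactly.  All arithmetic is exact
(:class:`fractions.Fraction`); floating-point flux vectors from the LP are
rationalized (denominator bound 10^6) before summation, and any internal
residual above 1e-6 is an error rather than silently rounded away.

This module also derives the threonine-bypass cycle's internal flux
ratios from scratch by solving the steady-state linear system of the
bypass sub-network with the external PEP input normalized to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import sympy

from .core import MetabolicModel, UnknownIdError, format_equation

__all__ = [
    "NetReaction",
    "LumpingError",
    "lump",
    "merge_cofactors",
    "derive_bypass_fluxes",
    "net_carbon",
    "equation_string",
    "BYPASS_MEMBERS",
    "BYPASS_INTERNAL",
    "CLASSICAL_MEMBERS",
]

#: reactions forming the threonine-bypass cycle (PEP in, acetyl-CoA out)
BYPASS_MEMBERS = (
    "ppc", "aspC", "gdh", "thr_synth", "tdh", "kbl",
    "glyA", "gcv", "sdaA", "pps", "adk",
)

#: metabolites internal to the bypass cycle (must cancel in the net equation)
BYPASS_INTERNAL = frozenset(
    {"OAA", "Asp", "Thr", "AKB", "Gly", "Ser", "Pyr",
     "MTHF", "THF", "Glu", "AKG", "AMP"}
)

#: the classical route from PEP to acetyl-CoA
CLASSICAL_MEMBERS = ("pyk", "pdh")

#: species omitted when printing equations (balanced internally, not shown)
DISPLAY_EXCLUDED = ("Pi", "H2O")

_RESIDUAL_TOL = 1e-6
_DENOMINATOR_BOUND = 10**6


class LumpingError(ValueError):
    """A flux vector that is not a steady state of its sub-network."""


@dataclass(frozen=True)
class NetReaction:
    """A lumped overall equation.

    ``stoichiometry`` maps metabolite id to exact net coefficient;
    ``source_fluxes`` records the (rationalized) flux vector used;
    ``eliminated`` is the set of internal metabolites that cancelled.
    """

    stoichiometry: Mapping[str, Fraction]
    source_fluxes: Mapping[str, Fraction]
    eliminated: frozenset[str]

    def coefficient(self, met_id: str) -> Fraction:
        return self.stoichiometry.get(met_id, Fraction(0))

    def __str__(self) -> str:
        return equation_string(self)


def _rationalize(value) -> Fraction:
    if isinstance(value, Fraction):
        return value
    if isinstance(value, int):
        return Fraction(value)
    approx = Fraction(float(value)).limit_denominator(_DENOMINATOR_BOUND)
    if abs(float(approx) - float(value)) > _RESIDUAL_TOL:
        raise LumpingError(
            f"flux value {value!r} is not close to a rational with "
            f"denominator <= {_DENOMINATOR_BOUND}"
        )
    return approx


def lump(
    model: MetabolicModel,
    fluxes: Mapping[str, object],
    internal: Iterable[str] = (),
) -> NetReaction:
    """Collapse a flux vector into a net overall reaction.

    ``stoichiometry[m] = sum_r flux_r * coeff_{r,m}`` exactly; every
    metabolite listed in ``internal`` must cancel (|residual| <= 1e-6
    after rationalization, stored as exactly 0), otherwise the flux vector
    is not a steady state of the sub-network and a :class:`LumpingError`
    names the offender and its residual.
    """
    internal = frozenset(internal)
    rational_fluxes: dict[str, Fraction] = {}
    net: dict[str, Fraction] = {}
    for rxn_id, value in fluxes.items():
        reaction = model.reaction(rxn_id)  # raises UnknownIdError
        v = _rationalize(value)
        rational_fluxes[rxn_id] = v
        if v == 0:
            continue
        for met, coeff in reaction.stoichiometry.items():
            net[met] = net.get(met, Fraction(0)) + v * coeff
    for met in internal:
        residual = net.get(met, Fraction(0))
        if abs(float(residual)) > _RESIDUAL_TOL:
            raise LumpingError(
                f"internal metabolite {met!r} does not cancel: "
                f"residual {residual} (flux vector is not a steady state "
                "of the sub-network)"
            )
        net[met] = Fraction(0)
    net = {m: c for m, c in net.items() if c != 0 or m in internal}
    return NetReaction(
        stoichiometry=net,
        source_fluxes=rational_fluxes,
        eliminated=internal,
    )


# ---------------------------------------------------------------------------
# cofactor merging (NADH == NADPH under the transhydrogenase assumption)
# ---------------------------------------------------------------------------

#: pseudo-species naming the merged redox pair
MERGED_REDUCED = "NAD(P)H"
MERGED_OXIDIZED = "NAD(P)"

_REDUCED = ("NADH", "NADPH")
_OXIDIZED = ("NAD", "NADP")


def merge_cofactors(net: NetReaction) -> NetReaction:
    """Merge NADH/NADPH (and NAD+/NADP+) into one redox-equivalent pair.

    Coefficients are summed; ATP-equivalents are untouched.  Idempotent.
    """
    stoich = dict(net.stoichiometry)
    changed = False
    for group, merged_id in ((_REDUCED, MERGED_REDUCED), (_OXIDIZED, MERGED_OXIDIZED)):
        total = Fraction(0)
        present = False
        for species in group:
            if species in stoich:
                total += stoich.pop(species)
                present = True
        if merged_id in stoich:
            total += stoich.pop(merged_id)
            present = True
        if present:
            changed = True
            if total != 0:
                stoich[merged_id] = total
    if not changed:
        return net
    return NetReaction(
        stoichiometry=stoich,
        source_fluxes=net.source_fluxes,
        eliminated=net.eliminated,
    )


def net_carbon(net: NetReaction, model: MetabolicModel) -> Fraction:
    """Carbon sum of a net reaction (moiety convention); 0 = conserved.

    Metabolite ids absent from the model (e.g. the merged redox
    pseudo-species) carry no carbon.
    """
    known = {m.id: m.carbons for m in model.metabolites}
    total = Fraction(0)
    for met, coeff in net.stoichiometry.items():
        total += coeff * known.get(met, 0)
    return total


def equation_string(net: NetReaction, exclude: tuple[str, ...] = DISPLAY_EXCLUDED) -> str:
    """Human-readable equation, omitting phosphate/water by default."""
    shown = {
        m: c for m, c in net.stoichiometry.items() if c != 0 and m not in exclude
    }
    return format_equation(shown)


# ---------------------------------------------------------------------------
# bypass flux-ratio derivation
# ---------------------------------------------------------------------------


def derive_bypass_fluxes(model: MetabolicModel) -> dict[str, Fraction]:
    """Solve the bypass sub-network's steady state, PEP input normalized to 1.

    Members: PEP carboxylase, transaminase, glutamate dehydrogenase, lumped
    threonine synthesis, tdh, kbl, glyA, the glycine cleavage system, serine
    deaminase, PEP synthase and adenylate kinase.  All cycle intermediates
    (and the carrier pairs THF/MTHF, Glu/AKG, AMP) are balanced; the net PEP
    consumption is constrained to 1.  Returns the unique exact flux vector,
    or raises :class:`LumpingError` reporting the null-space dimension when
    the system is under- or over-determined.
    """
    members = [rid for rid in BYPASS_MEMBERS if model.has_reaction(rid)]
    missing = set(BYPASS_MEMBERS) - set(members)
    if missing:
        raise UnknownIdError(
            f"model lacks bypass member reaction(s): {', '.join(sorted(missing))}"
        )
    reactions = [model.reaction(rid) for rid in members]
    balanced = sorted(BYPASS_INTERNAL)
    rows = []
    rhs = []
    for met in balanced:
        rows.append([sympy.Rational(r.stoichiometry.get(met, 0)) for r in reactions])
        rhs.append(sympy.Integer(0))
    # normalization: net PEP coefficient of the sub-network is -1 (1 PEP in)
    rows.append([sympy.Rational(r.stoichiometry.get("PEP", 0)) for r in reactions])
    rhs.append(sympy.Integer(-1))

    A = sympy.Matrix(rows)
    b = sympy.Matrix(rhs)
    nullity = len(A.nullspace())
    if nullity > 0:
        raise LumpingError(
            f"bypass sub-network is underdetermined: null-space dimension "
            f"{nullity} after normalization"
        )
    solution = A.solve_least_squares(b)
    residual = A * solution - b
    if any(x != 0 for x in residual):
        raise LumpingError(
            "bypass sub-network steady-state system is inconsistent "
            f"(residual {[sympy.nsimplify(x) for x in residual if x != 0]})"
        )
    return {
        rid: Fraction(int(sympy.fraction(val)[0]), int(sympy.fraction(val)[1]))
        for rid, val in zip(members, solution)
    }
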