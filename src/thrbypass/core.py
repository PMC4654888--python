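"""Network data model and the curated central-carbon + threonine-bypass network.

The model is a small constraint-based (stoichiometric) network of E. coli
central carbon metabolism extended with threonine synthesis/degradation,
the glycine/serine one-carbon loop, and PHB (poly(3-hydroxybutyrate))
monomer synthesis.  Stoichiometric coefficients are exact rationals
(:class:`fractions.Fraction`); flux bounds are floats in mmol/gDCW/h.

Conventions
-----------
* Exchange reactions are written ``metabolite ->`` with a single
  metabolite of coefficient -1: positive flux is secretion, negative flux
  is uptake.
* Carrier cofactors (ATP/ADP/AMP, NAD(H), NADP(H), CoA, THF) carry an
  ``is_cofactor`` flag and their ``carbons`` field counts only the
  *transferable moiety*: the acetyl group of acetyl-CoA counts 2 C, the
  methylene group of methylene-THF counts 1 C, backbones count 0.  Carbon
  bookkeeping is then a plain flux-weighted sum over all species.
* Glycolysis is lumped with the PTS convention: glucose import spends one
  PEP, so the net conversion is glucose -> 2 PEP + 2 NADH + 0 ATP and
  pyruvate kinase supplies the "+ ATP" of the classical equation.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping

import yaml

__all__ = [
    "DEFAULT_BOUND",
    "ModelError",
    "UnknownIdError",
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "build_curated_model",
    "carbon_balance",
    "read_model",
    "write_model",
    "read_sbml",
    "write_sbml",
    "parse_equation",
    "format_equation",
    "BYPASS_REACTIONS",
]

#: default "unbounded" magnitude for flux bounds (mmol/gDCW/h)
DEFAULT_BOUND = 1000.0

#: reactions whose bounds encode activation of the threonine-degradation
#: operon (closed in the wild type, open when the bypass is active)
BYPASS_REACTIONS = ("tdh", "kbl")


class ModelError(ValueError):
    """Malformed model content (duplicate ids, dangling references...)."""


class UnknownIdError(ModelError):
    """A reaction or metabolite id that does not exist in the model."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Metabolite:
    """A chemical species node.

    ``carbons`` counts carbon atoms; for ``is_cofactor`` carriers it counts
    only the carried moiety (see module docstring).  ``is_boundary`` marks
    species eligible for exchange with the environment.
    """

    id: str
    name: str = ""
    carbons: int = 0
    is_cofactor: bool = False
    is_boundary: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("metabolite id must be non-empty")
        if self.carbons < 0:
            raise ModelError(f"metabolite {self.id!r}: carbons must be >= 0")


@dataclass
class Reaction:
    """Signed stoichiometry over metabolite ids with flux bounds.

    Negative coefficients are consumed, positive produced.  An exchange
    reaction touches exactly one (non-cofactor) metabolite.
    """

    id: str
    stoichiometry: dict[str, Fraction]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: stoichiometry is empty")
        if self.lower_bound > self.upper_bound:
            raise ModelError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        self.stoichiometry = {
            m: Fraction(c) for m, c in self.stoichiometry.items() if Fraction(c) != 0
        }
        if not self.stoichiometry:
            raise ModelError(f"reaction {self.id!r}: all coefficients are zero")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    @property
    def is_exchange(self) -> bool:
        return len(self.stoichiometry) == 1

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            name=self.name,
        )


@dataclass
class MetabolicModel:
    """An ordered reaction set viewed as a stoichiometric matrix.

    ``atp_per_nadh`` is the stoichiometric ATP yield of the lumped
    respiration reaction (the P/O ratio).  ``cofactor_policy`` is
    ``"merged"`` when NADH and NADPH are freely interconvertible through an
    unbounded transhydrogenase (the convention used for the printed yields)
    or ``"split"`` when they are distinct pools.
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    atp_per_nadh: Fraction = Fraction(56, 33)
    cofactor_policy: str = "merged"
    name: str = ""

    def __post_init__(self) -> None:
        self.atp_per_nadh = Fraction(self.atp_per_nadh)
        self.validate()

    # -- lookups ------------------------------------------------------------

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise UnknownIdError(f"unknown metabolite id {met_id!r}")

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise UnknownIdError(f"unknown reaction id {rxn_id!r}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    @property
    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.is_exchange]

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.cofactor_policy not in ("merged", "split"):
            raise ModelError(
                f"cofactor_policy must be 'merged' or 'split', "
                f"got {self.cofactor_policy!r}"
            )
        if self.atp_per_nadh < 0:
            raise ModelError("atp_per_nadh must be non-negative")
        met_ids = [m.id for m in self.metabolites]
        dup = _first_duplicate(met_ids)
        if dup is not None:
            raise ModelError(f"duplicate metabolite id {dup!r}")
        rxn_ids = [r.id for r in self.reactions]
        dup = _first_duplicate(rxn_ids)
        if dup is not None:
            raise ModelError(f"duplicate reaction id {dup!r}")
        known = set(met_ids)
        by_id = {m.id: m for m in self.metabolites}
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelError(
                    f"reaction {r.id!r} references undeclared metabolite(s): "
                    f"{', '.join(sorted(missing))}"
                )
            if r.is_exchange:
                (met,) = r.stoichiometry
                if by_id[met].is_cofactor:
                    raise ModelError(
                        f"exchange reaction {r.id!r} touches cofactor {met!r}"
                    )

    # -- views --------------------------------------------------------------

    def stoichiometric_matrix(self):
        """Return (S, metabolite_ids, reaction_ids) with S as float ndarray."""
        import numpy as np

        met_index = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                S[met_index[met], j] = float(coeff)
        return S, self.metabolite_ids, self.reaction_ids

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=[r.copy() for r in self.reactions],
            atp_per_nadh=self.atp_per_nadh,
            cofactor_policy=self.cofactor_policy,
            name=self.name,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MetabolicModel):
            return NotImplemented
        return (
            self.metabolites == other.metabolites
            and len(self.reactions) == len(other.reactions)
            and all(
                a.id == b.id
                and a.stoichiometry == b.stoichiometry
                and a.lower_bound == b.lower_bound
                and a.upper_bound == b.upper_bound
                for a, b in zip(self.reactions, other.reactions)
            )
            and self.atp_per_nadh == other.atp_per_nadh
            and self.cofactor_policy == other.cofactor_policy
        )


def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# carbon bookkeeping
# ---------------------------------------------------------------------------


def carbon_balance(reaction: Reaction, model: MetabolicModel) -> Fraction:
    """Flux-weighted carbon sum of a reaction; 0 means carbon-balanced.

    Uses the moiety convention: carrier cofactors contribute the carbons of
    their carried group only (acetyl of AcCoA = 2, methylene of MTHF = 1,
    bare carriers = 0), so the sum runs over every metabolite.
    """
    total = Fraction(0)
    for met_id, coeff in reaction.stoichiometry.items():
        met = model.metabolite(met_id)  # raises UnknownIdError
        total += coeff * met.carbons
    return total


# ---------------------------------------------------------------------------
# curated network (transcribed pathway topology + textbook stoichiometry)
# ---------------------------------------------------------------------------

_M = Metabolite

_CURATED_METABOLITES: tuple[Metabolite, ...] = (
    _M("Glc", "D-glucose", 6, is_boundary=True),
    _M("PGA", "3-phosphoglycerate", 3),
    _M("PEP", "phosphoenolpyruvate", 3),
    _M("Pyr", "pyruvate", 3),
    _M("OAA", "oxaloacetate", 4),
    _M("Asp", "L-aspartate", 4),
    _M("Thr", "L-threonine", 4),
    _M("AKB", "2-amino-3-ketobutyrate", 4),
    _M("Gly", "glycine", 2),
    _M("Ser", "L-serine", 3),
    _M("Glu", "L-glutamate", 5),
    _M("AKG", "2-oxoglutarate", 5),
    _M("AcCoA", "acetyl-CoA (acetyl moiety)", 2, is_cofactor=True),
    _M("CoA", "coenzyme A", 0, is_cofactor=True),
    _M("THF", "tetrahydrofolate", 0, is_cofactor=True),
    _M("MTHF", "methylene-THF (methylene moiety)", 1, is_cofactor=True),
    _M("ATP", "ATP", 0, is_cofactor=True),
    _M("ADP", "ADP", 0, is_cofactor=True),
    _M("AMP", "AMP", 0, is_cofactor=True),
    _M("NAD", "NAD+", 0, is_cofactor=True),
    _M("NADH", "NADH", 0, is_cofactor=True),
    _M("NADP", "NADP+", 0, is_cofactor=True),
    _M("NADPH", "NADPH", 0, is_cofactor=True),
    _M("CO2", "carbon dioxide", 1, is_boundary=True),
    _M("NH4", "ammonium", 0, is_boundary=True),
    _M("Pi", "inorganic phosphate", 0, is_boundary=True),
    _M("O2", "molecular oxygen", 0, is_boundary=True),
    _M("H2O", "water", 0, is_boundary=True),
    _M("PHB", "3-hydroxybutyrate monomer", 4, is_boundary=True),
)

_F = Fraction


def _curated_reactions(
    atp_per_nadh: Fraction, bypass_active: bool, serB_active: bool
) -> list[Reaction]:
    p = Fraction(atp_per_nadh)
    big = DEFAULT_BOUND
    bypass_ub = big if bypass_active else 0.0
    serB_ub = big if serB_active else 0.0
    R = Reaction
    return [
        # exchanges (metabolite ->; negative flux = uptake)
        R("EX_glc", {"Glc": _F(-1)}, -10.0, big, "glucose exchange"),
        R("EX_o2", {"O2": _F(-1)}, -big, big, "oxygen exchange"),
        R("EX_co2", {"CO2": _F(-1)}, -big, big, "CO2 exchange"),
        R("EX_nh4", {"NH4": _F(-1)}, -big, big, "ammonium exchange"),
        R("EX_pi", {"Pi": _F(-1)}, -big, big, "phosphate exchange"),
        R("EX_h2o", {"H2O": _F(-1)}, -big, big, "water exchange"),
        R("EX_phb", {"PHB": _F(-1)}, 0.0, big, "PHB monomer sink"),
        # glycolysis, PTS-lumped: glucose -> 2 PGA + 2 NADH (0 net ATP)
        R(
            "emp",
            {"Glc": _F(-1), "NAD": _F(-2), "PGA": _F(2), "NADH": _F(2)},
            0.0,
            big,
            "EMP glycolysis to 3-phosphoglycerate (PTS convention)",
        ),
        R("eno", {"PGA": _F(-1), "PEP": _F(1), "H2O": _F(1)}, 0.0, big,
          "phosphoglycerate mutase + enolase"),
        R("pyk", {"PEP": _F(-1), "ADP": _F(-1), "Pyr": _F(1), "ATP": _F(1)},
          0.0, big, "pyruvate kinase"),
        R(
            "pdh",
            {"Pyr": _F(-1), "CoA": _F(-1), "NAD": _F(-1),
             "AcCoA": _F(1), "CO2": _F(1), "NADH": _F(1)},
            0.0, big, "pyruvate dehydrogenase complex",
        ),
        R("ppc", {"PEP": _F(-1), "CO2": _F(-1), "OAA": _F(1), "Pi": _F(1)},
          0.0, big, "PEP carboxylase"),
        R(
            "pps",
            {"Pyr": _F(-1), "ATP": _F(-1), "H2O": _F(-1),
             "PEP": _F(1), "AMP": _F(1), "Pi": _F(1)},
            0.0, big, "PEP synthase (ATP -> AMP, 2 ATP-equivalents)",
        ),
        R("adk", {"ATP": _F(-1), "AMP": _F(-1), "ADP": _F(2)}, -big, big,
          "adenylate kinase"),
        R("aspC", {"OAA": _F(-1), "Glu": _F(-1), "Asp": _F(1), "AKG": _F(1)},
          -big, big, "aspartate transaminase"),
        R(
            "gdh",
            {"AKG": _F(-1), "NH4": _F(-1), "NADPH": _F(-1),
             "Glu": _F(1), "NADP": _F(1), "H2O": _F(1)},
            0.0, big, "glutamate dehydrogenase (NADPH)",
        ),
        R(
            "thr_synth",
            {"Asp": _F(-1), "ATP": _F(-2), "NADPH": _F(-2),
             "Thr": _F(1), "ADP": _F(2), "NADP": _F(2), "Pi": _F(2)},
            0.0, big, "threonine synthesis from aspartate (5 steps, lumped)",
        ),
        R("tdh", {"Thr": _F(-1), "NAD": _F(-1), "AKB": _F(1), "NADH": _F(1)},
          0.0, bypass_ub, "threonine dehydrogenase"),
        R("kbl", {"AKB": _F(-1), "CoA": _F(-1), "AcCoA": _F(1), "Gly": _F(1)},
          0.0, bypass_ub, "2-amino-3-ketobutyrate CoA ligase"),
        R(
            "glyA",
            {"Gly": _F(-1), "MTHF": _F(-1), "H2O": _F(-1),
             "Ser": _F(1), "THF": _F(1)},
            0.0, big, "serine hydroxymethyltransferase (glycine -> serine)",
        ),
        R(
            "gcv",
            {"Gly": _F(-1), "THF": _F(-1), "NAD": _F(-1),
             "MTHF": _F(1), "CO2": _F(1), "NH4": _F(1), "NADH": _F(1)},
            0.0, big, "glycine cleavage system",
        ),
        R("sdaA", {"Ser": _F(-1), "Pyr": _F(1), "NH4": _F(1)}, 0.0, big,
          "serine deaminase"),
        R(
            "serB",
            {"PGA": _F(-1), "NAD": _F(-1), "Glu": _F(-1),
             "Ser": _F(1), "NADH": _F(1), "AKG": _F(1), "Pi": _F(1)},
            0.0, serB_ub, "serine de novo synthesis from PGA (serA/serC/serB, lumped)",
        ),
        R(
            "phaCAB",
            {"AcCoA": _F(-2), "NADPH": _F(-1),
             "PHB": _F(1), "CoA": _F(2), "NADP": _F(1)},
            0.0, big, "PHB monomer synthesis (phaA/phaB/phaC, lumped)",
        ),
        R(
            "resp",
            {"NADH": _F(-1), "O2": _F(-1, 2), "ADP": -p, "Pi": -p,
             "NAD": _F(1), "ATP": p, "H2O": _F(1)},
            0.0, big, "lumped respiration (atp_per_nadh ATP per NADH)",
        ),
        R("atpm", {"ATP": _F(-1), "H2O": _F(-1), "ADP": _F(1), "Pi": _F(1)},
          0.0, big, "ATP hydrolysis drain"),
        R("pntAB", {"NADH": _F(-1), "NADP": _F(-1), "NAD": _F(1), "NADPH": _F(1)},
          -big, big, "transhydrogenase"),
    ]


#: default P/O ratio.  The one free energetic parameter of the network is
#: calibrated so that the bypass-active FBA optimum reproduces the
#: established theoretical PHB yield of 1.26 mol/mol glucose exactly
#: (the optimum is 1 + (2+3p)/(12+9p) mol/mol at P/O ratio p, which
#: equals 63/50 at p = 56/33 ≈ 1.70 — an effective aerobic P/O well
#: inside the range measured for E. coli).
DEFAULT_ATP_PER_NADH = Fraction(56, 33)


def build_curated_model(
    atp_per_nadh: Fraction | float = DEFAULT_ATP_PER_NADH,
    bypass_active: bool = True,
    serB_active: bool = True,
    cofactor_policy: str = "merged",
) -> MetabolicModel:
    """Build the curated core network.

    Parameters
    ----------
    atp_per_nadh
        P/O ratio of the lumped respiration reaction; the default is
        calibrated to reproduce the 1.26 mol/mol theoretical yield
        (see :data:`DEFAULT_ATP_PER_NADH`).
    bypass_active
        When False, the threonine-degradation reactions (tdh, kbl) are
        closed to [0, 0] — the wild-type repression of the kbl-tdh operon.
    serB_active
        When False, the serine de novo branch from 3-phosphoglycerate is
        closed (a serB knockout).
    cofactor_policy
        "merged" keeps an unbounded reversible transhydrogenase so NADH and
        NADPH are interchangeable; "split" removes it.
    """
    p = Fraction(atp_per_nadh)
    if p < 0:
        raise ModelError("atp_per_nadh must be non-negative")
    reactions = _curated_reactions(p, bypass_active, serB_active)
    if cofactor_policy == "split":
        reactions = [r for r in reactions if r.id != "pntAB"]
    return MetabolicModel(
        metabolites=list(_CURATED_METABOLITES),
        reactions=reactions,
        atp_per_nadh=p,
        cofactor_policy=cofactor_policy,
        name="curated threonine-bypass core network",
    )


# ---------------------------------------------------------------------------
# serialization: equation strings, TSV pair, YAML/JSON single file
# ---------------------------------------------------------------------------


def _format_coeff(c: Fraction) -> str:
    c = Fraction(c)
    return str(c)  # "2", "5/2", ...


def format_equation(stoichiometry: Mapping[str, Fraction]) -> str:
    """Render signed stoichiometry as ``"A + 2 B -> C"`` (exact rationals)."""
    lhs, rhs = [], []
    for met, coeff in stoichiometry.items():
        coeff = Fraction(coeff)
        if coeff == 0:
            continue
        side = rhs if coeff > 0 else lhs
        mag = abs(coeff)
        side.append(met if mag == 1 else f"{_format_coeff(mag)} {met}")
    return f"{' + '.join(lhs)} -> {' + '.join(rhs)}"


def parse_equation(text: str) -> dict[str, Fraction]:
    """Parse ``"A + 2 B -> C"`` back into signed stoichiometry."""
    if "->" not in text:
        raise ModelError(f"equation {text!r} lacks '->'")
    lhs_text, rhs_text = text.split("->", 1)
    stoich: dict[str, Fraction] = {}

    def add_side(side_text: str, sign: int) -> None:
        side_text = side_text.strip()
        if not side_text:
            return
        for term in side_text.split(" + "):
            term = term.strip()
            if not term:
                continue
            parts = term.split()
            if len(parts) == 1:
                coeff, met = Fraction(1), parts[0]
            elif len(parts) == 2:
                coeff, met = Fraction(parts[0]), parts[1]
            else:
                raise ModelError(f"cannot parse equation term {term!r}")
            stoich[met] = stoich.get(met, Fraction(0)) + sign * coeff

    add_side(lhs_text, -1)
    add_side(rhs_text, +1)
    return {m: c for m, c in stoich.items() if c != 0}


def _model_to_dict(model: MetabolicModel) -> dict:
    return {
        "name": model.name,
        "atp_per_nadh": str(model.atp_per_nadh),
        "cofactor_policy": model.cofactor_policy,
        "metabolites": [
            {
                "id": m.id,
                "name": m.name,
                "carbons": m.carbons,
                "is_cofactor": m.is_cofactor,
                "is_boundary": m.is_boundary,
            }
            for m in model.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                "name": r.name,
                "equation": format_equation(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
            }
            for r in model.reactions
        ],
    }


def _model_from_dict(data: Mapping) -> MetabolicModel:
    try:
        met_rows = data["metabolites"]
        rxn_rows = data["reactions"]
    except KeyError as exc:
        raise ModelError(f"model document lacks section {exc}") from None
    if not rxn_rows:
        raise ModelError("no reactions in model document")
    metabolites = [
        Metabolite(
            id=row["id"],
            name=row.get("name", ""),
            carbons=int(row.get("carbons", 0)),
            is_cofactor=bool(row.get("is_cofactor", False)),
            is_boundary=bool(row.get("is_boundary", False)),
        )
        for row in met_rows
    ]
    reactions = []
    for row in rxn_rows:
        try:
            stoich = parse_equation(row["equation"])
        except (ModelError, ValueError) as exc:
            raise ModelError(f"reaction {row.get('id')!r}: {exc}") from exc
        reactions.append(
            Reaction(
                id=row["id"],
                stoichiometry=stoich,
                lower_bound=float(row["lower_bound"]),
                upper_bound=float(row["upper_bound"]),
                name=row.get("name", ""),
            )
        )
    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        atp_per_nadh=Fraction(str(data.get("atp_per_nadh", "56/33"))),
        cofactor_policy=data.get("cofactor_policy", "merged"),
        name=data.get("name", ""),
    )


_MET_COLUMNS = ("id", "name", "carbons", "is_cofactor", "is_boundary")
_RXN_COLUMNS = ("id", "equation", "lower_bound", "upper_bound", "name")


def _write_tsv_dir(model: MetabolicModel, path: str) -> None:
    os.makedirs(path, exist_ok=True)
    data = _model_to_dict(model)
    with open(os.path.join(path, "metabolites.tsv"), "w") as fh:
        fh.write("\t".join(_MET_COLUMNS) + "\n")
        for row in data["metabolites"]:
            fh.write(
                "\t".join(
                    [row["id"], row["name"], str(row["carbons"]),
                     str(int(row["is_cofactor"])), str(int(row["is_boundary"]))]
                )
                + "\n"
            )
    with open(os.path.join(path, "reactions.tsv"), "w") as fh:
        fh.write("\t".join(_RXN_COLUMNS) + "\n")
        for row in data["reactions"]:
            fh.write(
                "\t".join(
                    [row["id"], row["equation"], repr(row["lower_bound"]),
                     repr(row["upper_bound"]), row["name"]]
                )
                + "\n"
            )
    with open(os.path.join(path, "model.yaml"), "w") as fh:
        yaml.safe_dump(
            {
                "name": data["name"],
                "atp_per_nadh": data["atp_per_nadh"],
                "cofactor_policy": data["cofactor_policy"],
            },
            fh,
            sort_keys=True,
        )


def _read_tsv_table(path: str, columns: tuple[str, ...]) -> list[dict]:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ModelError(f"{path}: empty table")
    header = lines[0].split("\t")
    if header != list(columns):
        raise ModelError(
            f"{path}: expected columns {list(columns)}, found {header}"
        )
    rows = []
    for i, ln in enumerate(lines[1:], start=2):
        fields = ln.split("\t")
        if len(fields) != len(columns):
            raise ModelError(f"{path}, line {i}: expected {len(columns)} fields")
        rows.append(dict(zip(columns, fields)))
    return rows


def _read_tsv_dir(path: str) -> MetabolicModel:
    met_rows = _read_tsv_table(os.path.join(path, "metabolites.tsv"), _MET_COLUMNS)
    rxn_rows = _read_tsv_table(os.path.join(path, "reactions.tsv"), _RXN_COLUMNS)
    meta_path = os.path.join(path, "model.yaml")
    meta = {}
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = yaml.safe_load(fh) or {}
    doc = {
        "name": meta.get("name", ""),
        "atp_per_nadh": meta.get("atp_per_nadh", "56/33"),
        "cofactor_policy": meta.get("cofactor_policy", "merged"),
        "metabolites": [
            {
                "id": r["id"],
                "name": r["name"],
                "carbons": int(r["carbons"]),
                "is_cofactor": bool(int(r["is_cofactor"])),
                "is_boundary": bool(int(r["is_boundary"])),
            }
            for r in met_rows
        ],
        "reactions": [
            {
                "id": r["id"],
                "equation": r["equation"],
                "lower_bound": float(r["lower_bound"]),
                "upper_bound": float(r["upper_bound"]),
                "name": r["name"],
            }
            for r in rxn_rows
        ],
    }
    return _model_from_dict(doc)


def write_model(model: MetabolicModel, path: str) -> None:
    """Write a model: ``.yaml``/``.yml``/``.json`` single file, else a
    directory holding ``metabolites.tsv`` + ``reactions.tsv`` (+ model.yaml)."""
    lower = path.lower()
    if lower.endswith((".yaml", ".yml")):
        with open(path, "w") as fh:
            yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False)
    elif lower.endswith(".json"):
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1)
    else:
        _write_tsv_dir(model, path)


def read_model(path: str) -> MetabolicModel:
    """Inverse of :func:`write_model`; round-trips models field-by-field."""
    lower = path.lower()
    if os.path.isdir(path):
        return _read_tsv_dir(path)
    with open(path) as fh:
        if lower.endswith((".yaml", ".yml")):
            data = yaml.safe_load(fh)
        elif lower.endswith(".json"):
            data = json.load(fh)
        else:
            raise ModelError(
                f"cannot infer model format of {path!r} "
                "(expected .yaml/.yml/.json or a TSV directory)"
            )
    if not isinstance(data, Mapping):
        raise ModelError(f"{path}: not a model document")
    return _model_from_dict(data)


def read_sbml(path: str) -> MetabolicModel:  # pragma: no cover - documented stub
    """SBML import is a documented non-goal of this package."""
    raise NotImplementedError(
        "SBML import is out of scope; use the YAML/JSON or TSV exchange format"
    )


def write_sbml(model: MetabolicModel, path: str) -> None:  # pragma: no cover
    """SBML export is a documented non-goal of this package."""
    raise NotImplementedError(
        "SBML export is out of scope; use the YAML/JSON or TSV exchange format"
    )


# ---------------------------------------------------------------------------
# packaged manifests
# ---------------------------------------------------------------------------


def curated_manifest_path() -> str:
    """Path of the packaged curated-model manifest (TSV directory)."""
    from importlib.resources import files

    return str(files("thrbypass").joinpath("data", "curated"))


def thr_synthesis_steps_model() -> MetabolicModel:
    """The five-step threonine-synthesis expansion as a mini model.

    Loads the packaged alternate manifest (aspartokinase, aspartate-
    semialdehyde dehydrogenase, homoserine dehydrogenase, homoserine
    kinase, threonine synthase); lumping the five steps at unit flux with
    the intermediates internal must reproduce the one-reaction form used
    in the curated model (Asp + 2 ATP + 2 NADPH -> Thr + ...).
    """
    from importlib.resources import files

    path = files("thrbypass").joinpath("data", "thr_synthesis_steps.tsv")
    with path.open() as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = lines[0].split("\t")
    if header != ["reaction_id", "equation"]:
        raise ModelError("thr_synthesis_steps.tsv: unexpected header")
    extra = [
        _M("A4P", "aspartyl-4-phosphate", 4),
        _M("ASA", "aspartate semialdehyde", 4),
        _M("Hser", "homoserine", 4),
        _M("PHS", "homoserine phosphate", 4),
    ]
    reactions = []
    for ln in lines[1:]:
        rid, eq = ln.split("\t")
        reactions.append(Reaction(rid, parse_equation(eq), 0.0, DEFAULT_BOUND))
    return MetabolicModel(
        metabolites=list(_CURATED_METABOLITES) + extra,
        reactions=reactions,
        atp_per_nadh=DEFAULT_ATP_PER_NADH,
        cofactor_policy="split",
        name="five-step threonine synthesis expansion",
    )
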