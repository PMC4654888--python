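"""Desk-scale synthetic inputs for exercising every stage of the pipeline.

Two generators:

* :func:`random_network` builds small random stoichiometric networks with a
  *planted* substrate-to-product path whose optimal yield is known by
  construction, so LP results can be checked against brute-force
  enumeration of the flux polytope's vertices.
* :func:`perturb_curated` produces sensitivity companions of the curated
  network (respiration removed, cofactor pools split, an unbalanced CO2
  source for negative-control carbon checks).

All randomness flows through one :class:`numpy.random.Generator` seeded
from the spec, so fixtures regenerate identically across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import (
    DEFAULT_BOUND,
    MetabolicModel,
    Metabolite,
    ModelError,
    Reaction,
)

__all__ = ["FixtureSpec", "random_network", "perturb_curated"]

_MET_RANGE = (3, 8)
_RXN_RANGE = (4, 12)
_MAX_COEFF = 4


@dataclass(frozen=True)
class FixtureSpec:
    """Size, seed and designed optimal yield of a random network fixture."""

    n_metabolites: int = 5
    n_reactions: int = 8
    seed: int = 0
    planted_path_yield: Fraction = Fraction(2)

    def __post_init__(self) -> None:
        lo, hi = _MET_RANGE
        if not lo <= self.n_metabolites <= hi:
            raise ModelError(
                f"n_metabolites must be in [{lo}, {hi}], got {self.n_metabolites}"
            )
        lo, hi = _RXN_RANGE
        if not lo <= self.n_reactions <= hi:
            raise ModelError(
                f"n_reactions must be in [{lo}, {hi}], got {self.n_reactions}"
            )
        q = Fraction(self.planted_path_yield)
        if not (1 <= q.numerator <= _MAX_COEFF and 1 <= q.denominator <= _MAX_COEFF):
            raise ModelError(
                "planted_path_yield must be a ratio of integers in [1, 4], "
                f"got {q}"
            )
        object.__setattr__(self, "planted_path_yield", q)


def random_network(spec: FixtureSpec) -> MetabolicModel:
    """Generate a random network whose LP optimum equals the planted yield.

    Layout: substrate S (uptake capped at 1), one amplifying reaction
    ``den S -> num X1`` realizing the planted yield num/den, a 1:1 step
    ``X1 -> P``, and product exchange.  Remaining metabolites are decoys
    and remaining reactions are distractors that, by construction, can
    never beat the planted path: they either convert X1/decoys into decoys
    (dead ends without exchanges) or convert X1 to P at a strictly worse
    ratio.  All coefficients are small integers (|c| <= 4) and all bounds
    finite, so the flux polytope is compact and vertex-enumerable.
    """
    rng = np.random.default_rng(spec.seed)
    q = spec.planted_path_yield
    k, n = spec.n_metabolites, spec.n_reactions

    met_ids = ["S", "X1", "P"] + [f"D{i}" for i in range(1, k - 2)]
    decoys = met_ids[3:]
    metabolites = [
        Metabolite("S", "substrate", carbons=q.numerator, is_boundary=True),
        Metabolite("X1", "intermediate", carbons=q.denominator),
        Metabolite("P", "product", carbons=q.denominator, is_boundary=True),
    ] + [Metabolite(d, "decoy", carbons=1) for d in decoys]

    reactions = [
        Reaction("EX_S", {"S": Fraction(-1)}, -1.0, 0.0, "substrate uptake"),
        Reaction("EX_P", {"P": Fraction(-1)}, 0.0, 16.0, "product secretion"),
        Reaction(
            "plant",
            {"S": Fraction(-q.denominator), "X1": Fraction(q.numerator)},
            0.0,
            8.0,
            "planted amplifying step",
        ),
        Reaction("chain", {"X1": Fraction(-1), "P": Fraction(1)}, 0.0, 8.0,
                 "planted 1:1 step"),
    ]

    sources = ["X1"] + decoys
    for i in range(n - 4):
        kind = rng.integers(0, 3) if decoys else 2
        if kind == 0:  # drain into a decoy (dead end)
            src = sources[rng.integers(0, len(sources))]
            choices = [d for d in decoys if d != src]
            dst = choices[rng.integers(0, len(choices))] if choices else None
            if dst is None:
                kind = 2
            else:
                a = int(rng.integers(1, _MAX_COEFF + 1))
                b = int(rng.integers(1, _MAX_COEFF + 1))
                reactions.append(
                    Reaction(
                        f"dis{i}",
                        {src: Fraction(-a), dst: Fraction(b)},
                        0.0,
                        2.0,
                        "distractor drain",
                    )
                )
                continue
        if kind == 1 and len(decoys) >= 2:
            # decoy-to-decoy conversion (possibly reversible); decoys never
            # reach P, so these cycles cannot raise the optimum
            src = decoys[rng.integers(0, len(decoys))]
            choices = [d for d in decoys if d != src]
            dst = choices[rng.integers(0, len(choices))]
            lb = -2.0 if rng.random() < 0.5 else 0.0
            reactions.append(
                Reaction(
                    f"dis{i}",
                    {src: Fraction(-1), dst: Fraction(1)},
                    lb,
                    2.0,
                    "distractor conversion",
                )
            )
            continue
        # kind == 2: strictly-worse parallel route X1 -> P
        a = int(rng.integers(2, _MAX_COEFF + 1))
        reactions.append(
            Reaction(
                f"dis{i}",
                {"X1": Fraction(-a), "P": Fraction(1)},
                0.0,
                2.0,
                "distractor inefficient route",
            )
        )

    return MetabolicModel(
        metabolites=metabolites,
        reactions=reactions,
        atp_per_nadh=Fraction(5, 2),
        cofactor_policy="split",
        name=f"random fixture seed={spec.seed}",
    )


_PERTURBATIONS = ("drop_respiration", "split_cofactors", "free_co2")


def perturb_curated(model: MetabolicModel, which: str) -> MetabolicModel:
    """Sensitivity companions of the curated model.

    * ``drop_respiration`` — close the lumped respiration reaction to
      [0, 0].  With glucose uptake pinned, the model then has no NADH sink
      and becomes infeasible; with free uptake, only redox-neutral modes
      remain.
    * ``split_cofactors`` — remove the transhydrogenase, separating the
      NADH and NADPH pools (a constraint addition, so yields cannot rise).
    * ``free_co2`` — add an unbalanced CO2 source reaction, a designed
      carbon-conservation violation for negative-control tests.
    """
    if which not in _PERTURBATIONS:
        raise ValueError(
            f"unknown perturbation {which!r}; expected one of {_PERTURBATIONS}"
        )
    m = model.copy()
    if which == "drop_respiration":
        resp = m.reaction("resp")
        resp.lower_bound = 0.0
        resp.upper_bound = 0.0
        return m
    if which == "split_cofactors":
        m.reactions = [r for r in m.reactions if r.id != "pntAB"]
        m.cofactor_policy = "split"
        return m
    m.reactions.append(
        Reaction("co2_source", {"CO2": Fraction(1)}, 0.0, DEFAULT_BOUND,
                 "unbalanced CO2 source (designed violation)")
    )
    m.validate()
    return m
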