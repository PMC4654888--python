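"""Engineered-strain scenarios as reaction-bound edits on the curated model.

The scenarios mirror the genotype ladder of the engineered strains: the
wild type (JM109) with the threonine/serine degradation steps repressed,
then successive derepression of threonine degradation (tdh/kbl), serine
deamination (sdaA), knockout of the serine de novo branch (serB), and
derepression of threonine synthesis, PEP carboxylase, serine
hydroxymethyltransferase and transhydrogenase.

This is a yield-potential model: promoter swaps become bound relaxations
(flux capacity), never expression levels — FBA sees only bounds.  A
consequence worth noting: a pure yield model cannot reproduce measured
*decreases* after a bound relaxation (as observed for gcv
overexpression); see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .core import (
    DEFAULT_ATP_PER_NADH,
    MetabolicModel,
    UnknownIdError,
    build_curated_model,
)
from .fba import YieldResult, compute_yield

__all__ = [
    "Edit",
    "ScenarioSpec",
    "builtin_scenarios",
    "apply_scenario",
    "wild_type_model",
    "scenario_yields",
]

_ACTIONS = ("activate", "deactivate", "derepress")


@dataclass(frozen=True)
class Edit:
    """One reaction-bound edit: open ('activate'/'derepress') or close."""

    reaction_id: str
    action: str
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.action not in _ACTIONS:
            raise ValueError(
                f"action must be one of {_ACTIONS}, got {self.action!r}"
            )


@dataclass(frozen=True)
class ScenarioSpec:
    """A named strain genotype mapped to model edits."""

    name: str
    edits: tuple[Edit, ...]
    description: str = ""


# curated default bounds, used as the "fully derepressed" target of
# activate/derepress edits (computed once from a fresh bypass-active build)
_DEFAULTS = {
    r.id: (r.lower_bound, r.upper_bound)
    for r in build_curated_model(bypass_active=True, serB_active=True).reactions
}


def wild_type_model(
    atp_per_nadh: Fraction | float = DEFAULT_ATP_PER_NADH,
    cofactor_policy: str = "merged",
) -> MetabolicModel:
    """The JM109 baseline: curated model with tdh, kbl and sdaA closed.

    The degradation operon (kbl-tdh) and serine deaminase are repressed by
    feedback regulation in the wild type, so their bounds are [0, 0]; every
    other reaction is open.
    """
    m = build_curated_model(
        atp_per_nadh=atp_per_nadh,
        bypass_active=False,
        serB_active=True,
        cofactor_policy=cofactor_policy,
    )
    sdaA = m.reaction("sdaA")
    sdaA.lower_bound = sdaA.upper_bound = 0.0
    return m


def builtin_scenarios() -> list[ScenarioSpec]:
    """The strain ladder, each spec cumulative relative to the wild type."""
    open_ = lambda rid: Edit(rid, "derepress")
    close = lambda rid: Edit(rid, "deactivate")
    tb01 = (open_("tdh"), open_("kbl"))
    tb02 = tb01 + (open_("sdaA"),)
    tb05 = tb02 + (close("serB"),)
    tb07 = tb05 + (open_("thr_synth"),)
    tb09 = tb07 + (open_("ppc"),)
    tb13 = tb09 + (open_("glyA"),)
    tb17 = tb13 + (open_("pntAB"),)
    return [
        ScenarioSpec("JM109", (), "wild type; threonine degradation repressed"),
        ScenarioSpec("TB01", tb01, "kbl-tdh operon under constitutive promoter"),
        ScenarioSpec("TB02", tb02, "TB01 + sdaA derepressed"),
        ScenarioSpec("TB05", tb05, "TB02 + serB knocked out"),
        ScenarioSpec("TB07", tb07, "TB05 + threonine synthesis derepressed"),
        ScenarioSpec("TB09", tb09, "TB07 + ppc overexpressed"),
        ScenarioSpec("TB13", tb13, "TB09 + glyA overexpressed"),
        ScenarioSpec("TB17", tb17, "TB13 + transhydrogenase overexpressed"),
    ]


def apply_scenario(model: MetabolicModel, spec: ScenarioSpec) -> MetabolicModel:
    """Return an edited copy of ``model``; idempotent and order-independent
    for the builtin specs (each edit sets absolute bounds)."""
    m = model.copy()
    for edit in spec.edits:
        if not m.has_reaction(edit.reaction_id):
            raise UnknownIdError(
                f"scenario {spec.name!r}: edit references unknown reaction "
                f"{edit.reaction_id!r}"
            )
        r = m.reaction(edit.reaction_id)
        if edit.action == "deactivate":
            r.lower_bound, r.upper_bound = 0.0, 0.0
        else:  # activate / derepress: widen to explicit or curated defaults
            if edit.bounds is not None:
                r.lower_bound, r.upper_bound = edit.bounds
            else:
                r.lower_bound, r.upper_bound = _DEFAULTS[edit.reaction_id]
    return m


def scenario_yields(
    base_model: MetabolicModel | None = None,
    glucose_uptake: float = 10.0,
    specs: list[ScenarioSpec] | None = None,
) -> list[tuple[str, YieldResult]]:
    """Predicted maximal PHB yield per scenario, in ladder order."""
    if base_model is None:
        base_model = wild_type_model()
    if specs is None:
        specs = builtin_scenarios()
    out = []
    for spec in specs:
        edited = apply_scenario(base_model, spec)
        out.append((spec.name, compute_yield(edited, glucose_uptake=glucose_uptake)))
    return out
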