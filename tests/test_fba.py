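"""LP solving, yields, knockouts and flux variability."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thrbypass import (
    GLUCOSE_MASS,
    PHB_MONOMER_MASS,
    InfeasibleModelError,
    UnknownIdError,
    apply_knockout,
    build_curated_model,
    compute_yield,
    flux_ranges,
    solve_fba,
)


def test_linear_chain_secretes_at_uptake_capacity(linear_chain):
    sol = solve_fba(linear_chain, "EX_B", "max")
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(5.0, abs=1e-9)


def test_objective_without_source_is_zero_not_infeasible(linear_chain):
    """With bounds straddling zero the zero vector is feasible, so a
    product with no source reports optimal 0 rather than infeasibility."""
    m = linear_chain.copy()
    m.reaction("EX_A").lower_bound = 0.0  # no substrate any more
    sol = solve_fba(m, "EX_B", "max")
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)


def test_unknown_objective_raises(linear_chain):
    with pytest.raises(UnknownIdError, match="nope"):
        solve_fba(linear_chain, "nope")


def _steady_state_residual(model, fluxes):
    S, mets, rxns = model.stoichiometric_matrix()
    v = np.array([fluxes[r] for r in rxns])
    return np.max(np.abs(S @ v))


def test_curated_optimum_is_a_steady_state(curated_on):
    res = compute_yield(curated_on)
    assert _steady_state_residual(curated_on, res.solution.fluxes) <= 1e-6
    lo = {r.id: r.lower_bound for r in curated_on.reactions}
    hi = {r.id: r.upper_bound for r in curated_on.reactions}
    for rid, v in res.solution.fluxes.items():
        if rid == "EX_glc":
            continue  # pinned by compute_yield
        assert lo[rid] - 1e-9 <= v <= hi[rid] + 1e-9


@settings(derandomize=True, max_examples=25, deadline=None)
@given(uptake=st.floats(min_value=0.1, max_value=100.0))
def test_mol_yield_is_scale_free_in_glucose_uptake(uptake):
    """LP homogeneity: the molar yield is invariant to the uptake rate."""
    model = build_curated_model()
    res = compute_yield(model, glucose_uptake=uptake)
    assert res.mol_yield == pytest.approx(1.26, abs=1e-6)


def test_mass_yield_consistent_with_mol_yield(curated_on):
    res = compute_yield(curated_on)
    assert res.mass_yield == pytest.approx(
        res.mol_yield * PHB_MONOMER_MASS / GLUCOSE_MASS, abs=1e-9
    )


def test_knockout_of_serB_equals_building_without_it():
    with_ko = apply_knockout(build_curated_model(serB_active=True), ["serB"])
    built = build_curated_model(serB_active=False)
    assert compute_yield(with_ko).mol_yield == pytest.approx(
        compute_yield(built).mol_yield, abs=1e-9
    )


def test_knockout_of_objective_gives_zero_production(curated_on):
    """With the product sink closed, max production is 0 when uptake is a
    capacity; with uptake pinned at 10 the carbon has no exit and the
    pinned problem is reported infeasible rather than silently zero."""
    ko = apply_knockout(curated_on, ["EX_phb"])
    sol = solve_fba(ko, "EX_phb", "max")  # EX_glc keeps its -10 capacity
    assert sol.status == "optimal"
    assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(InfeasibleModelError):
        compute_yield(ko)


def test_knockout_of_tdh_reverts_to_classical_yield(curated_on):
    """The bypass requires threonine dehydrogenase; without it the optimum
    is the classical pyruvate-dehydrogenase yield of 1.0 mol/mol."""
    ko = apply_knockout(curated_on, ["tdh"])
    assert compute_yield(ko).mol_yield == pytest.approx(1.0, abs=1e-9)


def test_knockout_leaves_original_untouched(curated_on):
    before = curated_on.reaction("tdh").upper_bound
    apply_knockout(curated_on, ["tdh"])
    assert curated_on.reaction("tdh").upper_bound == before


def test_knockout_unknown_ids_listed():
    m = build_curated_model()
    with pytest.raises(UnknownIdError, match="ghost1.*ghost2"):
        apply_knockout(m, ["ghost2", "ghost1"])


def test_flux_ranges_unique_optimum_collapses_to_points(linear_chain):
    ranges = flux_ranges(linear_chain, "EX_B", fraction=1.0)
    for rid, (lo, hi) in ranges.items():
        assert hi - lo == pytest.approx(0.0, abs=1e-6), rid


def test_bypass_is_required_at_the_optimum(curated_on):
    """tdh must carry flux in every optimal solution (min flux > 0)."""
    ranges = flux_ranges(curated_on, "EX_phb", fraction=1.0, reactions=["tdh"])
    lo, hi = ranges["tdh"]
    assert lo > 1.0  # far from zero at glucose uptake bound 10


def test_relaxed_fraction_encloses_optimal_ranges(curated_on):
    tight = flux_ranges(curated_on, "EX_phb", 1.0, reactions=["tdh", "pyk"])
    loose = flux_ranges(curated_on, "EX_phb", 0.5, reactions=["tdh", "pyk"])
    for rid in tight:
        assert loose[rid][0] <= tight[rid][0] + 1e-6
        assert loose[rid][1] >= tight[rid][1] - 1e-6


def test_relaxing_a_bound_never_decreases_the_optimum(curated_on):
    base = compute_yield(curated_on).mol_yield
    relaxed = curated_on.copy()
    relaxed.reaction("glyA").upper_bound *= 2
    assert compute_yield(relaxed).mol_yield >= base - 1e-9


def test_bypass_enabled_yield_dominates_disabled(curated_on, curated_off):
    assert (
        compute_yield(curated_on).mol_yield
        >= compute_yield(curated_off).mol_yield - 1e-9
    )


def test_infeasible_model_raises_not_silent_zero(curated_on):
    m = curated_on.copy()
    # force PHB secretion above what fixed glucose can support
    m.reaction("EX_phb").lower_bound = 100.0
    m.reaction("EX_phb").upper_bound = 1000.0
    with pytest.raises(InfeasibleModelError):
        compute_yield(m)


# --------------------------------------------------------------------------
# independent cross-check with an external FBA implementation
# --------------------------------------------------------------------------


def _to_cobra(model):
    import cobra

    cm = cobra.Model("check")
    mets = {m.id: cobra.Metabolite(m.id) for m in model.metabolites}
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id)
        cr.lower_bound = r.lower_bound
        cr.upper_bound = r.upper_bound
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r, cr in zip(model.reactions, rxns):
        cr.add_metabolites(
            {mets[mid]: float(c) for mid, c in r.stoichiometry.items()}
        )
    return cm


@pytest.mark.parametrize(
    "bypass, expected", [(True, 63 / 50), (False, 1.0)],
    ids=["bypass", "classical"],
)
def test_yield_agrees_with_cobrapy_oracle(bypass, expected):
    """The same LP solved by an independent stack (cobrapy/glpk) agrees."""
    model = build_curated_model(bypass_active=bypass)
    glc = model.reaction("EX_glc")
    glc.lower_bound = glc.upper_bound = -10.0
    cm = _to_cobra(model)
    cm.objective = "EX_phb"
    sol = cm.optimize()
    assert sol.status == "optimal"
    assert sol.objective_value / 10.0 == pytest.approx(expected, abs=1e-6)
    assert compute_yield(model).mol_yield == pytest.approx(
        sol.objective_value / 10.0, abs=1e-6
    )
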