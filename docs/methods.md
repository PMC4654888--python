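# Methods

## Scope and model form

`thrbypass` implements a desk-scale constraint-based model of the
threonine bypass: a curated core network rather than a genome-scale
reconstruction. There are no gene–protein–reaction rules, no biomass
objective and no growth-associated maintenance; the model answers one
question — the maximal stoichiometric (theoretical) yield of PHB monomer
on glucose and how the threonine-degradation route changes it.

The network has 29 metabolites and 27 reactions:

* **Glycolysis, PTS-lumped.** Glucose import by the phosphotransferase
  system spends one PEP, so the lump is
  `Glc + 2 NAD+ -> 2 PGA + 2 NADH` followed by `PGA -> PEP` with **zero**
  net ATP; pyruvate kinase then supplies the "+ ATP" of the classical
  PEP → acetyl-CoA equation. This convention keeps the printed classical
  equation exact at the cost of slightly generous ATP accounting (a real
  PTS cell converts one of the two PEP without the kinase step).
* **Threonine synthesis** is lumped to
  `Asp + 2 ATP + 2 NADPH -> Thr + 2 ADP + 2 NADP+ + 2 Pi`; the packaged
  five-step expansion (aspartokinase → threonine synthase) lumps to the
  identical net reaction and is tested to.
* **Nitrogen** enters through NADPH-dependent glutamate dehydrogenase and
  is fully recycled inside the bypass cycle (glycine cleavage and serine
  deaminase release what aspartate formation consumes).
* **PEP synthase** is costed as ATP → AMP; adenylate kinase restores AMP,
  making the step worth two ATP equivalents.
* **Respiration** is one lumped reaction
  `NADH + ½ O2 + p·ADP + p·Pi -> NAD+ + p·ATP + H2O` with `p =
  atp_per_nadh` (the P/O ratio), plus a free ATP-hydrolysis drain
  (`atpm`) so that surplus ATP can be dissipated; without such a drain
  the classical (bypass-off) case has no steady state at a pinned glucose
  uptake. The drain has bounds [0, ∞) — it is not a maintenance demand.
* **Cofactor policy.** `merged` (default) includes an unbounded
  reversible transhydrogenase, making NADH and NADPH equivalent; `split`
  removes it. All printed-yield computations use `merged`.
* **Oxygen** is unbounded; nothing in the in-scope computations
  constrains it.

Coefficients are `fractions.Fraction`; equation strings, the TSV pair
format and the YAML/JSON single-file format round-trip them exactly.
Water and phosphate are carried loosely (both are freely exchanged
boundary species) and free protons are not tracked: the model balances
carbon, nitrogen, redox and adenylates, which is what the yield
computation needs. Printed equations omit Pi and H₂O.

## Carbon bookkeeping

Carrier cofactors are counted by their transferable moiety: acetyl-CoA
contributes 2 carbons, methylene-THF 1, bare CoA/THF/adenylates/
pyridine nucleotides 0. Carbon balance of a reaction (or of a lumped net
reaction) is then a plain coefficient-weighted sum over every metabolite;
all 20 non-exchange curated reactions sum to zero, and the
`free_co2` perturbation exists as a designed violation that the check
must catch.

## The LP and its tolerances

`solve_fba` minimizes/maximizes one flux with scipy's HiGHS dual simplex
(`method="highs-ds"`), which is deterministic for a fixed model. Primal
feasibility is at solver default (≈1e-9); results are asserted at 1e-6.
The zero flux vector is feasible whenever all bound intervals contain
zero, so an objective with no source reports `optimal` at 0 —
infeasibility is reserved for genuinely empty polytopes (e.g. pinned
glucose with no redox sink). Alternative optima are not resolved
lexicographically; flux-level statements are made through `flux_ranges`
(flux variability at a fraction of the optimum).

## Calibration of the P/O ratio

The single free energetic parameter is `atp_per_nadh`. Reducing the LP by
hand (PEP split between pyruvate kinase and PEP carboxylase, redox and
adenylate balances) gives the closed-form optimum

```
yield(p) = 1 + (2 + 3p) / (12 + 9p)   mol PHB / mol glucose
```

monotone in `p`, 7/6 at `p = 0`, asymptote 4/3. The default is the value
that makes the optimum exactly 63/50 = 1.26, the established theoretical
bypass yield: `p = 56/33 ≈ 1.70`, a plausible effective aerobic P/O for
*E. coli* (textbook range roughly 1.3–2). The closed form doubles as an
independent oracle in the test suite. At `p = 0` the bypass is still
partially used — pyruvate-kinase ATP from the classical branch funds it —
which is why the yield floor is 7/6, not 1.0.

A noteworthy structural result of the LP: at the optimum the
serine-deaminase pyruvate is **not** recycled to PEP by PEP synthase
(`pps` carries zero flux in every optimal solution); sending it through
pyruvate dehydrogenase is strictly cheaper in ATP. The published cycle
scheme closes through PEP synthase, and `derive_bypass_fluxes` solves
exactly that closed sub-network (PEP input normalized to 1, all
intermediates balanced; solved exactly over the rationals, uniqueness
checked via the null space), reproducing the cycle's net equation

```
PEP + CO2 + 2 CoA + 3 NAD(P)H + 6 ATP -> 2 AcCoA + 3 NAD(P) + 6 ADP
```

Before cofactor merging the model's redox split is 6 NADPH + 3 NAD⁺
consumed per PEP (NADPH-dependent nitrogen assimilation); other
assignments of the nitrogen route shift the split while leaving the
merged cost of 3 reducing equivalents unchanged, so only the merged form
is treated as canonical. Adenylates are conserved exactly: 6 ATP in,
6 ADP out.

## Scenarios

Strain genotypes are bound edits on the wild-type baseline (tdh, kbl and
sdaA closed; everything else open): `deactivate` sets [0, 0],
`derepress`/`activate` restores the curated default bounds. The ladder
JM109 → TB01 → TB02 → TB05 → TB07 → TB09 → TB13 → TB17 is cumulative and
its predicted maximal yields are non-decreasing (1.0, 1.0, then 1.26
throughout): once tdh/kbl *and* sdaA are open the cycle is complete and
every later derepression widens bounds that are not binding. This is the
model's honest resolution: a yield-potential model cannot show the
measured superiority of TB17 over TB02-TB13 (NADPH kinetics), nor the
measured *decrease* from gcv overexpression — those are
regulatory/kinetic effects outside FBA's vocabulary, and out of scope
here along with all fermentation quantities.

## Synthetic fixtures

`random_network` plants a substrate → product path of known yield
`num/den` (both ≤ 4): an amplifying step `den S -> num X1`, a 1:1 step to
the product, uptake capped at 1. Distractor reactions only convert the
intermediate or decoy metabolites into dead-end decoys, shuttle decoys
among themselves, or convert X1 to product at a strictly worse ratio —
by construction none can exceed the planted optimum. All bounds are
finite, so the flux polytope is compact and small enough (≤ 12 reactions)
for exact brute-force vertex enumeration, the oracle used to validate
the LP on hundreds of seeded instances. Fixtures emulate the *shape* of
the problem (steady-state LP over a signed stoichiometry with bounds),
not biology: no cofactors, no carbon conservation, no measurement noise
(nothing in scope is fitted to data), so passing them validates the
solver plumbing, not the curated network — which has its own exact
checks.

Perturbed variants of the curated model probe its energetic assumptions:
`drop_respiration` (respiration closed → no NADH sink → no steady state
at pinned uptake), `split_cofactors` (transhydrogenase removed → the
network has no NADPH source → production collapses to 0), `free_co2`
(unbalanced CO₂ source, caught by the carbon check).

## Problem sizes and determinism

Every LP in the package is ≤ 29 × 27 and solves in milliseconds; the
vertex-enumeration sweep uses 200 fixtures of 3–6 metabolites and 4–9
reactions plus a handful at the maximal 8 × 12 size, chosen so the whole
suite stays interactive on one CPU. All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); the report writer
emits byte-identical files across runs.

## Known limitations

* The curated network is a lumped core model: pentose-phosphate,
  TCA-cycle and fermentative routes are absent by design, so yields are
  upper bounds conditional on the drawn topology.
* Oxygen/proton/water bookkeeping is deliberately loose (see above);
  the model should not be used for P/O inference or pH arguments.
* Bound edits cannot represent expression levels; scenario predictions
  are capacities, not rates or titers.
* SBML import/export is a stub; the exchange formats are the TSV pair
  and the YAML/JSON document.
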