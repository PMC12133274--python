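# Methods

This note records the model, the numerical procedures, the defaults and
the design choices behind `ofmsens`, in the order the pipeline runs
them.  It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## The enzyme-constrained model

A model is a stoichiometric matrix `S ∈ R^{m×r}` plus enzyme data.  For
every catalysed reaction `i`, flux and enzyme concentration are coupled
linearly, `v_i = kcat_i · e_i`, and every enzyme pool `k` (a
compartment, a pathway, or the whole proteome) bounds the summed mass of
its members, `Σ_{i∈R_k} w_i e_i ≤ E_k`, with `w_i` the enzyme molar
mass.  Units: fluxes mmol·gDCW⁻¹·h⁻¹, kcats h⁻¹, masses mg·mmol⁻¹,
capacities mg·gDCW⁻¹; the coupling and pool rows are dimensionally
consistent under these choices.  Fixed fluxes (`v_j = c_j > 0`, e.g. ATP
maintenance) are the inhomogeneous constraints.

Modelling conventions:

- Reversible reactions are split into forward/backward irreversible
  copies before LP construction; a missing `kcat_reverse` produces a
  cost-free backward copy plus a warning rather than an error, because
  incomplete kinetic annotation is the norm in practice and the
  validator surfaces it.
- Several isozymes on one reaction are expanded into parallel flux
  variables summing to the reaction flux, one coupling and one enzyme
  variable per isozyme; this keeps the problem linear and lets pools
  weight each isozyme by its own subunit composition.
- Exchange and biomass reactions may be cost-free (empty isozyme list).
  Cost-free *internal* conversions weaken the uniqueness guarantee and
  are therefore flagged by the validator as warnings.
- Reactions and metabolites are ordered lexicographically with the
  objective reaction last; all outputs are canonically ordered, so runs
  are reproducible byte-for-byte.
- Named parameters (kcats, capacities, fixed-flux values, bounds) are
  symbolic references resolved through a registry; the native JSON
  schema (`src/ofmsens/schema.json`) carries default values so a model
  file is self-contained.

## Solving

The LP is solved with HiGHS dual simplex (through scipy), which returns
a *basic* (vertex) solution deterministically — a requirement, because
pruning and the at-most-K decomposition presume a vertex, and interior
points would smear flux over alternate optima.  Duals are converted to
one fixed convention (maximization; duals of active ≤-rows nonnegative;
`c = A_eqᵀλ + A_ubᵀμ − ν_lb + ν_ub`), verified in the tests via
stationarity, complementary slackness and strong duality residuals.
Defaults: solver feasibility `tol_feas = 1e-9`; downstream zero/activity
classification `tol_zero = 1e-6` (relative to the largest magnitude in
the block being classified), `tol_act = 1e-7` for constraint activity.
All are keyword-configurable.

Fixed fluxes are encoded as `lb = ub = c_j` (maintenance reactions are
conventionally equalities); the homogenizer treats them as active
inhomogeneous constraints, consistent with that encoding.

## Pruning and uniqueness

Given an optimal vertex, reactions with `|v| ≤ tol_zero · max|v|` and
enzymes below the analogous concentration threshold are removed;
isozymes with inactive enzymes are dropped from kept reactions; pool
membership, metabolites and fixed fluxes are restricted accordingly
(capacities untouched — an inactive constraint remains valid).  The
pruned model is re-solved: by the uniqueness guarantee the result equals
the restricted input solution, and re-solving also yields internally
consistent duals for the reduced LP.  An objective change beyond 1e-6
relative raises a "pruning inconsistency" error, which in practice means
`tol_zero` was too aggressive or the input was not a vertex.

Uniqueness is never assumed: `verify_unique` fixes the objective at its
optimal value and minimizes/maximizes every variable (FVA at the
optimum); the optimum is certified unique when every width is ≤ 1e-6.
This gate runs before any differentiation.  Degeneracy is possible in
principle (duplicated columns with identical costs, ties between
cost-free routes) and the tests construct such cases deliberately; with
generic kcats it is measure-zero, which is why the random-network
generator draws kcats log-uniformly and rejects the rare degenerate
draw.

## Implicit differentiation

At the pruned vertex the active constraints — all equalities, active
pool rows, active bounds, with `lb = ub` contributing a single row —
are collected into `M(p) x = b(p)`.  Redundant rows (conserved-moiety
steady-state rows) are removed by rank-revealing QR with tolerance
1e-9, logged by row id; fewer independent rows than variables raises a
"non-vertex" error.  Duals are recomputed by solving `Mᵀy = c` on the
reduced system rather than reusing solver duals, which sidesteps dual
degeneracy among redundant rows.  For each parameter `p`:

    M · ∂x/∂p = ∂b/∂p − (∂M/∂p) x

with `∂M/∂p` and `∂b/∂p` read off the parameter-dependence records
collected at build time (kcats sit in coupling rows of `M`; capacities,
fixed-flux values and bounds sit in `b`).  One LU factorization of `M`
is shared by all parameters, so batch and single-parameter runs are
bitwise identical; parameters touching only inactive rows yield exact
zero columns without a solve.  Strict complementarity failures (an
active row with ~zero dual) are warned about and the one-sided
derivative from the chosen active set is returned — the boundary case is
surfaced, not guessed away.

Control coefficients are `(p_j/x_i)·∂x_i/∂p_j`; entries with
`|x_i| ≤ tol_zero` are reported as NaN (undefined), never as zero.

The finite-difference comparator re-solves the pruned model at
`p·(1 ± rel_step)` (default `rel_step = 1e-3`, i.e. two-sided 0.1%
perturbations) and takes the central slope.  It is deliberately
independent of the implicit path — same model, fresh LPs — and the suite
requires agreement within 1e-4 relative sup-norm on every fixture and on
50-model random batteries.  Because the pruned solution is a rational
function of each parameter within an active set, the central difference
carries an O(h²) ≈ 1e-6 relative truncation error, comfortably inside
that band.

## Optimal flux modes

Elementary flux modes — support-minimal rays of `{v | Sv = 0, v ≥ 0}` —
are undefined for flux polyhedra with inhomogeneous constraints.  The
homogenization used here folds every *active inhomogeneous* constraint
into a slack column: the fixed fluxes, and the objective reaction held
at its optimal value `v_r*`.  With `w = Σ S_col(j)·c_j + S_col(r)·v_r*`,

    A = [S_free | w],   cone {x | A x = 0, x ≥ 0},

and rays with slack coordinate v̄ > 0, rescaled to v̄ = 1, are the
optimal flux modes: support-minimal pathways that deliver the fixed
demands *and* the optimal objective in their optimal ratio.  Folding the
objective is what makes the construction work end-to-end: without it the
optimum is generally not a convex combination of v̄ = 1 rays (growth-
carrying rays with v̄ = 0 would be needed, the decomposition becomes
non-unique, and the at-most-K bound fails — checked by hand on the
overflow fixture), whereas with it the decomposition is unique, the v̄
row forces Σλ = 1, and at most K modes carry weight, K the number of
pool constraints.  `fold_objective=False` is available to recover plain
EFM enumeration of homogeneous systems.

Rays are enumerated by incremental Double Description in null-space
coordinates: with `N` a basis of null(A), the cone is the preimage of
`{z | Nz ≥ 0}`; the algorithm starts from a simplicial cone of d
independent nonnegativity constraints and inserts the rest one at a
time, combining adjacent positive/negative ray pairs, with adjacency
decided by the algebraic rank test.  Constraints are inserted by
descending nonzero count of the corresponding columns of `A` (a standard
growth-limiting heuristic, configurable in principle through the
ordering hook), and output is sorted by support, so enumeration is
deterministic.  Tolerance for sign classification is 1e-9 relative.
This is adequate for pruned models, which are small; full EFM
enumeration of genome-scale networks is out of scope.

The independent oracle, `brute_force_modes`, enumerates column subsets
in increasing cardinality and accepts a subset as a mode support iff the
restricted null space is 1-dimensional with a strictly positive
generator and no accepted subset is contained in it.  Double Description
must match it exactly (as sets of normalized rays) on every small
instance; the suite runs 30 seeded networks of ≤ 12 reactions.

Decomposition solves `min ‖Rλ − v*‖, λ ≥ 0` by NNLS with the v̄ row of
ones appended (pinning Σλ = 1); residual above 1e-8 relative, a weight
sum off by more than 1e-8, or more than K positive weights raise hard
errors rather than warnings, since each signals a missed mode or a wrong
active set.

## OFM usage sensitivities

Because `v_r*(p)` enters `w`, the cone — and each v̄-normalized ray —
moves with kinetic parameters.  On its support `T`, a ray solves
`S[:,T] r_T = −w`, so its displacement is
`∂r_T/∂p = −pinv(S[:,T]) · S_col(r) · ∂v_r*/∂p` (the fixed-flux part of
`w` is constant for kinetic and capacity parameters).  Differentiating
`R(p) λ(p) = v*(p)` then gives

    R_sub · ∂λ/∂p = ∂v*_sub/∂p − Σ_k λ_k ∂r_k,sub/∂p

on a square, well-conditioned row subset `R_sub` chosen greedily by
maximizing the smallest singular value, with the v̄ row always included.
Including that row makes the columns of `∂λ/∂p` sum to zero exactly (for
K = 2, `∂λ₁/∂p = −∂λ₂/∂p` bitwise); a condition number above 1e10
raises an error with diagnostics.  Scaled usage coefficients
`(p/λ)·∂λ/∂p` are reported where `λ > tol_zero`.

Fixed-flux parameters (`c_j`) change the cone through `w` in a way the
ray-displacement formula above does not cover (the folded value itself
moves); they are rejected with an explicit error rather than silently
mis-differentiated.

The oracle for `∂λ/∂p` is a full re-run per perturbation: re-solve the
pruned model, re-homogenize, re-enumerate the OFMs, re-decompose, and
match modes across perturbations by support — exactly the expensive
baseline the implicit route replaces.  Agreement within 1e-4 relative is
asserted on the overflow fixture.

## The fixture generators

The generators define the study conditions; their constants are fixed
once, documented in `fixtures.py`, and every expected number in the
tests is derived from them in closed form or by the brute-force oracle.

- **chain**: one catalysed step, kcat 2 h⁻¹, mass 1 mg/mmol, capacity
  5 mg/gDCW → `v* = kcat·E/w = 10`, all kcat/capacity control
  coefficients exactly 1.
- **branch**: two routes, kcats 1 vs 2 h⁻¹, shared unit pool → optimum
  2, the slow route pruned away; 2 EFMs before pruning, 1 OFM after.
- **overflow**: yields 10 vs 2 ATP/glucose, kcats (resp, ferm, biomass)
  = (1, 10, 10) h⁻¹, unit masses, membrane and cytosol capacities 1
  mg/gDCW, maintenance flux 1 mmol/gDCW/h.  Both pools bind, both routes
  run: `v_resp = 1`, `v_ferm = 1/3`, `v_bio = 29/3`, and the OFM weights
  are `λ_resp = y_R·v_resp/(1+v_bio) = 15/16`, `λ_ferm = 1/16`.  The
  membrane/cytosol split reproduces, at desk scale, the crowding
  mechanism by which membrane kinetics favour respiration and cytosolic
  kinetics favour fermentation.
- **random_ec_network**: uptake → backbone chain of catalysed
  conversions → secretion objective, plus random forward shortcuts with
  small-integer stoichiometry; kcats log-uniform in [0.1, 100] h⁻¹,
  masses uniform in [10, 100] mg/mmol, capacities uniform in
  [0.5, 5] mg/gDCW, pools a random partition of the enzymes.  Draws are
  rejected (rarely) until the optimum is positive and unique after
  pruning.  Identical seeds give byte-identical JSON.

What the generators do *not* emulate: mass conservation of elemental
composition, reversibility, cofactor coupling, realistic network
diameter, or genome-scale size.  Passing tests therefore demonstrate the
correctness of the mathematics on generic networks of the assumed
structure, not predictive accuracy on any real organism.

## Problem sizes and runtime

The test suite and the acceptance script run the full pipeline on the
three named fixtures, 50 random networks (5 metabolites, 8 reactions, 2
pools each) for the sensitivity/uniqueness/decomposition batteries, and
30 random networks of ≤ 12 reactions for the Double Description vs
brute-force comparison.  These sizes keep each battery in the
tens-of-seconds range on one CPU while exercising every code path;
all thresholds above are independent of the sizes chosen.

## Known limitations

- Sensitivities are local: an active-set change (a metabolic switch) at
  finite perturbation invalidates the linearization, and switching
  points are not detected or analysed.
- Non-strict complementarity yields one-sided derivatives, reported with
  a warning rather than refused.
- OFM usage sensitivities to fixed-flux values are unsupported (see
  above).
- COBRA-JSON import is structural only; kcats and molar masses must be
  supplied by the user as parameters.
- SBML, gapfilling, thermodynamic constraints and genome-scale EFM
  enumeration are out of scope.
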