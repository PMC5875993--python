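# Methods

## Model representation and measurements

Models are handled as `cobra.Model` objects; SBML Level 3 FBC is preferred
and Level 2 accepted via COBRApy's reader. The solver backend is GLPK
through optlang, which internally represents every reaction as a pair of
non-negative forward/reverse variables — exactly the split-flux formulation
the minimization below requires, so no model rewriting is needed.

Measured exchange fluxes and the growth rate are applied as bound
intervals `[v*(1−tol), v*(1+tol)]` with the interval ends swapped for
negative values; the default `tolerance_fraction` is 0, i.e. equalities.
The growth rate is **fixed** (lb = ub) rather than imposed as a lower bound
only: with a free upper side, the minimization could trade unused growth
capacity against boundary inflow and report an optimistically low bound.
A `growth_as_lower_bound` switch restores the permissive convention.
Uptake is negative (COBRA/BiGG convention); the CSV reader warns when a
declared carbon source has a non-negative measured flux.

Currency metabolites are matched by full identifier, compartment included.
The shipped default list enumerates ATP/ADP/AMP, NAD(P)(H), FAD(H₂), CoA,
CO₂, H₂O, H⁺, O₂, phosphate, diphosphate and quinones across common
compartment suffix spellings (`x_c`, `x[c]`, `M_x_c`, …). Computing the
currency set from atom transitions is out of scope; identifiers are
user-supplied or defaulted, and unknown ids are dropped with a warning
naming them.

## Boundary detection

A non-core reaction enters the boundary set when some direction open under
its *current bounds* (forward when ub > 0, reverse when lb < 0) produces a
non-currency metabolite that participates in a core reaction. Judging
direction from bounds rather than the SBML reversibility flag means a
measurement-constrained model yields a tighter, condition-specific
boundary set. Metabolites whose summed stoichiometric coefficient in a
reaction is zero are ignored. Core participants are collected from **both**
sides of core reactions: a metabolite that core reactions only produce
still shares a carbon pool with the core, so peripheral producers of it
are reported; treating the two sides asymmetrically would make the result
depend on how each core reaction happens to be written (direction of its
equation), which we consider an artifact. This symmetric reading is a
design choice and can over-report relative to a strictly
consumption-oriented reading.

Exchange reactions appearing in the boundary set are flagged as potential
carbon sources; the CLI refuses to proceed (exit code 4) when one lies
outside the core, since the bow-tie premise assumes the labeled uptake is
part of the core, and an override flag documents the exception.

## Flux-into-core minimization

The LP minimizes the sum of the core-directed split components of the
boundary reactions subject to steady state and bounds. The objective is
built directly on cobra's forward/reverse solver variables; infinite
bounds are replaced by ±1000 mmol·gDW⁻¹·h⁻¹ (the COBRA convention,
configurable in the explicit `SplitProblem` path). Because the objective is
a non-negative weighted sum of non-negative variables it is bounded below,
so "unbounded" can only signal a malformed model and is reported as such,
distinctly from infeasibility.

**Alternate optima.** Only the optimal objective is unique; the solver's
per-reaction component values are one optimal vertex among possibly many.
Reported per-reaction bounds are therefore made deterministic by a second
pass: with the total inflow constrained to its optimum (plus a 1e−9 slack),
each selected component is maximized individually, FVA-style. This yields
the loosest per-reaction bound consistent with minimal total inflow,
independent of row ordering or solver arbitrariness. The raw
single-solution values remain available (`raw_bound_toward_core`, CLI
`--raw-solution`) and sum to the objective; the tightened values need not.
A bound below 1e−7 mmol·gDW⁻¹·h⁻¹ is reported as zero (LP noise floor;
GLPK's default tolerances are ~1e−9, so 1e−7 separates noise from signal
with two orders of margin).

**Legacy procedure.** The sequential variant visits boundary reactions in
lexicographic id order (the procedure is inherently order-dependent; a
fixed order makes runs reproducible, and `order="model"` is available) and
sets each core-directed bound to the smallest of `[0, 0.05, 0.2] × uptake`
that keeps the constrained model feasible, accumulating constraints as it
goes. Feasibility means the measurement-constrained model (growth fixed)
admits any solution — not a separate biomass re-optimization. A reaction
infeasible even at the largest level keeps its original bounds and is
flagged rather than guessed at; its pre-existing core-directed capacity is
reported but excluded from the total.

## Simulated annealing

The energy of a candidate core is the LP optimum above, computed without
the tightening pass (only the objective is needed). The temperature decays
exponentially from `t_max` to `t_min` over `steps` iterations; both are in
flux units, as is the energy.

Moves follow a 50/50 add/remove draw, with removal forced at the maximum
size. Removals are rejected — returning the input core while still
consuming the schedule step — when the reduced core would be disconnected
in the reaction-adjacency graph or would retain less than
`minimum_overlap` of the *initial* core (not the current one). Additions
draw uniformly from the current boundary set and are rejected only when
that set is empty. `maximum_size` accepts an absolute count or a fraction
of the model's reactions (floored).

The acceptance reference is the energy of the last *accepted* core, and
the best core seen is tracked and returned. A literal reading of the
procedure in which the reference energy is overwritten by every proposal,
accepted or not, is available as `faithful_pseudocode=True`; it degrades
the walk toward accepting most moves and is kept only for comparison.

Randomness comes from `numpy.random.Generator` (PCG64) seeded per run;
draws occur in a fixed order — move-type uniform, element index, then an
acceptance uniform only for uphill proposals — so a seed reproduces its
trace bit-exactly across platforms. Energies are cached by frozen core id
set; since the energy is a deterministic function of the core, caching
cannot alter results, and a cache may be shared across seeds.
`multi_seed_anneal` runs seeds sequentially and returns the minimum-energy
result (ties to the earlier seed).

## Synthetic bow-tie models

The generator emulates the bow-tie architecture: one substrate exchange
(`EX_S`) and funnel (`T_S`) feed a pool metabolite that fans out into
`n_core_precursors` precursors consumed by biomass with unit coefficients —
mirroring how central metabolism funnels carbon sources into a small
precursor set — plus an overflow route absorbing surplus uptake, an ATP
maintenance sink, peripheral branches draining precursors outward, and a
currency-only feeder exercising the currency-exclusion logic. Each
*backflow route* `A₁ → W_k → X_k` makes `X_k` a biomass requirement (demand
coefficient `d_k`) producible only peripherally, so at growth rate μ the
minimum inflow is exactly `Σ d_k·μ` — a closed-form optimum available at
generation time. Defaults (uptake 10 mmol·gDW⁻¹·h⁻¹, μ = 1 h⁻¹, demand
0.3 in the standard backflow fixture) are chosen so demands fall strictly
between the legacy quantization levels, exposing the LP's advantage; the
generator rejects specs whose demands exceed the substrate budget.

What the fixtures do *not* emulate: carbon atom transitions (the currency
list is the only carbon filter, as in real use), compartmentalization
beyond a cytosol/extracellular split, realistic cofactor coupling,
thermodynamic constraints, and network sizes where LP degeneracy is
extensive. Passing tests therefore demonstrate algorithmic correctness on
networks whose optimum is provable, not biological fidelity on a
genome-scale reconstruction.

The independent oracle (`brute_force_min_inflow`) rebuilds the split LP as
dense arrays by direct iteration over the stoichiometry and solves with
scipy's HiGHS — sharing no LP code or solver with the main path — and is
size-guarded since it exists only for cross-checks on small fixtures.

## Numerical and testing choices

Test problem sizes are kept small by design: fixtures of 10–16 reactions
whose optima are analytic, a 20-fixture randomized oracle panel, and
annealing runs of 500 steps over ~10-core-reaction search spaces; these
sizes already exercise every code path while keeping the full suite in a
few seconds. Determinism is asserted bit-exactly for annealing traces and
to 1e−9 relative for LP objectives under input permutation. The annealing
success-rate check (20 seeds, ≥95% reaching the known zero-energy core
within 500 steps) uses a schedule of `t_max = 1.0`, `t_min = 1e−3` — on the
fixture's energy scale (0.3) this gives genuine uphill acceptance early and
near-greedy behaviour late.

## Known limitations

- Bidirectional peripheral exchange fluxes with high exchange but low net
  flux can receive inappropriately low bounds; detecting these requires
  labeling information outside this package's scope.
- The legacy procedure's per-reaction results depend on visit order by
  construction; only its total is meaningful for comparison.
- The annealer's constraints make the search space finite but the method
  remains stochastic; multiple seeds are recommended, and the per-seed
  trace is exported for mixing diagnostics.
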