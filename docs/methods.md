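# Methods

## The profiling model

The framework treats a genome-scale metabolic model (GEM) as a linear
steady-state system — stoichiometric matrix *S*, flux vector *v*, bounds
*v*<sub>l</sub> ≤ *v* ≤ *v*<sub>u</sub>, biomass objective *c* — and encodes
two data layers purely as bound rewrites:

- **Expression layer.** Every GPR-bearing reaction gets a Reaction Activity
  Score: the rule is evaluated on per-gene abundances with AND → minimum
  (complex subunits are jointly required, the scarcest limits the enzyme)
  and OR → sum (isozymes are interchangeable and pool their capacity). The
  flux cap is v_i = α·RAS_i, imposed symmetrically on reversible reactions
  (lower bound −v_i, upper bound +v_i) and only on the open direction of
  irreversible ones: a bound that is already 0 encodes thermodynamic
  impossibility and is never reopened. The rewrite can only tighten bounds.

- **Nutrient layer.** Every measured medium substrate caps uptake through
  its exchange reaction at MUR_j = |ΔS_j| over the culture window; the
  exchange lower bound becomes −MUR_j, the secretion bound is untouched.
  Unmeasured exchanges keep model defaults (serum components, trace
  nutrients and gases are typically unquantified; closing them would starve
  the model on data that was never collected). An availability-only mode —
  final concentration 0, cap = initial concentration — covers plain media
  recipes without spent-medium measurements.

Assumptions inherited from constraint-based modelling: steady state
(Sv = 0), growth as the maximisation target, and fluxes meaningful only up
to the bound units. All fluxes here stay in mM per 48 h window — the units
the measurements come in — rather than mmol/gDW/h, since no dry-weight
normalisation is part of the data.

### Why a single α, and how it is chosen

RAS values are in (arbitrary) expression units; exchange caps are in
mM/48 h. A single reaction-independent factor α converts the former to the
latter. Because α only scales a subset of bounds, the per-condition biomass
optimum Z_c(α) is a non-decreasing, saturating, piecewise-linear curve:
small α pinches every GPR reaction (Z → 0), large α leaves only the
nutrient caps binding (Z = nutrient-only optimum). The calibration scans a
log-uniform grid (default 25 points, 10⁻⁶…1) and scores, at each α, the
shape agreement between {Z_c(α)} and the observed reciprocal doubling
times.

The default score is a *scaled RMSE*: predictions are first least-squares
scaled onto observations (s* = ⟨p,o⟩/⟨p,p⟩), then the RMSE of s*·p − o is
taken. Rationale: predicted flux (mM/48 h) and growth rate (1/h) differ in
units by an unknown constant, so only the between-condition ratio structure
is comparable; a pure correlation would ignore ratio mismatches, while the
scaled RMSE penalises them. Pearson correlation is available as an
alternative. Ties — including the score plateau above the saturation
region, where predictions stop changing with α — break toward the smaller
α, i.e. the tightest model consistent with the data. Conditions without an
observation (no growth, undefined doubling time) are excluded from the
score but still predicted and reported.

Identifiability is structural, not guaranteed: the score can only prefer an
α at which some observed conditions are still expression-limited and others
already nutrient-saturated. If the true operating point lies entirely on
the plateau (or entirely in the rising region, where all predictions scale
uniformly and the scaled score is flat), any α on the flat stretch scores
identically and the tie rule returns its lower edge. This is a property of
the method, not of the implementation, and it bounds what calibration can
recover.

## Linear programming

FBA and FVA are assembled directly on the sparse stoichiometric matrix
(memory proportional to nonzeros) and solved with HiGHS through
`scipy.optimize.linprog` — deterministic across repeated calls on the same
input. FVA solves the min/max pair per queried reaction subject to
retaining w᷆ᵀv ≥ γ·Z₀; the right-hand side is relaxed by 10⁻⁹·max(1,|Z₀|) so
that γ = 1 (the default: the network held at its optimum) is not cut off by
round-off. Feasibility tolerance 10⁻⁹, reporting tolerance 10⁻⁶; a
mass-balance residual above 10⁻⁶ at a reported optimum raises rather than
returning silently wrong numbers. Degenerate optima are expected (parallel
pathways): the objective value and FVA intervals are reproducible outputs,
the particular FBA flux vector is not and is documented as such.

## The synthetic-data generator

`gemprofiler.fixtures` generates every input the pipeline needs from a
seed, at toy scale (≤30 reactions so an exhaustive vertex-enumeration LP
reference stays tractable in the tests). It emulates a seven-condition
nutrient-availability study on a cultured cell line:

- **Network.** One nutrient (the glutamine analogue) is the sole source of
  biomass precursor p2 and can also feed the p1 pool — mirroring how
  glutaminolysis feeds both biosynthesis and energy metabolism; the glucose
  analogue feeds only p1. Growth (biomass drains p1 + p2) is therefore
  glutamine-dependent and glucose-substitutable by construction. Auxiliary
  nutrients, a secreted waste product (the lactate analogue), random
  1:1 conversions on the p1 side (reversible with probability 0.3) and
  random GPR forms (single gene, AND pairs, OR-of-AND) add variety.
  Exchange bounds default to ±1000, wide enough that every measured cap
  tightens them. Networks that cannot grow are resampled (bounded retries);
  everything is deterministic per seed.
- **Expression.** Negative-binomial counts (dispersion size 10), three
  replicates per condition, lognormal per-gene base means (median 300,
  σ = 1) and independent lognormal condition fold-changes (σ = 0.5), so
  activity scores genuinely differ across conditions.
- **Media.** The seven-condition template varies the two main nutrients
  (25/10/2 mM glucose-like × 4/2/0.5/0 mM glutamine-like) including two
  zero-availability conditions; auxiliary nutrients are constant.
  Availability-only mode (full consumption assumed) defines the caps.
- **Observations.** Reciprocal doubling times are forward-simulated from
  the combined model at a known ground-truth α, times a fixed
  unit-conversion scale (0.005 h⁻¹ per mM/48 h) and multiplicative
  lognormal noise (CV 5% by default). Conditions with zero biomass flux
  yield an absent observation, as dead cultures have no doubling time.

The ground-truth α defaults to 10⁻⁴·²⁵ ≈ 5.6·10⁻⁵, an on-grid point chosen
to sit inside the per-condition saturation cascade (CPM-scale scores of a
few 10⁴ against caps of 0.5–25 mM/48 h put the cascade near 10⁻⁵…3·10⁻⁴):
below the knee of the rich conditions, above that of the poor ones, which
is precisely the regime in which the calibration is identifiable. Across
seeds the lognormal expression tails occasionally push a study's whole
cascade away from this point; those studies are honestly unidentifiable at
the grid resolution and account for the <10% of replicates in which
recovery misses by more than one grid step.

What the generator does **not** emulate: realistic human-network topology
(no compartments beyond an id suffix, no cofactor coupling, no redundant
subsystems at scale), isoform-level expression, library-preparation
artefacts beyond depth (handled by CPM), or measurement error on
concentrations. Passing tests therefore demonstrate the correctness and
calibration behaviour of the machinery under the stated noise model, not
predictive accuracy on real transcriptomes or on genome-scale
reconstructions.

## Numerical and design choices

- **Expression aggregation** defaults to per-replicate CPM then mean across
  replicates: replicate library sizes differ, CPM removes depth artefacts
  while preserving the scale equivariance (RAS is 1-homogeneous in
  abundances) that makes the α scan meaningful. `none`/`median` are
  retained as options.
- **Missing genes** default to `skip` (dropped from their operator): a gene
  absent from a count table is usually unannotated rather than silent, and
  zeroing it would spuriously close every AND clause above it. `zero` is
  available when absence genuinely means no expression. A score of 0 is a
  legitimate value, distinct from an undefined one (undefined leaves the
  reaction unconstrained).
- **Zero scores** close the reaction by default (`block`), the literal
  reading of v_i = α·RAS_i; `leave` is available.
- **Gene id matching** strips trailing `.N` version suffixes on both sides
  and accepts a user id-mapping table; no online translation.
- **Order of rewrites**: expression first, nutrients second. The two
  commute whenever no exchange reaction carries a GPR (the usual case); if
  one does, the nutrient cap wins on the exchange lower bound.
- **Degenerate inputs**: a forced-positive lower bound that exceeds a new
  cap is clamped down to the cap (tightening wins); an availability cap
  wider than the current bound interval is applied as written (assignment
  semantics) — with the ±1000 defaults used throughout this only tightens.
- **Biomass lookup**: the unique nonzero-objective reaction, else the
  unique id containing "biomass" (case-insensitive); anything else is an
  explicit ambiguity error.

## Problem sizes used in the tests and acceptance script

Toy networks of ~13 reactions, 7 conditions, 25-point α grids, 20 replicate
studies for the recovery measurement, 1000 random GPR rules and 100 random
≤6-reaction networks for the oracle-equivalence checks. These sizes keep
the exhaustive references (recursive rule evaluation, polytope vertex
enumeration) exact and fast while exercising every code path; the
implementation itself is sparse throughout and sized for genome-scale
models.

## Known limitations

- Fluxes remain in mM/48 h; no conversion to specific rates (mmol/gDW/h),
  so absolute fluxes are comparable only within a study.
- One global α: no per-reaction or per-pathway scaling.
- Bound rescaling only: the framework never removes reactions
  (no GIMME/iMAT/FASTCORE-style context extraction).
- The calibration recovers α only inside the saturation cascade (see
  above); outside it the tie rule returns the plateau edge.
- FBA flux vectors are non-unique under degeneracy; only objective values
  and FVA intervals should be compared across runs or solvers.
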