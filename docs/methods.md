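# Methods

This note documents the model, the numerical choices, the synthetic
study conditions, and the limits of what the test suite demonstrates.

## The four-objective flux model

All computations run over the steady-state flux polytope
{v : S·v = 0, lb ≤ v ≤ ub}. The four objectives are linear or
piecewise-linear functionals of v:

* biomass and ATP production are single-reaction fluxes (maximised);
* enzyme cost Σ wᵢ|vᵢ| is linearised with slack variables sᵢ ≥ ±vᵢ;
  default weights are 1 for every gene-associated reaction and 0
  otherwise (exchange/boundary and spontaneous reactions carry no
  catalytic cost). kcat- or mass-weighted variants plug in through
  `ObjectiveWeights`.
* carbon uptake Σ cⱼ·max(0, −vⱼ) counts only the uptake direction of
  exchange fluxes (secretion never offsets uptake); cⱼ is the carbon
  count parsed from the exchanged metabolite's formula, 0 (with a
  logged warning) when no formula is annotated. Exchanges follow the
  uptake-negative sign convention, enforced at load time for
  extracellular species.

Because |v| and max(0, −v) are convex, they are admitted only in
minimised objectives and upper-bounded constraints — exactly where the
model needs them; objective values are always re-evaluated exactly from
v, never read off the slack variables.

GPR rules are evaluated quantitatively: AND = min (an enzyme complex is
limited by its scarcest subunit), OR = max (the strongest isozyme
carries the reaction). This is the standard convention; both
combinators are overridable. A knockdown to residual activity a scales
the affected reaction's bounds to (a·lb, a·ub), so bounds only tighten.

## Solvers and tolerances

LPs are solved with scipy's HiGHS interface (deterministic; repeated
runs agree bit-for-bit). Defaults: feasibility tolerance τ_feas = 1e-9,
objective/dominance tolerance τ_obj = 1e-6, PDS clamp τ_pds = 1e-6; all
exposed in `RunConfig`. The MOMA projection (min ‖v − v_ref‖² s.t.
S·v = 0, bounds) is a convex QP solved with SLSQP (analytic gradient,
ftol 1e-14) with a trust-constr fallback; a feasible reference is
returned unchanged without invoking the solver, which makes the
"distance 0 iff reference feasible" property exact. No QP library is
available in the supported environment, and the problem sizes here
(tens of reactions) are well inside SLSQP's comfort zone; solutions are
verified against hand-derived projections in the tests.

## ε-constraint sampling

Ranges for the three constrained objectives come from the four
single-objective extreme solutions (utopia/nadir estimate). Each grid
cell maximises the primary objective (biomass by default) under
ε-constraints (≥ ε for maximised, ≤ ε for minimised objectives), then
lexicographically minimises enzyme cost and carbon uptake with the
previous optima pinned at τ_obj/10 relative slack — ε-constraint
scalarisation is known to emit weakly-optimal points and alternate
optima (e.g. futile cycles riding a biomass optimum), and the clean-up
makes stored fluxes reproducible. Pooled solutions pass a final
dominance filter with tolerance τ_obj; points equal within tolerance
are duplicates and all retained. Infeasible cells are counted, not
fatal. The default desk-scale grid is 10 levels per constrained
objective (10³ cells + 4 extremes, ~3 LPs per feasible cell); grids are
configuration, not code.

The enumeration oracle (`brute_force_pareto`) grids the nullspace
coordinates of S (refusing networks with more than 4 degrees of
freedom), filters to the feasible box, evaluates objectives and applies
the same dominance filter. Front equivalence is asserted two-sided:
(i) no enumerated feasible point dominates any sampled solution beyond
relative τ_obj — i.e. every sampled point is Pareto-optimal; (ii) every
oracle-front point lies within a normalised objective distance of the
sampled front bounded by the two grid resolutions,
2·(1/(levels−1) + 1/(points_per_axis−1)). Measured coverage sits at
roughly half that bound on all fixtures.

## Cell-line fitting

Per-gene flux engagement Σ |vᵢ| over the gene's reactions is the
model-side analogue of enzyme abundance (the working assumption being
that pathway flux tracks the abundance of its enzymes). Similarity
blends two kernels with weight α (default 0.5):

* abundance vs engagement: Spearman rank correlation — proteomic
  intensities are relative units, so only monotone agreement is
  meaningful;
* measured vs solution exchange fluxes: Lin's concordance correlation —
  CORE rates are absolute (mmol/gDW/h, the same units as model fluxes),
  and any pure correlation (Pearson or Spearman) is invariant to
  positive rescaling, which would make proportionally scaled Pareto
  solutions (same pathway mix, different magnitude) indistinguishable.
  Concordance penalises magnitude mismatch and restores
  identifiability of the solution's scale.

Both kernels are configurable (including all-Spearman). A component
with fewer than 3 shared items drops out and the other is renormalised;
fewer than 3 in both raises. Selection takes the top ⌈fraction·N⌉
solutions by score, extended to all solutions tied with the cut-off
score, so duplicate solutions are never split arbitrarily; the
cell-line model's prediction is the mean objective vector of the
selection and its representative flux is the top-scoring solution. The
package default fraction is 1%; the recovery study below uses 5%
because at desk-scale front density (~700 solutions including
duplicates) the σ = 0.05 noise ball spans a few dozen statistically
indistinguishable neighbours, and a selection smaller than that
neighbourhood cannot contain the generating solution reliably no
matter the kernel.

## PDS

The Pareto deviation score of an objective point is its Euclidean
distance to the nearest sampled solution after min–max normalising each
objective by the front's own range (degenerate ranges are dropped with
a warning); distances below τ_pds are clamped to zero, absorbing grid
discreteness. Distance is measured to the discrete sample, not an
interpolated manifold, and in objective space, not flux space — the
objectives are what define fitness trade-offs, and normalisation makes
the four axes commensurable; a raw-flux-space variant is retained
behind `space="flux"` for sensitivity analysis. Perturbed fluxes come
from MOMA started at the cell line's representative flux. One
consequence worth knowing: a knockout that collapses the cell toward
the idle state can land *on* the front (the zero state is
Pareto-optimal — zero cost, zero carbon), so PDS deliberately does not
flag it; PDS measures loss of Pareto-optimality, not growth reduction.

## Target identification

Projections bin solutions into equal-count phenotype bins (default 20;
12 on the small fixtures) after snapping phenotype values to a 1e-5
relative grid so LP jitter cannot split clusters of duplicate
solutions; bins whose quantile edges collapse merge automatically.
Envelopes are per-bin flux extrema. Monotonousness is the Spearman
correlation of bin centres with an envelope (0 by convention for a
constant envelope). Solutions with an undefined Warburg ratio (no O₂
uptake and no lactate secretion) are excluded from Warburg projections;
lactate secretion without measurable O₂ uptake caps the ratio at a
documented ceiling (1e3).

Boundary proximity interpolates the envelopes between bin centres and
counts a model as close when its distance to a boundary is within a
fraction (default 0.25) of the local band width, or within the
estimator's own resolution (global flux range / number of bins) —
distances below the bin resolution are not distinguishable from zero.
The default mode requires proximity to the upper *or* lower boundary,
one combined condition; a `matched` mode demanding proximity to the
specific envelope driving the call is available, but the either-mode is
what the classification rule uses: models pinned anywhere on the
projection boundary are the ones a perturbation can displace off the
surface. Calls: suppressing if monotonousness(upper) ≤ −0.8,
promoting if monotonousness(lower) ≥ +0.8, both requiring the
proximity fraction ≥ 0.5; the cutoffs are configuration with these
defaults. An enzyme can be called in several phenotype classes at once;
the overlap report lists all pairwise intersections and the
growth-promoting ∩ Warburg-suppressing ("ambiguous") set explicitly.

The in-silico Warburg proxy (lactate secretion / O₂ uptake) tracks the
experimental ECAR/OCR ratio only approximately: real extracellular
acidification also carries a CO₂/bicarbonate component that the proxy
ignores.

## Synthetic study conditions

The fixtures are designed so every pipeline stage has an enumerable
ground truth:

* `chain-net` — one path, no trade-off; the front is a single ray.
* `Y-net` — glucose splits between a biomass path (yield 1) and an ATP
  path (yield 2); the biomass-path flux equals the growth rate, giving
  an analytically known growth-promoting call.
* `parallel-net` — Y-net plus an isozyme-like duplicate of the ATP path
  and a low-yield salvage route (0.25 ATP/glucose). Single knockouts
  reroute through the twin path at near-zero fitness cost; the double
  knockout forces the wasteful salvage route, whose flux configuration
  is genuinely dominated — guaranteeing the strict
  double-worse-than-singles ordering independent of grid coincidences.
* `ferm-resp-net` — fermentation (glc + 1 cap → 2 lac + 2 ATP) versus
  respiration (glc + 6 O₂ + 20 cap → 6 CO₂ + 30 ATP) under a shared
  catalytic-capacity budget, with biomass consuming glucose, ATP and
  capacity. Three deliberate features: respiration is glucose- and
  carbon-efficient while fermentation is capacity-efficient (the
  crowding rationale for the Warburg effect); maintenance ATP
  hydrolysis also consumes capacity, so maximal respiration coincides
  with maximal growth rather than idle ATP burning; and fermentation
  has a finite Vmax, so fast growth cannot run on fermentation alone —
  respiratory flux must rise with growth rate. Together these
  guarantee a growth–Warburg trade-off with falling respiratory upper
  envelopes along the Warburg axis.
* `random-net` — seeded random sparse pathway network for smoke and
  property tests.

Synthetic panels emulate a cancer cell-line collection: generating
solutions are drawn uniformly from front states with biomass ≥ 20% of
the front maximum (a cancer panel's doubling times span roughly a
fivefold range) and, when the model has lactate/O₂ exchanges, with a
strictly positive Warburg ratio (cultured cancer lines universally
secrete lactate aerobically; idle or purely respiratory states are not
cell-line states). Abundances get multiplicative lognormal noise
(non-negative by construction); exchange fluxes get additive Gaussian
noise with sd = σ × the measurement's own magnitude (a measurement CV),
floored at 2% of the metabolite's front-wide scale so zero fluxes still
carry noise. Boundary fluxes of intracellular pseudo-species (the
capacity pool) are not part of the emulated CORE profile — spent-medium
metabolomics cannot see them. Panels are bit-reproducible per seed.

What passing tests on these panels do *not* show: real proteomes have
thousands of enzymes with shared peptides and batch structure, real
CORE data has missingness and medium-dependent biases, and real
metabolic networks have orders of magnitude more alternate optima; the
synthetic results certify the machinery (recovery, scoring, geometry),
not clinical performance.

Stochastic-study sizes used by the test suite and acceptance script:
front grids of 6–10 levels per objective, enumeration oracles at 9–41
points per axis (chosen so every fixture stays under a few tens of
thousands of grid points), 100-line panels at σ = 0.05 for recovery,
20–30-line panels for classification. With these sizes the full suite
runs in about two minutes on one CPU. The classification overlap
("ambiguous") set is structurally present but its exact membership
moves with panel composition, since several proximity fractions sit
near the 0.5 cutoff; the pinned-seed conditions in the tests are
reported as the study configuration.

## Known limitations

* The enzyme-cost weights default to 1 per gene-associated reaction;
  without kcat/molecular-weight data the objective is a flux-sum proxy.
* PDS against the discrete sampled surface underestimates distance to
  the true continuous front by up to the sampling resolution.
* The ε-constraint grid inherits the usual scalarisation bias: regions
  of the front where the primary objective is flat are sampled more
  sparsely; rotating the primary objective is supported but not
  automated.
* MOMA accuracy is limited by SLSQP convergence (~1e-7 on the test
  problems); for genome-scale models a dedicated QP solver would be
  preferable.
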