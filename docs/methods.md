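# Methods

`fossilrange` implements the quantitative core of a fossil-inclusive
historical-biogeography and diversification study: time-scaling a
cladogram from stratigraphic ranges, fitting time-stratified likelihood
models of geographic-range evolution, counting biogeographic events by
stochastic mapping, and scoring diversification shifts and diversity
curves on time-sliced trees.  This note documents the models, the
conventions that affect numbers, and the design choices made where the
method family leaves them open.

## Time-scaling (equal method)

Input is a rooted binary cladogram plus a table of first and last
appearance data (FAD/LAD, Ma).  Leaves are dated at their FAD (minimum-age
dating; the LAD is used only by the diversity curves).  Node ages start at
the maximum of their children's ages, the root is pushed back by a
configurable `root_extension` (no default is claimed beyond the fixtures'
10 Myr), and every chain of zero-duration branches — which the
max-of-children rule necessarily creates along each node's oldest
descendant path — is removed by re-spacing the tied nodes at equal
intervals strictly between the nearest strictly older ancestor and the
leaf that pinned the tie.  The pass runs root-to-tips so that time opened
upstream is available downstream; within a node, tied children are
processed in child order.  The result is a tree with strictly positive
durations whose leaf ages equal the FADs exactly.

## Range-evolution models

The state space is every non-empty subset of the ordered area list up to a
maximum range size `m` (default: all areas), plus an absorbing null range
that is never observable at a tip.  All three families share the same
anagenetic process: area gain at rate `d` per (source area, target area)
pair and area loss at rate `e` per occupied area (size-1 ranges decay to
null).  They differ only in cladogenesis:

| family    | sympatric copy | subset sympatry | vicariance            | 
|-----------|----------------|-----------------|-----------------------|
| DEC       | single-area only | yes           | one singleton daughter |
| DIVALIKE  | single-area only | no            | any disjoint bipartition |
| BAYAREA-like | any range (identity) | no     | no                    |

Two optional free parameters define the M1/M2 tiers:

* **x** (M1, M2): per-pair dispersal rates are multiplied by
  `(dist(a,b) / mean off-diagonal distance of the stratum)^x`.  The mean
  normalisation makes `x = 0` exactly a no-op and keeps `d` comparable
  across strata; sensible fits have `x <= 0`.
* **j** (M2): founder-event speciation.  Each ordered jump event (one
  daughter starts in a single area outside the parent range) has weight
  `j`, and all non-jump events have weight `(3 - j)/3`, so `j = 0`
  reduces bit-for-bit to the standard model.  This weight convention is
  the one that makes fitted likelihoods comparable with the reference
  implementations of these models; it is stated here prominently because
  it shifts LnL.  Jumps are not distance-scaled by default (a flag
  enables it).

Event probabilities are weights normalised per parent range.  Time is cut
into strata, each with its own symmetric positive distance matrix; a
branch crossing a boundary is integrated piecewise with the per-stratum
rate matrices chained oldest to youngest.

## Likelihood, fitting and model selection

Felsenstein pruning over the range states with cladogenetic mixing at
nodes; per-node rescaling guards against underflow.  Transition matrices
use an eigendecomposition of each stratum's rate matrix (with a residual
and condition-number check, falling back to `scipy.linalg.expm`).  The
root is summed against a prior that is uniform over non-null states —
the convention is configurable to a point mass, which the simulation
cross-checks use; the choice shifts LnL by a roughly constant term and is
therefore stated here.

`RangeEvolutionModel.fit` maximises the likelihood with bounded L-BFGS-B
in `(log10 d, log10 e, x, j)` space, bounds `d, e ∈ [1e-12, 5] /Myr`,
`x ∈ [-5, 0]`, `j ∈ [0, 2.99999]`, from a deterministic seed-derived list
of multistarts (default 5); refits with the same seed are bit-identical.
Model comparison: likelihood-ratio tests for nested tiers (G clamped to 0
when within 1e-6 of zero to absorb optimiser noise) and
`AICc = -2 LnL + 2k + 2k(k+1)/(n-k-1)` with `n` = number of tips for the
non-nested comparisons, plus ΔAICc and Akaike weights in the comparison
table.

Ancestral ranges are marginal posteriors (state of a node immediately
before its own cladogenetic event) computed by the standard
inside–outside pass and validated against joint enumeration on small
trees.

## Stochastic mapping

Histories exactly consistent with the tips are drawn by: root state ∝
prior × root conditional; at each node an ordered daughter pair ∝ event
probability × the two daughters' branch-propagated conditionals; branch
endpoint states ∝ transition probability × tipward conditional, with
stratum-boundary states sampled from endpoint-conditioned products; and
within-segment paths by endpoint-conditioned uniformization.  One global
uniformization bound (the maximum exit rate over all strata) is used so
jump-matrix powers are shared across branches; the path law is invariant
to the bound.  Because the null range is absorbing and endpoints are
non-null, sampled paths cannot enter it; a rejection guard remains as a
safety check.  Event counts follow the six-category taxonomy (range
expansion, range contraction, founder, sympatry, subset speciation,
vicariance); every map of a `T`-tip tree carries exactly `T - 1`
cladogenetic events, and percentages divide each category's mean count by
the grand-total mean so they sum to 100 — the convention that reproduces
the published percentage columns from published mean counts.

## Diversification shifts and diversity curves

A time-sliced tree at time `t` keeps every taxon with FAD ≥ t in its
original topology and collapses each branch crossing `t` whose whole clade
is younger into a single ghost terminal; slicing at 0 is the identity.
Node imbalance is scored with the equal-rates-Markov tail: the ordered
daughter size of an `n`-terminal node is uniform on `1..n-1`, so
`P(larger daughter ≥ L) = 2(n-L)/(n-1)`.  Family-wise calibration
simulates the null distribution of the tree-wide minimum tail over ERM
trees of the same terminal count (default 1999 replicates) and flags
nodes at or below the empirical alpha quantile.  This concretely defined
statistic stands in for the original study's tree-shape software, whose
exact statistic is not published; node-level flags are therefore
comparable only qualitatively.  A flagged shift is marked a *possible
artefact* when more than `theta = 0.5` of the clade's taxa have a LAD
older than the focal bin's older bound (extinction-dominated clade), or
when the clade's split is unchanged from the preceding bin.

Taxic diversity counts taxa whose closed `[LAD, FAD]` range intersects a
bin; phyletic diversity counts tree edges (each terminal edge unioned with
its taxon's observed range) whose span intersects the bin, so ghost
lineages are included and phyletic ≥ taxic everywhere.  Default bins are
the seven named intervals with ICS-style bounds
145–100.5–66–56–33.9–23.03–5.333–0 Ma; the three default strata are
170–91.1, 91.1–55.5 and 55.5–0 Ma.

## Synthetic data

`simulate_fossil_tree` grows a birth–death tree forward from an origin
time; each terminal lineage accrues Poisson(ψ) fossil occurrences over
its lifespan, sampled taxa take FAD/LAD from their occurrence extremes,
and unsampled lineages are pruned (occurrences are attached to terminal
lineages only, so every sampled taxon is a tip — the generator does not
produce sampled ancestors).  `simulate_ranges` runs the range process
forward (Gillespie anagenesis per stratum, cladogenesis from the model's
event table) and logs the true events in the same taxonomy the stochastic
mapper counts.  A replicate in which any lineage hits the null range is
rejected and redrawn, so simulated datasets live in the conditioned space
the likelihood observes.

That conditioning has one important consequence, documented here because
it shaped the validation design: under DEC- and DIVALIKE-style
cladogenesis every node restarts a daughter in a single area, so on large
trees the no-null condition censors precisely the realisations that carry
the extinction-rate signal, and `e` becomes unrecoverable (fitted rates
collapse to 0) for any `e` large enough to estimate.  The
parameter-recovery study therefore simulates and fits the
copy-cladogenesis (BAYAREA-like) family — where the conditioning is mild —
with generating rates `d = 0.03`, `e = 0.01 /Myr` over 4 areas on fossil
birth–death trees of 150–450 tips around a 300-tip design point (birth
0.09, death 0.03, ψ 0.15 /Myr, origin 95 Ma).  Under those conditions the
median relative errors of both rates are well inside the 25% envelope and
the fitted founder weight rank-tracks the truth (Spearman ρ ≈ 0.95 in the
check suite).  What passing these tests does *not* show: recovery of `e`
under subdivision-heavy cladogenesis on deep trees, or robustness to
preservation that varies across lineages — real fossil data violate both.

The pleurodire-style fixture provides the 10 study areas (South America,
Africa, North America, Madagascar, Australia, Europe, India, Arabia/
Middle East, East Asia, Antarctica — the last with no tip presences yet a
legal state component), the three strata, and the seven bins.  Its
distance matrices are synthetic round numbers that merely grow with
stratigraphic youth to exercise the `x` machinery; the original study's
distances live only in its supplementary material and are not reproduced.

## Problem sizes and numerics

The reproduction script runs the full nine-model grid on a simulated
~100-tip, 10-area study with `m = 2` (56 range states), 50 stochastic
maps, 1999 ERM null trees, and a 20-replicate recovery study; the test
suite validates the likelihood against exhaustive enumeration on ≤ 4-tip,
≤ 3-area instances (210 random draws), the path sampler against rejection
sampling at 10⁴ draws, and mapping means against 400 forward simulations.
Matrix exponentials fall back from eigendecomposition to
scaling-and-squaring when the eigenbasis is ill-conditioned (condition
number > 1e12 or reconstruction residual > 1e-9·‖Q‖).  Propagator entries
can carry ~1e-15 negative round-off; samplers clip weight vectors at zero.

## Known limitations

* The BAYAREA-like family is the likelihood analogue of the original
  Bayesian method; no MCMC is implemented.
* The root-state convention and optimiser differ in unknown ways from the
  reference implementations, so absolute LnL values on real datasets are
  comparable only up to those conventions.
* The shift detector is a concretely defined ERM tail statistic, not a
  re-implementation of any specific legacy tree-shape statistic.
* Whole-replicate rejection of null-range realisations biases simulated
  datasets toward low-extinction histories on deep trees (see above).
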