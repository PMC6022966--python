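# Methods

## The model

`ptdyn` treats a plate of single-cell transcriptomes as samples from a
one-dimensional continuum of states: each cell sits at an unobserved
progression coordinate, and the goal is to (i) recover the ordering,
(ii) describe how functional programs change along it, and (iii)
classify how pairs of programs relate geometrically. The trajectory
model is deliberately linear (non-branching); datasets with distinct
genetic backgrounds must be processed independently, because mixing
branches makes a linear ordering meaningless. Pseudotime carries no
time unit — it is an ordering, not a clock.

## Preprocessing

Cells in which *every* listed housekeeping gene (default ACTB and
GAPDH) has FPKM ≤ 0 are removed; zero is the only unambiguous
"not expressed" on the FPKM scale, and a cell with both housekeepers
silent is a failed library rather than a biological state. Quantile
normalization then forces one common value distribution across cells
(reference = across-column mean of sorted columns; ties receive the
mean of the reference over their rank span, which makes the transform
idempotent and matches the convention of limma's
`normalizeQuantiles`). Cell-cycle correction is not performed here;
a pre-corrected matrix can be supplied instead (set
`quantile_normalized` accordingly). Gene-level scores for everything
downstream are per-gene z-scores of log2(FPKM + 1) across cells
(population SD); zero-variance genes carry no ordering information and
are dropped with a warning.

## Pseudotime

Cell–cell similarity is computed on the standardized log expression of
all retained genes. The default distance is **1 − Spearman rank
correlation** between cell profiles. Pearson correlation distance and
euclidean distance are available (`metric=`); rank correlation is the
default because dropout zeros become ≈ −2 SD outliers on the
standardized log scale, and in simulations at 20% dropout they visibly
corrupt Pearson similarity (median recovery ρ ≈ 0.88 vs ≈ 0.93 for
ranks) while leaving rank correlation nearly untouched. Both
correlation metrics are undefined for a cell with zero variance across
genes — which happens in degenerate noise-free single-program
simulations — and the error message points to the euclidean
alternative used in those checks.

The graph ensemble follows the original Wanderlust construction: per
graph, every cell keeps a uniform without-replacement sample of l of
its k nearest neighbors (defaults k = 16, l = 8, 20 graphs); edges are
symmetrized and weighted by distance. k = 16 suits plates of 50–100
cells; orderings are stable for k anywhere in 10–20 (grid-median
Spearman ≥ 0.95 against the default, with dips to ≈ 0.94 at the grid
extremes under the default noise). Subsampled graphs can fragment on
small plates, so each graph is repaired deterministically by repeatedly
adding the globally shortest edge joining two components. Per graph,
a cell's trajectory value is its weighted shortest-path distance from
the start cell; PT is the across-graph mean affinely rescaled to
[0, 1]. Waypoint refinement is intentionally omitted — the mean of
shortest paths is the whole estimator.

Anchoring: the start cell maximizes the stromal GSZ (ties break to the
lexicographically smaller cell id); after ordering, if the mean
proliferative GSZ of the top PT decile is below that of the bottom
decile, PT is flipped (1 − PT) and re-anchored. The orientation step is
idempotent. Note that when the early program saturates (a sigmoid
plateau), any plateau cell can carry the maximal anchor signature; the
start cell is guaranteed to be *early*, not to be *the earliest*.

**Slow component.** Sorted PT versus normalized cell rank is fitted
with one line and with a continuous two-segment line whose knot is
scanned over all interior ranks. If the two-segment fit reduces the
residual sum of squares by at least 25% (relative; configurable), the
fitted PT at the knot is reported as PT*, the boundary between the
initial "slow" phase (many near-identical cells) and the faster later
phase. An exactly linear curve reports no breakpoint (an absolute RSS
floor guards the degenerate 0/0 case).

## Gene set Z-score

For gene-level scores x_g in one cell, a set of m genes among N scored
genes gets

    GSZ = (S − m·μ) / sqrt(m·σ²·(N − m)/(N − 1) + λ)

with S = Σ_{g∈set} x_g and μ, σ² the per-cell mean and population
variance over all genes. The variance term is the exact variance of a
sum of m scores drawn without replacement, so GSZ is the z-score of
the observed set sum against random same-size sets — verified in the
tests against a 100,000-draw Monte-Carlo oracle. λ (default 0) is an
additive variance regularizer for near-degenerate sets; λ > 0 defines
GSZ = 0 for a set covering the whole matrix, which is otherwise an
error. Two consequences worth remembering: GSZ(set) = −GSZ(complement)
at λ = 0, and GSZ is a *relative* measure — a program flat in absolute
terms loses score when other programs surge, so late "declines" of
saturated programs are partly arithmetic, not biology.

## Profiles and trajectories

Profiles are LOESS smooths of GSZ against PT, evaluated at the
observed PT values: a tri-cube-weighted local polynomial over the
nearest ⌈span·n⌉ cells (defaults span 0.5, degree 2 — degree 2 tracks
saturating plateaus that local-linear fits flatten; both are
configurable, and the degree-1 variant is cross-checked against
statsmodels' `lowess` in the tests). Smoothing is linear in the
response, so profiles commute with positive affine transforms of the
raw scores. Relative activity rescales a smoothed profile by its own
min and max to exactly [0, 1]; constant profiles are rejected as
degenerate rather than divided by zero. A biaxial trajectory pairs two
smoothed profiles point-wise along PT ("bivariate LOESS" = two
univariate fits sharing the PT axis).

## PT association

Each target (gene or set score) is tested with a Gaussian likelihood-
ratio test: full model = natural cubic regression spline of PT with
`spline_df` (default 3) degrees of freedom plus intercept, reduced =
intercept only; LR = 2(ℓ_full − ℓ_reduced) with maximized Gaussian
likelihoods. patsy's `cr` basis spans the constant, so the design is
built with `cr(df = spline_df + 1)`, giving exactly `spline_df` degrees
of freedom beyond the intercept. P-values use the exact finite-sample
null of this statistic — LR = n·log(1 + qF/(n − p)) with
F ~ F(q, n − p) — rather than the asymptotic χ²_q, which at n ≈ 80 is
measurably anti-conservative (empirical size 0.06–0.07 at α = 0.05
versus 0.048–0.062 for the exact reference; both distributions agree
as n grows). Benjamini–Hochberg adjustment is applied per run;
direction (correlated / anti-correlated with PT) comes from the sign
of the Spearman correlation, since the spline test itself is
sign-blind; exact ties default to "correlated".

## Trajectory typology

Five modes are distinguished: switch_like, parallel_anticorrelated,
divergent, orthogonal, curved (plus unclassified). Statistics are
computed on a *macro curve*: the relative-activity-scaled smooths
averaged within 12 rank bins along PT. Raw smoothed curves of noisy
data accumulate wiggle in their path length — genuinely straight
anti-diagonals measured curvature κ ≈ 0.4–0.5 before binning — so the
curvature index κ = 1 − chord/path is meaningful only at macro scale.
Axis orientation is judged by whether the minimum precedes the maximum
along PT (endpoints mislead when an early-completing program drifts
back, see the GSZ relativity note above).

Decision rules, in order, with all thresholds configurable
(`TypologyThresholds`):

1. **switch_like** — both axes have a net endpoint change ≥ 0.25 (this
   excludes rise-and-return humps, which switch into nothing) and one
   axis crosses 80% completion before the other crosses 20%.
2/3. **parallel_anticorrelated / divergent** — r ≤ −0.8 and κ ≤ 0.35.
   With multiple branches supplied and branch endpoints landing in
   opposite corners of the unit square, the call is divergent;
   a single branch cannot distinguish the two and takes the simpler
   parallel label. The anti-diagonal κ ceiling is 0.35 rather than a
   strict straightness bound because antagonistic pairs in realistic
   noise bow to κ up to ≈ 0.27 while remaining r ≤ −0.9.
4. **orthogonal** — |r| ≤ 0.3 and one axis moves by ≤ 0.3 net while
   the other traverses its 10–90% completion range.
5. **curved** — κ > 0.1 and nothing above fired.

Labels are invariant to axis swaps (the reported leading axis names the
same signature) and to affine rescaling of the raw scores.

## Synthetic data

The generator emulates a small FPKM plate with a known latent
pseudotime: t ~ Uniform(0, 1) per cell; per module,
log2-expression = baseline + amplitude·f(t) + N(0, noise_sd); shapes
f: [0, 1] → [0, 1] are a decreasing sigmoid (stromal), a delayed ramp
(cell cycle; also late_rise for glycolysis), a saturating exponential
(oxphos), a logistic/anti-logistic bipolar pair (MITF/AXL), linear
trends (TssA/TssP) and a constant. Values convert to the FPKM-like
scale by 2^x − 1 truncated at zero; each non-housekeeping entry drops
to zero with probability `dropout_rate`; an exact fraction
`frac_failed_cells` of cells has both housekeeping genes zeroed.
Defaults — baseline 3.0 (housekeeping 8.0) log2 units, amplitude 2.0
(a 4-fold swing), 40 genes per module, 400 background genes,
noise_sd 0.5, dropout 0.2 — were chosen as plausible for curated
signatures on small FPKM plates. The culture-sized fixture triplet
generates 93/60/85 cells with 9/6/8 failed cells, so housekeeping
filtering leaves 84/54/77 — the plate sizes the pipeline is aimed at.
The third culture flips MITF/AXL polarity, giving the two-branch
divergent geometry.

What the generator does **not** emulate: sequencing-read sampling,
batch effects, doublets, gene–gene correlation beyond module
membership, branching lineages, or non-uniform cell densities along
the trajectory. Passing tests therefore demonstrate correctness of the
algorithms under idealized-but-noisy conditions, not performance on
any particular real dataset. Typology stability checks rank cells by
the generator's true pseudotime so they measure the classifier, not
the orderer; ordering quality is measured separately by the recovery
checks (noise-free recovery is exact; at noise 0.5 + 20% dropout the
median Spearman against truth is ≈ 0.92).

## Problem sizes and numerical choices

Simulation-based checks use the sizes a small-plate study would have:
84–100 cells, ~700 genes, 10 seeds for recovery medians, 50 seeds for
typology stability, 2000 replicates for test calibration, 100,000
draws for the GSZ oracle. Edge weights are floored at 1e-12 so
identical profiles cannot create zero-weight edges; LOESS raises a
descriptive error when the span yields too few positively weighted
points; quantile normalization and relative activity are exact (not
merely approximate) at their boundary values by construction.

## Known limitations

- A single linear trajectory only; no branch detection.
- GSZ relativity (see above) can manufacture late declines of
  plateaued programs; interpret biaxial hooks with that in mind.
- The start-cell anchor assumes the stromal program is highest at the
  trajectory's origin; a dataset violating that assumption needs an
  explicit `start_cell`.
- The typology thresholds are committed definitions of qualitative
  modes, validated on the synthetic archetypes and fixtures; real
  datasets with weaker smoothing may need threshold adjustment via
  `TypologyThresholds`.
- Accession-scale analyses (re-deriving published per-culture cell
  counts and PT* values from deposited data) require the external
  dataset; the package ships culture-sized synthetic surrogates that
  exercise the same code paths with known ground truth.
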