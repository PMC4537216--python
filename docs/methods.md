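# Methods

## The piecewise profile model

A gene's normalized trajectory is modeled as a piecewise continuous
curve with a fixed origin `t0` (the first sampling time) and seven free
parameters: durations `t1..t4` (hours, ≥ 0) and amplitudes `A1..A3`
(dimensionless, ≥ 0).  The curve is flat at `A1` for `t1` hours, ramps
linearly to `A2` over `t2`, stays flat for `t3`, ramps to `A3` over
`t4`, and is flat thereafter.  `t1` (time to first inflection) and
`t2+t3+t4` (time from first inflection until the profile levels off)
are the biologically interpretable timescales; on a sparse grid the
inner durations `t2..t4` are individually degenerate whenever a ramp
falls between samples, but `t1`, `t2+t3+t4`, `A1` and `A3` remain well
constrained, and all downstream quantities use only those.

Zero-length ramps are jumps; the boundary point of a zero-length ramp
takes the value of the preceding plateau (an arbitrary measure-zero
convention, fixed and tested).  Multi-peak profiles are out of scope.

## Cost and fit ensembles

Fits minimize `F = Σ_j (d_j − s_j)² / σ_j²` where `d` is the replicate
mean and `σ` the replicate SD at each time.  Dividing by `σ²`
down-weights noisy points; because replicates can coincide, `σ` is
floored at `max(1e-6, 0.01 × mean(d))` per gene before fitting.

The optimizer is a classic DE/rand/1/bin population: 15 agents,
crossover rate 0.75, mixing (scale) factor 0.6, greedy selection (a
trial replaces its parent only on strictly smaller cost), iterated to
2000 generations or until the best cost improves by less than 1e-6
(relative) over 100 generations.  Twenty independent restarts are
pooled into the fit ensemble; the spread of its well-fitting members is
the confidence information used everywhere downstream.  A member is a
*good fit* if its mean absolute deviation from `d`, in units of `σ`, is
≤ 1 across the time course (boundary inclusive).

Three implementation details matter for reliability:

* initial durations are differences of sorted uniform knot positions,
  so initial knots cover the observation window uniformly and the
  knots-inside-window constraint holds by construction;
* mutants leaving the search box are reflected back inside rather than
  clipped, which preserves population diversity near the bounds;
* half of each initial population is *data-anchored*: knots taken from
  the sampling times, amplitudes read off the observed levels at those
  times.  DE then refines these candidates.  Without anchoring, 15-agent
  populations collapse prematurely on narrow noiseless basins.

Search bounds: each duration in `[0, T − t0]` with the duration sum
rescaled onto that span when exceeded; amplitudes in
`[0, 1.5 × max(d)]`, so fits may moderately overshoot the observed
maximum.  Fits are vectorized jointly over genes, restarts and agents;
with a fixed seed a single-profile fit is bit-reproducible, and a batch
run is bit-reproducible given the same batch composition.

## Behavioral classification

With `Δ12 = A2 − A1`, `Δ23 = A3 − A2` and a significance margin `δ`:
increase-then-decrease is *transient_up*, the mirror is
*transient_down*, significant changes in one direction only are *up* or
*down*, and no significant change is *flat*.  `δ` defaults to the
median replicate SD of the gene's profile, tying "significant" to the
measured noise on the same normalized scale.  A gene's call is the
majority vote among good-fit ensemble members; agreement below 0.9 (or
an empty good-fit set) yields *ambiguous*.  Raising the agreement bar
can only move genes into *ambiguous*, never out of it.

Gene sets are scored per category by the hypergeometric tail with
Benjamini–Hochberg adjustment across sets within a category; the
universe is the set of genes that survived preprocessing, not the
genome.  Pathway averaging takes the time-wise mean of max-normalized
profiles per set and flags sets whose mean range falls below 0.2 (on
the 0–1 scale) as flat, i.e. internally incoherent.

## Preprocessing ladder

Fitting path (both molecule types): drop genes with summed counts < 10
over the whole course; divide each sample by its total count (depth
normalization); for proteins, keep genes with ≥ 1.5 max/min fold change
of the replicate-mean profile (minimum floored at half a count at depth
scale); average replicates (mean, SD with the floor above); divide by
the profile maximum.  RNA uses a significance filter instead of the
fold-change filter: counts are scaled by median-of-ratios size factors
(per sample, the median over all-nonzero genes of count divided by the
gene's geometric mean), then each later time point is compared to the
first by a Welch t-test on `log(normalized + 0.5)` across replicates,
keeping genes with p < 0.05 at one or more time points.  This
self-contained test replaces an external count-model test; its
per-comparison null false-positive rate measures ≈ 0.035 at α = 0.05 on
negative-binomial null data (slightly conservative at n = 3).
BH adjustment across comparisons is available but off by default.
Residual rRNA counts are discarded before any relative RNA analysis.

## Regulation framework

Protein kinetics are `dp/dt = k_s·m(t) − k_d·p` with `m` the piecewise
transcript curve, solved in closed form on every linear segment (the
trajectory is advanced over the union of model knots and sampling
times, so grid values are exact).  Fast `k_d` makes protein track `m`;
`k_d = 0` makes it track the running integral `M(t)` (trapezoidal, so
exact for piecewise-linear `m` sampled at its knots; `M(t0) = 0` ties
the first rank across genes and is handled by average ranks).

Per gene, `ρ_prop = Spearman(p, m)` and `ρ_int = Spearman(p, M)` over
the time course (≥ 4 finite pairs required; constant series give a
missing value and exclusion from histograms).  Labels: proportional if
`ρ_prop > 0.70` and `ρ_prop ≥ ρ_int`; integral if `ρ_int > 0.70` and
`ρ_int > ρ_prop`; otherwise intermediate.  When both pass the
threshold the larger wins — the two sets are nearly exclusive in
practice because for declining transcripts the two statistics
anti-correlate strongly.

Two rank-degeneracy facts shape what this statistic can and cannot do:

* `M(t)` is strictly increasing, so any monotonically rising protein
  has `ρ_int = 1` regardless of its true kinetics.  The regimes are
  only separable for transcripts that eventually decline; regime
  benchmarks therefore use a declining-transcript cohort
  (`DECLINING_CATEGORY_MIX`, 70% down / 30% transient-down), which also
  matches the starvation biology being emulated, where the vast
  majority of differentially expressed transcripts shut off.
* Plateau time points are exactly tied in `m` but only nearly tied in
  the lagged protein, so `ρ_prop` saturates around 0.96–0.99 even for
  arbitrarily fast degradation.

The cross-sectional check correlates absolute protein level (mean
spectral counts) against length-normalized mean RNA counts across genes
at a single time point, dropping (and counting) genes absent from
either table.

## Operon analysis

Within each operon, all C(n,2) pairwise Spearman correlations of
profiled members are summarized by their mean (median selectable; both
are reported in the literature and they differ for skewed pair sets).
Inter-gene distance is the bp gap between consecutive coding regions
(1-based inclusive coordinates, overlaps clamped to 0); the distance
trend is the Spearman correlation of pair ρ against pair distance, with
all pairs used by default and an adjacent-only option.  Two alternative
explanations are scored alongside: mean protein level vs distance from
the transcript start, and vs coding length.

K-means clustering (Euclidean, Lloyd, best of 10 seeded restarts) uses
15 clusters for RNA and 25 for protein by default; centroids are
displayed ordered by time of maximum, then overall mean.  RNA-class
fractions report the per-sample share of mRNA/tRNA/rRNA/ncRNA reads,
optionally after discarding residual rRNA and renormalizing.

## The synthetic generator

The generator emulates a glucose-starvation time course: nine sampling
times (3, 4, 5, 6, 8, 24, 48, 168, 336 h), three biological replicates,
2000 genes, sequencing depth 2 × 10⁶ expected counts per sample for
both RNA and protein (spectral counts use the same count-noise layer;
absolute protein scaling is a pluggable hook).

* **Transcripts.**  Knots are anchored to sampling times (first
  inflection at 4–6 h, when the culture runs out of glucose), making
  every drawn parameter identifiable from the grid.  Amplitude draws
  enforce the category definition with a wide margin (e.g. down-genes
  fall to 10–35% of baseline), so each drawn profile classifies as its
  intended category in the δ→0 limit.  Default category mix: 20% up,
  30% down, 15% each transient, 20% flat; `STARVATION_CATEGORY_MIX`
  provides the down-dominated composition of the emulated biology.
* **Operons.**  Sizes 1–5 (half singletons), members consecutive with
  uniform 0–2 kb gaps and 0.3–3 kb coding lengths, sharing one
  transcript shape up to a lognormal per-gene scale.  Proteins acquire
  a distance-coupled lognormal noise random walk along the operon
  (variance proportional to the bp gap, SD 0.35 at 1 kb), so protein
  pair correlation decays with pair distance while transcript coherence
  stays exactly 1.
* **Kinetics.**  Translation efficiency is lognormal (σ = 0.8).
  Proportional genes draw `k_d` at least 10× the gene's fastest ramp
  rate; integral genes have `k_d = 0`; intermediate genes draw `k_d`
  log-uniform between 1/span and 1/min-grid-gap (≈ 0.003–1 h⁻¹), the
  timescales the grid can actually resolve.  Initial protein is the
  balanced-growth steady state `k_s·m0/(k_d + μ)` with pre-starvation
  dilution μ = 0.7 h⁻¹ — without dilution, stable proteins would start
  at enormous levels and decline monotonically, making them
  rank-indistinguishable from proportional genes.  Because a regime
  label is only meaningful if the noiseless dynamics classify that way,
  `k_d` is rejection-sampled (≤ 40 tries) against the noiseless
  correlation pair, with intermediates required to sit clearly below
  the 0.70 threshold (max ρ < 0.55); shapes for which no `k_d` can
  achieve the assigned regime keep the last draw.
* **Counts.**  Negative binomial with variance `μ + 0.05·μ²`
  (≈ 23% CV per point at typical depth, replicate profile correlations
  in the low 0.9s), independent per replicate, Poisson in the
  dispersion→0 limit.  Per-gene random streams derive from the master
  seed with fixed purpose keys, so adding genes or skipping a stage
  never perturbs existing draws.  A lighter lognormal level-noise layer
  (`simulate_replicate_levels`, given CV) serves benchmarks that need a
  controlled signal-to-noise ratio without compositional effects.

What the generator does **not** emulate: library-prep and GC biases,
rRNA-depletion chemistry, peptide detectability differences, missing
values, batch effects, growth-phase dilution after t0, or regulatory
coupling between genes beyond operon co-transcription.  Passing tests
therefore demonstrate correctness of the algorithms and recoverability
under idealized noise, not performance on real libraries.

## Problem sizes and numerical choices

Benchmarks use 50 profiles (noiseless DE recovery), 200 genes at 10% CV
(classification), 300 genes at 10% CV (regulation), 10 × 150 genes
(distance trend), 500 genes (null calibration), and one 2000-gene
end-to-end run; these sizes give stable statistics while keeping a full
validation run in the minutes range on one CPU.  Depth normalization of
a small closed gene set distorts within-gene time courses through the
changing pool total (a compositional effect shared by any relative
measurement); regime benchmarks therefore operate on absolute levels
with replicate noise, while the pipeline itself works on relative
levels exactly as a real experiment must.  Ties in Spearman statistics
use average ranks throughout.  The good-fit boundary (= 1) and the
classification threshold (> 0.70) conventions are inclusive and strict
respectively, as documented on the functions.
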