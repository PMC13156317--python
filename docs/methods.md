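# Methods

This note documents the models and procedures implemented in
`resurvey_trends`, the choices made where the design was genuinely
open, and what the synthetic-data experiments do and do not show.

## Scope and data model

The pipeline analyses *vegetation-plot time series*: repeated surveys
of (semi-)permanent plots recording percent cover of every vascular
plant taxon, possibly split over vegetation layers.  Series carry a
resurvey design (`permanent` or `semi_permanent`), EUNIS habitat codes
per observation (level 1 = broad class such as `T` forests; level 3 =
narrow type such as `T18`), and — after classification — a
habitat-change trajectory.  Species-level side tables hold functional
traits, a phylogeny (newick), Red-List threat and non-native flags,
and co-occurrence niche widths.

Taxon names are treated as already harmonized keys; matching to
external taxonomic backbones is out of scope.  The one in-scope
harmonization step is an advisory heuristic that flags probable name
mismatches: a taxon lost and a congeneric taxon gained between
consecutive observations, recurring in more than 40% of at least five
plots of one site.  Flags are never auto-corrected, because resolving
them requires consulting the original data owners.

## Cleaning rules

Three exclusion filters are applied, in order: experimentally
manipulated plots are dropped; series containing presence/absence-only
observations (no cover data) are dropped, since most indices need
abundances; and series whose plot size changed by a factor of *more
than* two are dropped ("more than" is read strictly, so a ratio of
exactly 2 is retained).  Series with plot sizes known for only some
observations are flagged and retained with the ratio rule skipped.
Filtering is idempotent and purely functional.

Cover values from multiple layers of one taxon are combined as
independently overlapping screens, `100·(1 − Π(1 − c_l/100))`; the
same combination across taxa gives the overlap-corrected total
vegetation cover, and is reused for species-group covers so that group
cover can never exceed total cover.

## Trajectory classification

A series' trajectory is read from the level-3 codes of its first and
last observation: missing codes → `unclassifiable`; identical codes →
`stable`; otherwise an expert prefix-mapping table is consulted
(longest matching prefix pair wins), and failing that a level-1
complexity ranking decides: rank increase → `succession`, decrease →
`disturbance`, equal or incomparable ranks → `other`.  The default
ranking is sparse/man-made (U, V) < grassland (R) < shrubland (S) <
forest (T), with waters, coastal habitats and mires on separate,
mutually incomparable scales — so a grassland-to-mire shift is
`other`, not succession.  The fallback is antisymmetric by
construction.  The shipped default map contains no expert rules; the
CSV format lets users load a full expert table when they have one.

## Niche widths

Species niche width follows the co-occurrence logic: generalists
co-occur with more varied species sets than specialists.  For each
species with ≥50 plot occurrences spread over ≥20 distinct series, 100
Monte-Carlo replicates each sample 20 of its occurrence observations
(at most one per series, without replacement) and compute the
multiple-site Simpson dissimilarity over the full species lists; the
niche width is the replicate mean.  The Simpson (turnover) component
is used because it ignores richness differences and nestedness.  The
bottom and top deciles of scored species are labelled specialists and
generalists; ties are broken by taxon name, and species with enough
occurrences but too few distinct series are skipped with a recorded
reason.

## Diversity indices

Per observation the pipeline computes: total cover, richness S,
Shannon H = −Σ p_i ln p_i and Pielou evenness H/ln S (undefined at
S = 1; both H and J are emitted because "diversity" and "evenness"
are used interchangeably in parts of the literature); functional
richness/evenness/divergence; Faith PD, MPD and MNTD; richness and
cover of threatened, non-native, specialist and generalist species;
and the cover-weighted mean niche width.

Functional indices operate in a *pool-wide* principal-axis projection
of the standardized trait matrix (default 4 axes) so hull volumes are
comparable across observations; dimensionality is a user knob because
the underlying FD methodology leaves it open.  FRic is the convex-hull
volume (missing when S ≤ m or the configuration is degenerate); FEve
is the Villéger minimum-spanning-tree evenness (missing below 3
species); FDiv is the abundance-weighted divergence from the hull
centroid.  Traits are log-transformed, z-scored (sample variance,
matching R's `scale`), and de-correlated either by an explicit keep
list or greedily at |r| > 0.6, dropping the member of the worst pair
with the larger mean |r| (ties: lexicographically later name) — the
ordering rule is ours, chosen for determinism.

Completeness gates: functional indices and the CWM niche width require
the trait-/width-covered species to reach 80% of total vegetation
cover (overlap-combined, consistent with how total cover is defined);
phylogenetic indices require every co-occurring taxon on the tree.
Faith PD includes the root path by default (configurable), and
MPD/MNTD default to the unweighted forms with abundance-weighted
variants available.

## Per-series trends and pooling

For each series and index, OLS of log(value + offset) on calendar
year gives the annual percentage change `(e^slope − 1)·100`; OLS on
the raw value gives the absolute annual change.  The offset is 0.5 for
exactly the four count indices (threatened, non-native, specialist,
generalist numbers) so zero counts stay usable; any other index with a
non-positive value excludes that series' log fit with a recorded
reason rather than silently offsetting.  With two observations the
slope is the difference quotient; repeated years (N-to-N designs)
simply enter the regression as repeated x-values.

Pooling uses a weighted linear model with analytic weights
w = ln(n_obs): estimate Σwx/Σw, SE `sqrt(Σw(x − x̄)²/((n−1)Σw))`, Wald
95% CI ±1.96 SE.  The variance convention (analytic weights) is stated
explicitly because the source methodology names only a "weighted
linear model".  Balanced pooling drops level-3 habitats with fewer
than ten series and gives each remaining habitat equal total weight;
by default the balanced weights do not additionally multiply by
ln(n_obs) (a switch enables the combined scheme).  Covariate-adjusted
pooling (resurvey design, relative plot-size change) reports the
intercept of the weighted regression on centered covariates.  The
pre/post-2000 comparison refits trends within each period and applies
a weighted Welch t-test with weights rescaled to the group n, which
reduces to the ordinary Welch test under equal weights; the exact
weighted-t variant in the source is unspecified, so this
frequency-weight convention is documented here.

## Dominance analysis

Variance in annual percentage changes is partitioned over four
predictor blocks: level-3 habitat, trajectory
(stable/succession/disturbance), their interaction, and the year of
the last observation (entered linearly).  Eligibility requires ≥2
level-3 habitats, each with ≥2 trajectories, each cell holding ≥10
series.  General dominance is computed by averaging each block's R²
increment over *admissible orderings* of block entry, where the
interaction may never precede its main effects (marginality: an
interaction R² without its mains is not interpretable).  Averaging
over orderings telescopes, so the shares sum to the full-model R²
exactly — the subset-averaging formulation would not preserve this
identity under the marginality constraint, which is why the ordering
formulation was chosen.  Under an orthogonal design the shares equal
each block's marginal R².  Shares can in principle be negative in
pathological designs; such cases are logged, not clipped.

## Gamma diversity

Gamma diversity per group (habitat × trajectory) is the pooled count
of unique taxa.  To avoid bias from changing plot numbers, every
ordered pair of calendar decades is evaluated on the plots observed in
both decades only (first observation in the earlier, last in the later
decade), and the gamma difference is divided by the distance in
decades.  Decades are fixed calendar decades (years ≡ 0 mod 10).
Plots are matched by plot id, falling back to series id where N-to-N
designs have no stable plot identity.  Across a group's decade-pair
trends, a two-sided one-sample t-test probes the mean and an exact
binomial test the sign balance; zero trends are excluded from the sign
test (a documented choice — they carry no sign information), decade
pairs are unweighted by temporal distance, and degenerate inputs
follow fixed conventions (single trend: t-test skipped; identical
nonzero trends: reported as p < 1e-12).

## Synthetic data generator

The generator emulates the structure of a continental resurvey
compilation without reproducing any real species or landscape:

* **Pool.** Traits are multivariate log-normal with exchangeable
  correlation (default 0.3, dimension 14); the phylogeny is a
  pure-birth (Yule) tree; threat and non-native flags are Bernoulli
  (10% / 8%); habitat affinities are Dirichlet rows whose
  concentration interpolates specialists (low) to generalists (high).
* **Series.** Observation counts follow the published distribution
  of the compiled dataset (55% with two, 17.7% three, 8.6% four;
  the remaining mass split geometrically over 5–10); spans follow the
  published bins (10.3% at 1–4 y, 43.1% at 5–10, 18.1% at 11–20, the
  rest log-uniform up to 103 y); trajectory proportions equal the
  published category shares.  Mean initial richness is 15 (Poisson) —
  a typical vegetation-plot richness.
* **Dynamics.** Covers are multiplied by e^(c·t) with log-normal
  noise (sd 0.2) and capped at 100; turnover is a Poisson number of
  richness-neutral swaps (0.05/yr default) so richness trend and
  turnover are orthogonal knobs; richness follows S0·e^(r·t) enforced
  by randomized rounding whose probabilities are chosen unbiased *on
  the log scale* (E[ln S_t] = ln S0 + r·t exactly), because the log
  slope is the estimand of the trend regression — this makes the
  injected ground truth exact under the estimator rather than only
  approximately so.  Successional and disturbance series switch
  species pool and EUNIS codes at the series midpoint; a configurable
  fraction of species occurs in two layers, with the split chosen so
  the layer combination reproduces the intended total cover exactly.

What the generator does **not** emulate: spatial structure and
autocorrelation, climate or land-use drivers, observer and relocation
error, realistic European species pools, phylogenetic signal in traits
or affinities, and temporally autocorrelated index noise.  Passing
parameter-recovery tests therefore demonstrates the correctness of
the estimators under the stated generative model, not the robustness
of the scientific conclusions to real-world survey artifacts.

## Validation experiments and problem sizes

`experiments.richness_recovery` injects a true +1.0 %/yr richness
trend into 500 two-observation series spanning 10 years, runs the full
richness→trend→pooling path, and checks (a) the pooled estimate lands
within Monte-Carlo error of 1.0 and (b) the Wald CI covers the truth
at close to nominal rate.  Coverage is estimated over 300 replicates:
a 100-replicate estimate of a ~95% coverage probability carries a
Monte-Carlo standard error of ≈2.2 percentage points, too coarse for
a reliable verdict against a 90% floor, whereas 300 replicates bring
it to ≈1.3 points.
`experiments.gamma_null_calibration` simulates 60 trend-free series
with turnover over 40-year windows and measures the decadal gamma
t-test's rejection rate over 200 replicates (expected ≈ the nominal
5%).  These sizes give standard errors small enough for the checks to
be informative while keeping the default test run fast; they are the
package's chosen experiment sizes, stated here so results are
reproducible.

## Numerical conventions

Missing values are empty fields on disk and NaN/None in memory.
Result files render floats with `%.10g`, making re-runs under the same
config and seed byte-identical.  All randomness flows from
`numpy.random.default_rng` seeds; the principal-axis projection fixes
signs by the largest loading; decile and correlation-pruning ties
break lexicographically.  Known limitations: no autocorrelation
correction in the per-series OLS, no mixed-effects pooling, no
rarefaction-based gamma estimators, and dominance p-values assume the
usual homoscedastic linear-model F distribution.
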