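# resurvey-trends

Habitat-specific trend analysis for vegetation-plot resurvey time
series: from long-format community tables (plot observation × taxon ×
layer percent cover) to per-series diversity trends, weighted pooled
trends, variance partitioning by habitat and habitat-change
trajectory, and decadal gamma-diversity trends.

It is written for community ecologists and macroecologists working
with repeated vegetation surveys (permanent or semi-permanent plots),
where the questions are: *is local plant diversity going up or down,
at what rate, and how does that depend on habitat type and on whether
the habitat itself is stable, undergoing succession, or disturbed?*
Because raw continental resurvey compilations are access-restricted,
the package ships a synthetic-data generator with known ground truth
so every stage is testable end to end.

## The statistics at its core

For each time series and diversity index *y*, OLS of log *y* on the
survey year gives the **annual percentage change**

    pct = (e^slope − 1) · 100,

with a constant 0.5 added before the log for the four count indices
(threatened, non-native, specialist, generalist species numbers).
Per-series trends are pooled with a weighted linear model using
analytic weights *w* = ln(n_obs):

    estimate = Σ wᵢxᵢ / Σ wᵢ,
    SE = sqrt( Σ wᵢ(xᵢ − x̄)² / ((n−1) Σ wᵢ) ),   CI₉₅ = estimate ± 1.96·SE.

The index battery per plot observation covers taxonomic diversity
(richness S, Shannon H = −Σ pᵢ ln pᵢ, Pielou J = H/ln S, overlap-
corrected total cover 100·(1 − Π(1 − cᵢ/100))), functional diversity
(FRic convex-hull volume, FEve minimum-spanning-tree evenness, FDiv
divergence, all in a pool-wide principal-axis trait space),
phylogenetic diversity (Faith PD, MPD, MNTD), species-group richness
and cover, and the community-weighted mean niche width.  Niche widths
come from co-occurrence: the mean multiple-site Simpson dissimilarity

    Σ_{i<j} min(b_ij, b_ji) / ( (Σ S_i − S_T) + Σ_{i<j} min(b_ij, b_ji) )

over repeated random subsets of the plots a species occupies.  Trend
variance is partitioned by dominance analysis (average R² increments
over admissible predictor orderings: level-3 habitat, trajectory,
their interaction, last observation year), and gamma diversity is
compared between calendar decades on the matched set of plots observed
in both decades.  `docs/methods.md` documents every formula, gate and
convention.

## Worked example

```python
import numpy as np
import resurvey_trends as rt
from resurvey_trends.trajectory import trajectory_shares, share_report

cfg = rt.SimConfig(n_series=200, richness_log_trend=np.log(1.005), seed=7)
pool = rt.generate_pool(cfg)
ds, truth = rt.simulate_dataset(pool, cfg, seed=8)
ds, report = rt.filter_dataset(ds)
rt.assign_trajectories(ds)
print("series retained:", ds.n_series, "observations:", ds.n_observations)
print("trajectory shares (%):", share_report(trajectory_shares(ds)))

ds.traits = rt.prepare_traits(ds.traits)
div, reasons = rt.compute_diversity(ds)
tt = rt.compute_all_trends(div, dataset=ds)

rich = tt[(tt["index"] == "richness") & tt["pct_per_year"].notna()]
pooled = rt.weighted_mean_trend(rich["pct_per_year"], rich["weight"], index="richness")
print(f"pooled richness trend: {pooled.estimate:+.2f} %/yr "
      f"(95% CI {pooled.ci_low:+.2f} to {pooled.ci_high:+.2f}, n={pooled.n_series})")
```

Output:

```
series retained: 200 observations: 602
trajectory shares (%): {'stable': 20.0, 'succession': 5.5, 'disturbance': 2.5, 'other': 22.5, 'unclassifiable': 49.5}
pooled richness trend: +0.48 %/yr (95% CI +0.42 to +0.53, n=200)
```

The generator injected a true +0.50 %/yr richness trend
(`truth.true_pct_per_year["richness"]`); the pipeline's pooled
estimate recovers it within its confidence interval, and the
trajectory classifier reproduces the categories the generator drew.

The same steps are available from the shell via
`resurvey-trends simulate | preprocess | niche | diversity | trends |
synthesize | gamma`, each writing CSV tables plus a run manifest
(config echo, seed, versions); see `resurvey-trends --help`.

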