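"""Pooling of per-series trends and variance partitioning.

The per-series annual percentage changes are pooled meta-analytically
with a weighted linear model: the pooled estimate is the weighted mean
``sum(w_i x_i) / sum(w_i)`` with analytic weights ``w_i = ln(n_obs)``,
its standard error ``sqrt(sum(w_i (x_i - xbar)^2) / ((n - 1) sum(w_i)))``
and the Wald 95% CI ``estimate +/- 1.96 SE``.  Variants: *balanced*
pooling gives every level-3 habitat equal total weight, subgroup
pooling runs per habitat x trajectory cell, and a weighted Welch
t-test compares trends fitted before versus after a split year.

Variance in the trends is partitioned by *dominance analysis*: the
full-model R² of a linear model with predictor blocks (level-3
habitat, trajectory, their interaction, year of last observation) is
decomposed into per-block shares by averaging each block's R²
increment over admissible orderings of block entry — admissible
meaning the interaction never precedes its main effects.  The shares
telescope to the full R² exactly, and equal the marginal R² of each
block under an orthogonal design.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import DataError

log = logging.getLogger(__name__)

__all__ = [
    "PooledTrend",
    "weighted_mean_trend",
    "balanced_mean_trend",
    "subgroup_trends",
    "weighted_ttest",
    "compare_periods",
    "DominanceResult",
    "dominance_analysis",
]

Z95 = 1.96


@dataclass
class PooledTrend:
    """Weighted pooled trend with Wald CI."""

    index: str = ""
    subgroup: str = "all"
    estimate: float = np.nan
    se: float = np.nan
    n_series: int = 0

    @property
    def ci_low(self) -> float:
        return self.estimate - Z95 * self.se

    @property
    def ci_high(self) -> float:
        return self.estimate + Z95 * self.se

    @property
    def significant(self) -> bool:
        return bool(np.isfinite(self.se) and (self.ci_low > 0 or self.ci_high < 0))

    def as_dict(self) -> dict:
        return dict(index=self.index, subgroup=self.subgroup,
                    estimate=self.estimate, se=self.se,
                    ci_low=self.ci_low, ci_high=self.ci_high,
                    n_series=self.n_series, significant=self.significant)


def _check_weights(x: np.ndarray, w: np.ndarray) -> None:
    if len(x) < 2:
        raise DataError("pooling needs at least two trend records")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise DataError("pooling weights must be positive and finite")


def weighted_mean_trend(values, weights, covariates: pd.DataFrame | None = None,
                        index: str = "", subgroup: str = "all") -> PooledTrend:
    """Intercept of a weighted linear model of the per-series trends.

    Without covariates this is the analytic-weight mean with
    ``SE = sqrt(sum w (x - xbar)^2 / ((n - 1) sum w))`` — reducing to
    the sample mean and classical SE under equal weights.  With
    covariates (e.g. resurvey design, relative plot-size change) the
    estimate is the intercept of the weighted regression after
    centering each covariate, i.e. the design-adjusted average trend.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    keep = np.isfinite(x)
    x, w = x[keep], w[keep]
    _check_weights(x, w)
    if covariates is not None:
        import statsmodels.api as sm
        C = covariates.loc[np.asarray(keep)] if len(covariates) == len(keep) else covariates
        C = C.apply(pd.to_numeric).astype(float)
        C = C - C.mean()
        X = sm.add_constant(C.values)
        fit = sm.WLS(x, X, weights=w).fit()
        return PooledTrend(index=index, subgroup=subgroup,
                           estimate=float(fit.params[0]), se=float(fit.bse[0]),
                           n_series=len(x))
    xbar = float((w * x).sum() / w.sum())
    n = len(x)
    se = float(np.sqrt((w * (x - xbar) ** 2).sum() / ((n - 1) * w.sum())))
    return PooledTrend(index=index, subgroup=subgroup, estimate=xbar, se=se,
                       n_series=n)


def balanced_mean_trend(trend_df: pd.DataFrame, value_col: str = "pct_per_year",
                        habitat_col: str = "eunis_l3_initial",
                        min_per_habitat: int = 10,
                        combine_obs_weight: bool = False,
                        index: str = "", ) -> PooledTrend:
    """Pooled trend with equal total weight per level-3 habitat type.

    Habitats with fewer than ``min_per_habitat`` series are excluded;
    each remaining series gets weight ``1 / n_habitat`` so every habitat
    contributes equally.  ``combine_obs_weight`` additionally multiplies
    by the ln(n_obs) series weight (off by default).
    """
    df = trend_df.dropna(subset=[value_col, habitat_col])
    counts = df[habitat_col].value_counts()
    keep_habitats = counts.index[counts >= min_per_habitat]
    df = df[df[habitat_col].isin(keep_habitats)]
    if df.empty or df[habitat_col].nunique() == 0:
        raise DataError("no habitat reaches the minimum number of series")
    w = 1.0 / df[habitat_col].map(counts).astype(float)
    if combine_obs_weight:
        w = w * df["weight"].astype(float)
    return weighted_mean_trend(df[value_col], w, index=index, subgroup="balanced")


def subgroup_trends(trend_df: pd.DataFrame, by=("eunis_l1_initial", "trajectory"),
                    value_col: str = "pct_per_year", weight_col: str = "weight",
                    min_series: int = 10) -> pd.DataFrame:
    """Weighted pooled trend per subgroup cell (e.g. habitat x trajectory).

    Empty cells are absent; cells with at least two series but fewer
    than ``min_series`` are computed and flagged ``eligible=False``;
    single-series cells carry the value with no SE and are ineligible.
    """
    rows = []
    grouped = trend_df.dropna(subset=[value_col]).groupby(list(by), sort=True,
                                                          dropna=True)
    for key, g in grouped:
        key = key if isinstance(key, tuple) else (key,)
        label = "/".join(str(k) for k in key)
        for index, gi in g.groupby("index", sort=True):
            n = len(gi)
            if n >= 2:
                pooled = weighted_mean_trend(gi[value_col], gi[weight_col],
                                             index=index, subgroup=label)
            else:
                pooled = PooledTrend(index=index, subgroup=label,
                                     estimate=float(gi[value_col].iloc[0]),
                                     n_series=1)
            row = pooled.as_dict()
            row.update({k: v for k, v in zip(by, key)})
            row["eligible"] = n >= min_series
            rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# weighted Welch t-test (period comparison)

def weighted_ttest(x1, w1, x2, w2) -> dict:
    """Two-sample Welch t-test with frequency-rescaled weights.

    Weights are rescaled within each group to sum to the group's n, so
    equal weights reproduce the ordinary unweighted Welch test.
    """
    out = {}
    means, variances, ns = [], [], []
    for x, w in ((np.asarray(x1, float), np.asarray(w1, float)),
                 (np.asarray(x2, float), np.asarray(w2, float))):
        keep = np.isfinite(x)
        x, w = x[keep], w[keep]
        _check_weights(x, w)
        n = len(x)
        w = w * n / w.sum()
        m = (w * x).sum() / w.sum()
        s2 = (w * (x - m) ** 2).sum() / (w.sum() - 1.0)
        means.append(m); variances.append(s2); ns.append(n)
    v1, v2 = variances[0] / ns[0], variances[1] / ns[1]
    se = np.sqrt(v1 + v2)
    if se == 0:
        t = 0.0 if means[0] == means[1] else np.inf * np.sign(means[0] - means[1])
        df = ns[0] + ns[1] - 2
    else:
        t = (means[0] - means[1]) / se
        df = (v1 + v2) ** 2 / (v1 ** 2 / (ns[0] - 1) + v2 ** 2 / (ns[1] - 1))
    p = float(2.0 * stats.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
    return dict(t=float(t), df=float(df), p=p,
                mean_1=means[0], mean_2=means[1], n_1=ns[0], n_2=ns[1])


def compare_periods(diversity_table: pd.DataFrame, dataset, split_year: int = 2000,
                    habitats: tuple = ("R", "S", "T"),
                    indices=None) -> pd.DataFrame:
    """Compare trends fitted from observations before vs after a split year.

    Observations are split at ``split_year`` (before: year < split;
    after: year >= split) *within* each series, trends are refitted per
    period, and a weighted Welch t-test (ln(n_obs) weights) compares
    the two trend samples per index, restricted to the named level-1
    habitat groups (grassland R, shrubland S, forest T by default).
    Comparisons where a period has fewer than two eligible series are
    skipped.
    """
    from .trends import compute_all_trends

    sid_l1 = {sid: (ts.first.eunis_l1 or "") for sid, ts in dataset.series.items()}
    rows = []
    for habitat in habitats:
        sids = [sid for sid, l1 in sid_l1.items() if l1 == habitat]
        sub = diversity_table[diversity_table["series_id"].isin(sids)]
        pre = sub[sub["year"] < split_year]
        post = sub[sub["year"] >= split_year]
        if pre.empty or post.empty:
            continue
        t_pre = compute_all_trends(pre, indices=indices)
        t_post = compute_all_trends(post, indices=indices)
        for index in sorted(set(t_pre["index"]) & set(t_post["index"])):
            g1 = t_pre[(t_pre["index"] == index) & t_pre["pct_per_year"].notna()]
            g2 = t_post[(t_post["index"] == index) & t_post["pct_per_year"].notna()]
            if len(g1) < 2 or len(g2) < 2:
                continue
            res = weighted_ttest(g1["pct_per_year"], g1["weight"],
                                 g2["pct_per_year"], g2["weight"])
            res.update(eunis_l1=habitat, index=index, split_year=split_year)
            rows.append(res)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# dominance analysis

TERMS = ("habitat_l3", "trajectory", "interaction", "last_obs_year")
_MAIN_TRAJECTORIES = ("stable", "succession", "disturbance")


@dataclass
class DominanceResult:
    """R² decomposition for one habitat x index group."""

    eligible: bool
    n_series: int = 0
    r2_full: float = np.nan
    shares: dict = field(default_factory=dict)
    p_value: float = np.nan
    reason: str = ""

    def as_dict(self) -> dict:
        d = dict(eligible=self.eligible, n_series=self.n_series,
                 r2_full=self.r2_full, p_value=self.p_value, reason=self.reason)
        for t in TERMS:
            d[f"share_{t}"] = self.shares.get(t, np.nan)
        return d


def _dummies(series: pd.Series) -> np.ndarray:
    d = pd.get_dummies(series.astype(str), drop_first=True)
    return d.values.astype(float)


def _r2(y: np.ndarray, blocks: list[np.ndarray]) -> float:
    X = np.column_stack([np.ones(len(y))] + blocks) if blocks else np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        return 0.0
    return float(1.0 - (resid ** 2).sum() / tss)


def _admissible_orders():
    for perm in itertools.permutations(TERMS):
        i = perm.index("interaction")
        if perm.index("habitat_l3") < i and perm.index("trajectory") < i:
            yield perm


def dominance_analysis(trend_df: pd.DataFrame, value_col: str = "pct_per_year",
                       min_per_cell: int = 10) -> DominanceResult:
    """General-dominance R² shares for one habitat-level-1 x index group.

    Predictor blocks: level-3 habitat (categorical), habitat-change
    trajectory (stable/succession/disturbance), their interaction, and
    the year of the last observation (linear).  The group is eligible
    only with >= 2 level-3 habitats, each holding >= 2 trajectories,
    each cell with >= ``min_per_cell`` series (the 2 x 2 x 10 rule).
    Shares are averages of R² increments over admissible block
    orderings (interaction after both mains) and sum to the full-model
    R² to numerical precision; the full-model ANOVA F-test p-value is
    reported alongside.
    """
    df = trend_df.dropna(subset=[value_col, "eunis_l3_initial", "trajectory",
                                 "last_obs_year"])
    df = df[df["trajectory"].isin(_MAIN_TRAJECTORIES)]

    cell = df.groupby(["eunis_l3_initial", "trajectory"]).size()
    good_cells = cell[cell >= min_per_cell]
    traj_per_l3 = good_cells.groupby(level=0).size()
    good_l3 = traj_per_l3.index[traj_per_l3 >= 2]
    if len(good_l3) < 2:
        return DominanceResult(eligible=False, n_series=len(df),
                               reason="fewer_than_2x2_replicated_cells")
    keep_pairs = {pair for pair in good_cells.index if pair[0] in good_l3}
    df = df[[tuple(p) in keep_pairs for p in
             zip(df["eunis_l3_initial"], df["trajectory"])]]
    if df["trajectory"].nunique() < 2:
        return DominanceResult(eligible=False, n_series=len(df),
                               reason="single_trajectory_level")

    y = df[value_col].values.astype(float)
    h = _dummies(df["eunis_l3_initial"])
    t = _dummies(df["trajectory"])
    inter = _dummies(df["eunis_l3_initial"].astype(str) + ":" + df["trajectory"].astype(str))
    yr = (df["last_obs_year"].values.astype(float)
          - df["last_obs_year"].values.mean())[:, None]
    blocks = {"habitat_l3": h, "trajectory": t, "interaction": inter,
              "last_obs_year": yr}

    cache: dict[frozenset, float] = {}

    def r2_of(terms: frozenset) -> float:
        if terms not in cache:
            cache[terms] = _r2(y, [blocks[b] for b in TERMS if b in terms])
        return cache[terms]

    totals = {term: 0.0 for term in TERMS}
    orders = list(_admissible_orders())
    for perm in orders:
        present: frozenset = frozenset()
        for term in perm:
            nxt = present | {term}
            totals[term] += r2_of(nxt) - r2_of(present)
            present = nxt
    shares = {term: totals[term] / len(orders) for term in TERMS}
    r2_full = r2_of(frozenset(TERMS))

    n = len(y)
    p_model = 1 + sum(b.shape[1] for b in blocks.values())
    df_resid = n - p_model
    if df_resid > 0 and r2_full < 1.0:
        f = (r2_full / (p_model - 1)) / ((1.0 - r2_full) / df_resid)
        p_value = float(stats.f.sf(f, p_model - 1, df_resid))
    else:
        p_value = np.nan
    neg = [t_ for t_, s in shares.items() if s < -1e-10]
    if neg:
        log.warning("negative dominance share(s) for %s", neg)
    return DominanceResult(eligible=True, n_series=n, r2_full=r2_full,
                           shares=shares, p_value=p_value)


def dominance_by_group(trend_table: pd.DataFrame, min_per_cell: int = 10
                       ) -> pd.DataFrame:
    """Run the dominance analysis per (level-1 habitat, index) group."""
    rows = []
    for (l1, index), g in trend_table.dropna(subset=["eunis_l1_initial"]).groupby(
            ["eunis_l1_initial", "index"], sort=True):
        res = dominance_analysis(g, min_per_cell=min_per_cell)
        row = res.as_dict()
        row.update(eunis_l1=l1, index=index)
        rows.append(row)
    return pd.DataFrame(rows)
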