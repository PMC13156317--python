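import numpy as np
import pandas as pd
import pytest
from scipy import stats

from resurvey_trends import (
    DataError, balanced_mean_trend, dominance_analysis, subgroup_trends,
    weighted_mean_trend, weighted_ttest,
)
from resurvey_trends.synthesis import _r2, dominance_by_group


# ------------------------------------------------------- weighted mean

def test_equal_weights_reduce_to_sample_mean_and_classical_se():
    x = np.array([1.0, 2.0, 4.0, 7.0])
    p = weighted_mean_trend(x, np.ones(4))
    assert p.estimate == pytest.approx(x.mean())
    assert p.se == pytest.approx(x.std(ddof=1) / np.sqrt(4))
    assert p.ci_high - p.ci_low == pytest.approx(2 * 1.96 * p.se)


def test_log_n_obs_weighting_hand_example():
    # x = (0, 4) with n_obs = (2, 8): weights ln2 : ln8 = 1 : 3
    p = weighted_mean_trend([0.0, 4.0], [np.log(2), np.log(8)])
    assert p.estimate == pytest.approx(3.0)


def test_identical_values_give_degenerate_ci():
    p = weighted_mean_trend([2.5, 2.5, 2.5], [1.0, 2.0, 3.0])
    assert p.estimate == 2.5
    assert p.se == 0.0
    assert p.significant


def test_pooling_rejects_bad_inputs():
    with pytest.raises(DataError):
        weighted_mean_trend([1.0], [1.0])
    with pytest.raises(DataError):
        weighted_mean_trend([1.0, 2.0], [1.0, 0.0])


def test_covariate_adjustment_matches_intercept_only_when_balanced():
    rng = np.random.default_rng(0)
    x = rng.normal(1.0, 0.5, 200)
    cov = pd.DataFrame({"design": np.r_[np.zeros(100), np.ones(100)]})
    p0 = weighted_mean_trend(x, np.ones(200))
    p1 = weighted_mean_trend(x, np.ones(200), covariates=cov)
    # centered balanced covariate leaves the intercept at the mean
    assert p1.estimate == pytest.approx(p0.estimate, abs=1e-9)


# ------------------------------------------------------ balanced mean

def _trend_frame(habitats, values):
    return pd.DataFrame({"eunis_l3_initial": habitats, "pct_per_year": values,
                         "weight": 1.0})


def test_balanced_mean_equal_habitat_impact():
    df = _trend_frame(["A"] * 20 + ["B"] * 10, [1.0] * 20 + [3.0] * 10)
    p = balanced_mean_trend(df)
    assert p.estimate == pytest.approx(2.0)


def test_balanced_mean_drops_small_habitats():
    df = _trend_frame(["A"] * 20 + ["B"] * 9, [1.0] * 20 + [3.0] * 9)
    p = balanced_mean_trend(df)
    assert p.estimate == pytest.approx(1.0)  # B excluded, only A left
    with pytest.raises(DataError):
        balanced_mean_trend(_trend_frame(["A"] * 5, [1.0] * 5))


def test_balanced_mean_invariant_to_replicating_a_habitat():
    df = _trend_frame(["A"] * 10 + ["B"] * 10, [1.0] * 10 + [3.0] * 10)
    rep = _trend_frame(["A"] * 30 + ["B"] * 10, [1.0] * 30 + [3.0] * 10)
    assert balanced_mean_trend(df).estimate == pytest.approx(
        balanced_mean_trend(rep).estimate)


# ---------------------------------------------------------- subgroups

def _subgroup_frame():
    rows = []
    for l1, traj, vals in [("R", "stable", [1.0, 2.0, 3.0]),
                           ("R", "succession", [4.0, 6.0]),
                           ("T", "stable", [0.5])]:
        for i, v in enumerate(vals):
            rows.append(dict(series_id=f"{l1}{traj}{i}", index="richness",
                             eunis_l1_initial=l1, trajectory=traj,
                             pct_per_year=v, weight=1.0))
    return pd.DataFrame(rows)


def test_subgroup_trends_cells():
    out = subgroup_trends(_subgroup_frame(), min_series=2)
    out = out.set_index(["eunis_l1_initial", "trajectory"])
    assert out.loc[("R", "stable"), "estimate"] == pytest.approx(2.0)
    assert not out.loc[("T", "stable"), "eligible"]
    assert ("S", "stable") not in out.index  # empty cells absent


def test_subgroup_cells_pool_back_to_habitat_mean():
    df = _subgroup_frame()
    out = subgroup_trends(df, min_series=2).set_index(["eunis_l1_initial", "trajectory"])
    r = df[df.eunis_l1_initial == "R"]
    whole = weighted_mean_trend(r.pct_per_year, r.weight).estimate
    n = out.loc[("R", "stable"), "n_series"], out.loc[("R", "succession"), "n_series"]
    est = out.loc[("R", "stable"), "estimate"], out.loc[("R", "succession"), "estimate"]
    recombined = (est[0] * n[0] + est[1] * n[1]) / sum(n)  # equal weights
    assert recombined == pytest.approx(whole)


# ------------------------------------------------------ weighted t-test

def test_equal_weights_match_scipy_welch():
    rng = np.random.default_rng(1)
    x1, x2 = rng.normal(0, 1, 30), rng.normal(0.5, 2, 40)
    res = weighted_ttest(x1, np.ones(30), x2, np.ones(40))
    ref = stats.ttest_ind(x1, x2, equal_var=False)
    assert res["t"] == pytest.approx(ref.statistic)
    assert res["p"] == pytest.approx(ref.pvalue)


def test_identical_groups_t_zero_p_one():
    x = np.array([1.0, 2.0, 3.0])
    res = weighted_ttest(x, np.ones(3), x, np.ones(3))
    assert res["t"] == pytest.approx(0.0)
    assert res["p"] == pytest.approx(1.0)


def test_separated_groups_reject():
    rng = np.random.default_rng(2)
    res = weighted_ttest(rng.normal(0, 0.01, 20), np.ones(20),
                         rng.normal(5, 0.01, 20), np.ones(20))
    assert res["p"] < 1e-3


# ------------------------------------------------------ dominance

def _dominance_frame(n_per_cell=12, noise=1.0, seed=0, effects=None):
    rng = np.random.default_rng(seed)
    effects = effects or {}
    rows = []
    for l3 in ("R22", "R35"):
        for traj in ("stable", "succession"):
            for i in range(n_per_cell):
                y = (effects.get("l3", 0.0) * (l3 == "R35")
                     + effects.get("traj", 0.0) * (traj == "succession")
                     + effects.get("inter", 0.0) * (l3 == "R35") * (traj == "succession")
                     + noise * rng.standard_normal())
                rows.append(dict(eunis_l3_initial=l3, trajectory=traj,
                                 last_obs_year=int(rng.integers(1990, 2020)),
                                 pct_per_year=y, index="richness",
                                 eunis_l1_initial="R"))
    return pd.DataFrame(rows)


def test_dominance_shares_sum_to_full_r2():
    df = _dominance_frame(effects={"l3": 1.0, "traj": 0.5, "inter": 0.7})
    res = dominance_analysis(df)
    assert res.eligible
    assert sum(res.shares.values()) == pytest.approx(res.r2_full, abs=1e-8)
    assert res.p_value < 0.05


def test_orthogonal_mains_get_their_marginal_r2():
    # balanced 2x2 design, exact main effects, constant year, no interaction
    df = _dominance_frame(noise=0.0, effects={"l3": 2.0, "traj": 1.0})
    df["last_obs_year"] = 2000
    res = dominance_analysis(df)
    y = df["pct_per_year"].values
    h = pd.get_dummies(df["eunis_l3_initial"], drop_first=True).values.astype(float)
    t = pd.get_dummies(df["trajectory"], drop_first=True).values.astype(float)
    assert res.shares["habitat_l3"] == pytest.approx(_r2(y, [h]), abs=1e-8)
    assert res.shares["trajectory"] == pytest.approx(_r2(y, [t]), abs=1e-8)
    assert res.shares["interaction"] == pytest.approx(0.0, abs=1e-8)
    assert res.shares["last_obs_year"] == pytest.approx(0.0, abs=1e-8)


def test_dominance_shares_nonnegative_on_noisy_design():
    res = dominance_analysis(_dominance_frame(noise=2.0, seed=5,
                                              effects={"l3": 1.0}))
    for share in res.shares.values():
        assert share >= -1e-10


def test_single_trajectory_group_is_ineligible():
    df = _dominance_frame()
    df = df[df["trajectory"] == "stable"]
    res = dominance_analysis(df)
    assert not res.eligible


def test_underreplicated_cells_are_ineligible():
    res = dominance_analysis(_dominance_frame(n_per_cell=5))
    assert not res.eligible


def test_dominance_by_group_runs_per_habitat_and_index():
    df = _dominance_frame()
    out = dominance_by_group(df)
    assert len(out) == 1
    assert out.iloc[0]["eunis_l1"] == "R"
    assert out.iloc[0]["eligible"]
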