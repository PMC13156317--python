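import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from resurvey_trends import (
    DataError, SpeciesRecord, TraitTable, combine_layer_cover, filter_dataset,
    flag_name_mismatches, prepare_traits, total_vegetation_cover,
)

from conftest import make_dataset, make_obs


# ----------------------------------------------------------------- layers

@pytest.mark.parametrize("covers,expected", [
    ([60], 60.0),
    ([50, 50], 75.0),
    ([100, 40], 100.0),
    ([], 0.0),
])
def test_combine_layer_cover_values(covers, expected):
    assert combine_layer_cover(covers) == pytest.approx(expected)


def test_combine_layer_cover_rejects_out_of_range():
    with pytest.raises(DataError):
        combine_layer_cover([50, 120])


@given(st.lists(st.floats(0, 100), min_size=1, max_size=6))
@settings(deadline=None, max_examples=100)
def test_combine_layer_cover_properties(covers):
    c = combine_layer_cover(covers)
    assert 0 <= c <= 100 + 1e-12
    assert c >= max(covers) - 1e-9                     # monotone: adding layers
    perm = list(reversed(covers))
    assert combine_layer_cover(perm) == pytest.approx(c)  # permutation-invariant


@pytest.mark.parametrize("species,expected", [
    ({"a b": 30, "c d": 30}, 51.0),
    ({}, 0.0),
    ({"a b": 80}, 80.0),
])
def test_total_vegetation_cover(species, expected):
    obs = make_obs("o", "s", 2000, species)
    assert total_vegetation_cover(obs) == pytest.approx(expected)


def test_total_cover_combines_layers_per_taxon_first():
    obs = make_obs("o", "s", 2000, [("a b", "herb", 50), ("a b", "tree", 50)])
    assert total_vegetation_cover(obs) == pytest.approx(75.0)


# ---------------------------------------------------------------- filters

def _series_with_sizes(sizes, manipulated=(False, False)):
    return [make_obs(f"o{i}", "S", 2000 + 10 * i, {"a b": 10}, plot_size=sz,
                     manipulated=m)
            for i, (sz, m) in enumerate(zip(sizes, manipulated))]


def test_filter_removes_plot_size_ratio_above_two():
    ds = make_dataset({"S": _series_with_sizes([25, 100])})
    out, rep = filter_dataset(ds)
    assert out.n_series == 0
    assert rep.n_series_removed_plot_size_ratio == 1


def test_filter_keeps_ratio_exactly_two():
    ds = make_dataset({"S": _series_with_sizes([25, 50])})
    out, rep = filter_dataset(ds)
    assert out.n_series == 1
    assert rep.n_series_removed_plot_size_ratio == 0


def test_filter_removes_presence_absence_series():
    obs = make_obs("o1", "S", 2000, {})
    obs.records = [SpeciesRecord(taxon="a b", cover=None)]
    ds = make_dataset({"S": [obs, make_obs("o2", "S", 2010, {"a b": 5})]})
    out, rep = filter_dataset(ds)
    assert out.n_series == 0
    assert rep.n_series_removed_presence_absence == 1


def test_filter_removes_manipulated_plots():
    ds = make_dataset({"S": _series_with_sizes([25, 25, 25],
                                               manipulated=(False, True, False))})
    out, rep = filter_dataset(ds)
    assert rep.n_obs_removed_manipulated == 1
    assert out.series["S"].observations[1].year == 2020


def test_filter_partial_plot_size_flagged_not_removed():
    ds = make_dataset({"S": _series_with_sizes([25, None])})
    out, rep = filter_dataset(ds)
    assert out.n_series == 1
    assert rep.n_series_flagged_partial_plot_size == 1


def test_filter_is_idempotent(sim_dataset):
    ds, _ = sim_dataset
    once, rep1 = filter_dataset(ds)
    twice, rep2 = filter_dataset(once)
    assert once.n_series == twice.n_series
    assert rep2.n_obs_removed_manipulated == 0
    assert rep2.n_series_removed_plot_size_ratio == 0


# ------------------------------------------------------- name mismatches

def _mismatch_site(n_plots, n_affected):
    """n_plots single-plot series; n_affected show a Festuca swap."""
    series = {}
    for i in range(n_plots):
        sid = f"P{i}"
        if i < n_affected:
            obs = [make_obs(f"{sid}a", sid, 2000,
                            {"Festuca rubra": 10, "Festuca ovina": 5}),
                   make_obs(f"{sid}b", sid, 2010,
                            {"Festuca nigrescens": 10, "Festuca ovina": 5})]
        else:
            obs = [make_obs(f"{sid}a", sid, 2000, {"Poa annua": 10}),
                   make_obs(f"{sid}b", sid, 2010, {"Poa annua": 10})]
        series[sid] = obs
    return make_dataset(series)


def test_mismatch_flagged_above_threshold():
    flags = flag_name_mismatches(_mismatch_site(6, 5))
    assert len(flags) == 1
    f = flags[0]
    assert (f.lost_taxon, f.gained_taxon) == ("Festuca rubra", "Festuca nigrescens")
    assert f.n_plots_affected == 5 and f.fraction_affected == pytest.approx(5 / 6)


def test_mismatch_needs_at_least_five_plots():
    assert flag_name_mismatches(_mismatch_site(3, 3)) == []


def test_mismatch_threshold_is_strict():
    # 2 of 5 plots = 40% exactly: not flagged
    assert flag_name_mismatches(_mismatch_site(5, 2)) == []


def test_mismatch_unique_genera_emit_nothing(sim_dataset):
    ds, _ = sim_dataset
    renamed = {}
    for sid, ts in ds.series.items():
        for obs in ts.observations:
            obs.records = [SpeciesRecord(taxon=f"Uni{r.taxon.replace(' ', '')} sp",
                                         layer=r.layer, cover=r.cover)
                           for r in obs.records]
    assert flag_name_mismatches(ds) == []


# ------------------------------------------------------------ traits

def test_prepare_traits_standardizes():
    rng = np.random.default_rng(0)
    raw = TraitTable(pd.DataFrame(rng.lognormal(size=(40, 5)),
                                  columns=list("abcde")))
    out = prepare_traits(raw)
    assert out.standardized
    for col in out.values.columns:
        v = out.values[col].dropna()
        assert abs(v.mean()) < 1e-8
        assert abs(v.var(ddof=1) - 1) < 1e-8


def test_prepare_traits_drops_duplicated_column():
    rng = np.random.default_rng(1)
    x = rng.lognormal(size=30)
    raw = TraitTable(pd.DataFrame({"a": x, "b": x * 2.0, "c": rng.lognormal(size=30)}))
    out = prepare_traits(raw)  # log(b) = log(a) + log 2 -> r = 1
    assert sum(c in out.values.columns for c in ("a", "b")) == 1
    assert "c" in out.values.columns


def test_prepare_traits_keeps_independent_columns():
    rng = np.random.default_rng(2)
    raw = pd.DataFrame(rng.lognormal(size=(500, 3)), columns=list("abc"))
    out = prepare_traits(TraitTable(raw), r_cutoff=0.6)
    corr = np.log(raw).corr().abs().values
    assert (corr[np.triu_indices(3, 1)] < 0.6).all()  # independent by construction
    assert list(out.values.columns) == list("abc")


def test_prepare_traits_nonpositive_to_missing():
    raw = TraitTable(pd.DataFrame({"a": [1.0, -2.0, 3.0, 4.0, 2.0],
                                   "b": [1.0, 2.0, 3.0, 4.0, 5.0]}))
    out = prepare_traits(raw)
    assert out.values["a"].isna().sum() == 1


def test_prepare_traits_keep_list():
    rng = np.random.default_rng(3)
    raw = TraitTable(pd.DataFrame(rng.lognormal(size=(30, 4)), columns=list("abcd")))
    out = prepare_traits(raw, keep_list=["b", "d"])
    assert list(out.values.columns) == ["b", "d"]
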