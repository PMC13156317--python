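import numpy as np
import pytest

from resurvey_trends import (
    Dataset, PlotObservation, SimConfig, SpeciesRecord, TimeSeries,
    generate_pool, simulate_dataset,
)


def make_obs(obs_id, series_id, year, species, **kw):
    """Build an observation from {taxon: cover} or [(taxon, layer, cover)]."""
    if isinstance(species, dict):
        records = [SpeciesRecord(taxon=t, cover=c) for t, c in species.items()]
    else:
        records = [SpeciesRecord(taxon=t, layer=l, cover=c) for t, l, c in species]
    return PlotObservation(obs_id=obs_id, series_id=series_id, year=year,
                           records=records, **kw)


def make_dataset(series_specs, **kw):
    """series_specs: {sid: ([observations], design)} or {sid: [observations]}."""
    series = {}
    for sid, spec in series_specs.items():
        if isinstance(spec, tuple):
            obs, design = spec
        else:
            obs, design = spec, "permanent"
        series[sid] = TimeSeries(series_id=sid, observations=list(obs), design=design)
    return Dataset(series=series, **kw)


@pytest.fixture
def toy_dataset():
    """Two series, four observations, three taxa."""
    return make_dataset({
        "A": [make_obs("A1", "A", 2000, {"Genus001 sp0001": 40, "Genus001 sp0002": 10},
                       plot_size=25, eunis_l1="R", eunis_l3="R22"),
              make_obs("A2", "A", 2010, {"Genus001 sp0001": 50, "Genus002 sp0006": 5},
                       plot_size=25, eunis_l1="R", eunis_l3="R22")],
        "B": [make_obs("B1", "B", 1995, {"Genus002 sp0006": 70},
                       plot_size=100, eunis_l1="T", eunis_l3="T18"),
              make_obs("B2", "B", 2005, {"Genus002 sp0006": 60, "Genus001 sp0002": 15},
                       plot_size=100, eunis_l1="T", eunis_l3="T18")],
    })


@pytest.fixture(scope="session")
def default_pool():
    return generate_pool(SimConfig(seed=101))


@pytest.fixture(scope="session")
def sim_dataset(default_pool):
    """Medium synthetic dataset shared by read-only tests."""
    cfg = SimConfig(n_series=60, seed=101)
    ds, truth = simulate_dataset(default_pool, cfg, seed=202)
    return ds, truth
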