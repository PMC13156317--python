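"""Synthetic vegetation-plot time series with known ground truth.

The generator emulates the structure of a European resurvey compilation
so that every downstream stage — cleaning, trajectory classification,
niche widths, diversity indices, trend fitting, pooling, dominance and
gamma analysis — can be exercised against a known generative model:

* a species pool with correlated log-normal traits, a pure-birth
  phylogeny, Bernoulli threat/non-native flags, and Dirichlet habitat
  affinities (low concentration = specialists, high = generalists);
* per series: a habitat, a habitat-change trajectory, 2-10 observation
  years spanning 1-103 years, an initial community sampled by
  affinity with log-normal covers split across vegetation layers;
* through time: expected richness follows ``S0 * e^(r t)`` (enforced
  by randomized rounding so the expectation is exact under the
  log-linear trend estimand), covers are multiplied by ``e^(c t)``
  with multiplicative log-normal noise and capped at 100, and a
  Poisson number of richness-neutral composition swaps models
  turnover; successional/disturbance series switch their species pool
  and EUNIS codes at the series midpoint.

True annual percentage changes are ``(e^trend - 1) * 100`` exactly,
recorded in the returned :class:`GroundTruth`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import dendropy
import numpy as np
import pandas as pd

from .datamodel import (
    DataError, Dataset, Phylogeny, PlotObservation, SpeciesAttributes,
    SpeciesRecord, TimeSeries, TraitTable,
)

log = logging.getLogger(__name__)

__all__ = ["SimConfig", "SpeciesPool", "GroundTruth", "generate_pool",
           "simulate_dataset"]

# level-1 letters used by the generator, with terrestrial complexity ranks
_LETTERS = ("V", "R", "S", "T", "Q")  # man-made, grassland, shrubland, forest, mire
_TERRESTRIAL_RANK = {"V": 0, "R": 1, "S": 2, "T": 3}

# observation-count distribution: printed shares for 2/3/4 observations,
# remainder split geometrically over 5..10
_OBS_COUNTS = (2, 3, 4, 5, 6, 7, 8, 9, 10)
_OBS_PROBS = (0.55, 0.177, 0.086, 0.0935, 0.04675, 0.023375,
              0.0116875, 0.00584375, 0.00584375)

# span bins (years between first and last observation) with their shares
_SPAN_BINS = ((1, 4, 0.103), (5, 10, 0.431), (11, 20, 0.181), (21, 103, 0.285))


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the study conditions."""

    # species pool
    n_species: int = 120
    n_habitats: int = 5
    trait_dim: int = 14
    trait_correlation: float = 0.3
    trait_log_mean: float = 1.0
    trait_log_sd: float = 0.5
    birth_rate: float = 1.0
    p_threatened: float = 0.10
    p_nonnative: float = 0.08
    habitat_affinity_concentration: float = 0.5
    species_per_genus: int = 5
    dual_layer_fraction: float = 0.15

    # series structure
    n_series: int = 100
    obs_per_series: int | None = None      # fixed count; None = draw from mix
    span_years: int | None = None          # fixed span; None = draw from bins
    year_min: int = 1920
    year_max: int = 2023
    mean_initial_richness: float = 15.0
    cover_log_mean: float = math.log(10.0)
    cover_log_sd: float = 1.0

    # dynamics
    richness_log_trend: float = 0.0        # r in S0 * e^(r t)
    cover_log_trend: float = 0.0           # c in cover * e^(c t)
    cover_noise_sd: float = 0.2            # log-scale multiplicative noise
    turnover_rate: float = 0.05            # swaps per year
    # exact count fractions (13527/3263/1945/10819/27836 of 57390 series)
    trajectory_mix: Mapping[str, float] = field(default_factory=lambda: {
        "stable": 13527 / 57390, "succession": 3263 / 57390,
        "disturbance": 1945 / 57390, "other": 10819 / 57390,
        "unclassifiable": 27836 / 57390})
    switch_fraction: float = 0.5           # habitat switch point within the span

    seed: int | None = None

    def __post_init__(self):
        for p in (self.p_threatened, self.p_nonnative, self.dual_layer_fraction):
            if not (0.0 <= p <= 1.0):
                raise DataError(f"probability out of [0,1]: {p}")
        if self.n_series < 1:
            raise DataError("n_series must be >= 1")
        if self.n_habitats < 2:
            raise DataError("need at least two habitats")
        total = sum(self.trajectory_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise DataError(f"trajectory_mix must sum to 1, got {total}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        return cls(**dict(d))


@dataclass
class SpeciesPool:
    """Taxa with raw traits, phylogeny, flags and habitat affinities."""

    taxa: list[str]
    traits: TraitTable                    # raw, unstandardized
    phylogeny: Phylogeny
    attributes: SpeciesAttributes
    affinity: np.ndarray                  # species x habitat, rows sum to 1
    home_layer: list[str]
    second_layer: list[str | None]
    layer_split: np.ndarray               # fraction of cover in the home layer

    def __post_init__(self):
        if not np.allclose(self.affinity.sum(axis=1), 1.0, atol=1e-9):
            raise DataError("affinity rows must sum to 1")


@dataclass
class GroundTruth:
    """What the generator injected, for parameter-recovery checks."""

    series: pd.DataFrame                  # trajectory, habitats, years per series
    true_pct_per_year: dict[str, float]   # per index family
    species_breadth: pd.Series            # affinity breadth in (0, 1]


def _pure_birth_tree(taxa: list[str], rate: float, rng: np.random.Generator
                     ) -> Phylogeny:
    """Simulate a Yule tree over the given taxa (uniform label order)."""
    ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=ns)
    root = tree.seed_node
    start = {root: 0.0}
    active = [root]
    t = 0.0
    while len(active) < len(taxa):
        t += rng.exponential(1.0 / (rate * len(active)))
        i = int(rng.integers(len(active)))
        parent = active.pop(i)
        parent.edge.length = t - start[parent]
        for _ in range(2):
            child = parent.new_child()
            start[child] = t
            active.append(child)
    t_end = t + rng.exponential(1.0 / (rate * len(active)))
    order = rng.permutation(len(active))
    for label_idx, leaf_idx in enumerate(order):
        leaf = active[leaf_idx]
        leaf.edge.length = t_end - start[leaf]
        leaf.taxon = ns.new_taxon(taxa[label_idx])
    return Phylogeny(tree)


def generate_pool(config: SimConfig, rng: np.random.Generator | None = None
                  ) -> SpeciesPool:
    """Draw the species pool: traits, tree, flags and habitat affinities."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, d = config.n_species, config.trait_dim

    taxa = [f"Genus{i // config.species_per_genus + 1:03d} sp{i + 1:04d}"
            for i in range(n)]

    corr = np.full((d, d), config.trait_correlation)
    np.fill_diagonal(corr, 1.0)
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as exc:
        raise DataError("trait correlation matrix is not positive definite") from exc
    z = rng.standard_normal((n, d))
    logvals = config.trait_log_mean + config.trait_log_sd * (z @ chol.T)
    traits = TraitTable(values=pd.DataFrame(
        np.exp(logvals), index=taxa,
        columns=[f"trait{j + 1:02d}" for j in range(d)]))

    phylo = _pure_birth_tree(taxa, config.birth_rate, rng)

    attrs = SpeciesAttributes(table=pd.DataFrame({
        "threatened": rng.random(n) < config.p_threatened,
        "non_native": rng.random(n) < config.p_nonnative,
    }, index=taxa))

    alpha = np.full(config.n_habitats, config.habitat_affinity_concentration)
    affinity = rng.dirichlet(alpha, size=n)

    layers = np.array(["herb", "shrub", "tree"])
    home = list(rng.choice(layers, size=n, p=[0.6, 0.25, 0.15]))
    second: list[str | None] = []
    for i in range(n):
        if rng.random() < config.dual_layer_fraction:
            second.append(str(rng.choice([l for l in layers if l != home[i]])))
        else:
            second.append(None)
    split = 0.5 + 0.4 * rng.random(n)

    return SpeciesPool(taxa=taxa, traits=traits, phylogeny=phylo,
                       attributes=attrs, affinity=affinity, home_layer=home,
                       second_layer=second, layer_split=split)


# ----------------------------------------------------------------------
# series simulation

def _habitat_letter(h: int) -> str:
    return _LETTERS[h % len(_LETTERS)]


def _l3_code(h: int, variant: int) -> str:
    return f"{_habitat_letter(h)}{h // len(_LETTERS) + 1}{variant}"


def _habitats_by_letter(n_habitats: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for h in range(n_habitats):
        out.setdefault(_habitat_letter(h), []).append(h)
    return out


def _pick_habitats(trajectory: str, by_letter: dict[str, list[int]],
                   rng: np.random.Generator) -> tuple[int, int]:
    """Initial and final habitat indices realizing a trajectory."""
    terrestrial = [l for l in by_letter if l in _TERRESTRIAL_RANK]

    def pick(letters):
        letter = letters[int(rng.integers(len(letters)))]
        pool = by_letter[letter]
        return pool[int(rng.integers(len(pool)))]

    if trajectory == "succession":
        froms = [l for l in terrestrial
                 if any(_TERRESTRIAL_RANK[m] > _TERRESTRIAL_RANK[l] for m in terrestrial)]
        if froms:
            h1 = pick(froms)
            l1 = _habitat_letter(h1)
            ups = [l for l in terrestrial if _TERRESTRIAL_RANK[l] > _TERRESTRIAL_RANK[l1]]
            return h1, pick(ups)
    elif trajectory == "disturbance":
        froms = [l for l in terrestrial
                 if any(_TERRESTRIAL_RANK[m] < _TERRESTRIAL_RANK[l] for m in terrestrial)]
        if froms:
            h1 = pick(froms)
            l1 = _habitat_letter(h1)
            downs = [l for l in terrestrial if _TERRESTRIAL_RANK[l] < _TERRESTRIAL_RANK[l1]]
            return h1, pick(downs)
    elif trajectory == "other" and "Q" in by_letter and terrestrial:
        return pick(terrestrial), pick(["Q"])
    # stable, unclassifiable, or an unrealizable shift
    h = pick(sorted(by_letter))
    return h, h


def _draw_years(config: SimConfig, rng: np.random.Generator) -> list[int]:
    n_obs = (config.obs_per_series if config.obs_per_series is not None
             else int(rng.choice(_OBS_COUNTS, p=_OBS_PROBS)))
    if config.span_years is not None:
        span = config.span_years
    else:
        probs = [b[2] for b in _SPAN_BINS]
        lo, hi, _ = _SPAN_BINS[int(rng.choice(len(_SPAN_BINS), p=probs))]
        span = int(rng.integers(lo, hi + 1))
    span = min(span, config.year_max - config.year_min)
    first = int(rng.integers(config.year_min, config.year_max - span + 1))
    n_obs = min(n_obs, span + 1)
    years = {first, first + span}
    interior = np.arange(first + 1, first + span)
    extra = n_obs - 2
    if extra > 0 and len(interior) > 0:
        years.update(rng.choice(interior, size=min(extra, len(interior)),
                                replace=False).tolist())
    return sorted(int(y) for y in years)


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    lo = math.floor(x)
    frac = x - lo
    if frac <= 0:
        return lo
    return lo + (1 if rng.random() < frac else 0)


def _log_stochastic_round(x: float, rng: np.random.Generator) -> int:
    """Randomized rounding that is unbiased on the log scale.

    Returns floor(x) or ceil(x) with probabilities chosen so that
    ``E[ln(result)] = ln(x)`` exactly.  Used for richness targets: the
    injected trend acts on expected log-richness, the estimand of the
    log-linear trend regression, so the per-series slope estimator is
    exactly unbiased under the generator.
    """
    lo = math.floor(x)
    if x - lo <= 0:
        return lo
    if lo < 1:
        return 1
    q = (math.log(x) - math.log(lo)) / (math.log(lo + 1) - math.log(lo))
    return lo + (1 if rng.random() < q else 0)


def _sample_species(pool: SpeciesPool, habitat: int, k: int, exclude: set[int],
                    rng: np.random.Generator) -> list[int]:
    p = pool.affinity[:, habitat].copy()
    if exclude:
        p[list(exclude)] = 0.0
    avail = int((p > 0).sum())
    k = min(k, avail)
    if k == 0:
        return []
    p = p / p.sum()
    return list(rng.choice(len(p), size=k, replace=False, p=p))


def _records_for(pool: SpeciesPool, members: dict[int, float], dt: float,
                 config: SimConfig, rng: np.random.Generator
                 ) -> list[SpeciesRecord]:
    recs = []
    growth = math.exp(config.cover_log_trend * dt)
    for i in sorted(members):
        cover = members[i] * growth
        if config.cover_noise_sd > 0:
            cover *= math.exp(config.cover_noise_sd * rng.standard_normal())
        cover = min(cover, 100.0)
        cover = max(cover, 1e-3)
        taxon = pool.taxa[i]
        if pool.second_layer[i] is not None:
            c1 = cover * pool.layer_split[i]
            # second-layer cover chosen so the overlap combination
            # reproduces the taxon's total cover exactly
            c2 = 100.0 * (1.0 - (1.0 - cover / 100.0) / (1.0 - c1 / 100.0))
            recs.append(SpeciesRecord(taxon=taxon, layer=pool.home_layer[i],
                                      cover=round(c1, 6)))
            recs.append(SpeciesRecord(taxon=taxon, layer=pool.second_layer[i],
                                      cover=round(max(c2, 0.0), 6)))
        else:
            recs.append(SpeciesRecord(taxon=taxon, layer=pool.home_layer[i],
                                      cover=round(cover, 6)))
    return recs


def simulate_dataset(pool: SpeciesPool, config: SimConfig,
                     seed: int | None = None) -> tuple[Dataset, GroundTruth]:
    """Simulate the full dataset of time series from a species pool.

    Deterministic for a given (pool, config, seed): the same inputs
    reproduce the dataset bitwise.  ``seed`` overrides ``config.seed``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    by_letter = _habitats_by_letter(config.n_habitats)
    traj_names = list(config.trajectory_mix)
    traj_probs = np.array([config.trajectory_mix[t] for t in traj_names])

    series: dict[str, TimeSeries] = {}
    truth_rows = []
    for s in range(config.n_series):
        sid = f"S{s + 1:05d}"
        trajectory = traj_names[int(rng.choice(len(traj_names), p=traj_probs))]
        h1, h2 = _pick_habitats(trajectory, by_letter, rng)
        realized = trajectory if (h1 != h2 or trajectory in
                                  ("stable", "unclassifiable")) else "stable"
        years = _draw_years(config, rng)
        switch_year = years[0] + config.switch_fraction * (years[-1] - years[0])
        variant_1 = int(rng.integers(1, 4))
        variant_2 = int(rng.integers(1, 4))
        if realized == "stable":
            h2, variant_2 = h1, variant_1

        s0 = max(2, min(_stochastic_round(
            rng.poisson(config.mean_initial_richness) + 0.0, rng),
            config.n_species))
        members = {i: min(100.0, float(np.exp(
            config.cover_log_mean + config.cover_log_sd * rng.standard_normal())))
            for i in _sample_species(pool, h1, s0, set(), rng)}
        s0 = len(members)

        obs_list = []
        prev_year = years[0]
        for k, year in enumerate(years):
            dt = year - years[0]
            habitat = h1 if year < switch_year or realized == "stable" else h2
            if k > 0:
                # richness-neutral turnover swaps
                n_swaps = rng.poisson(config.turnover_rate * (year - prev_year))
                for _ in range(int(n_swaps)):
                    if not members or len(members) >= config.n_species:
                        break
                    out_i = sorted(members)[int(rng.integers(len(members)))]
                    add = _sample_species(pool, habitat, 1, set(members), rng)
                    if add:
                        members[add[0]] = members.pop(out_i)
                # enforce the trend on expected log-richness
                target = s0 * math.exp(config.richness_log_trend * dt)
                target_n = max(1, _log_stochastic_round(target, rng))
                if target_n > config.n_species:
                    log.warning("series %s: richness target %d exceeds pool size %d",
                                sid, target_n, config.n_species)
                    target_n = config.n_species
                while len(members) > target_n:
                    out_i = sorted(members)[int(rng.integers(len(members)))]
                    del members[out_i]
                if len(members) < target_n:
                    for i in _sample_species(pool, habitat,
                                             target_n - len(members),
                                             set(members), rng):
                        members[i] = min(100.0, float(np.exp(
                            config.cover_log_mean
                            + config.cover_log_sd * rng.standard_normal())))
            prev_year = year

            if realized == "unclassifiable":
                l1 = l3 = None
            else:
                h = h1 if (year < switch_year or realized == "stable") else h2
                v = variant_1 if (year < switch_year or realized == "stable") else variant_2
                l1, l3 = _habitat_letter(h), _l3_code(h, v)
            obs_list.append(PlotObservation(
                obs_id=f"{sid}_{k + 1}", series_id=sid, year=year,
                records=_records_for(pool, members, dt, config, rng),
                plot_size=25.0, eunis_l1=l1, eunis_l3=l3))
        design = "semi_permanent" if rng.random() < 0.3 else "permanent"
        series[sid] = TimeSeries(series_id=sid, observations=obs_list, design=design)
        truth_rows.append(dict(series_id=sid, trajectory=realized,
                               habitat_initial=h1, habitat_final=h2,
                               first_year=years[0], last_year=years[-1],
                               n_obs=len(years)))

    dataset = Dataset(series=series, traits=pool.traits,
                      phylogeny=pool.phylogeny, attributes=pool.attributes)
    true_pct = {
        "richness": (math.exp(config.richness_log_trend) - 1.0) * 100.0,
        "total_cover": (math.exp(config.cover_log_trend) - 1.0) * 100.0,
    }
    breadth = pd.Series(
        1.0 / (np.square(pool.affinity).sum(axis=1) * config.n_habitats),
        index=pool.taxa, name="breadth")
    truth = GroundTruth(series=pd.DataFrame(truth_rows).set_index("series_id"),
                        true_pct_per_year=true_pct, species_breadth=breadth)
    return dataset, truth
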