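"""Data cleaning: exclusion filters, layer combination, name-mismatch
flags, and trait-matrix preparation.

The layer-combination rule treats covers in different vegetation layers
as independently overlapping screens: a taxon recorded at covers
``c_1..c_L`` (percent) across layers occupies
``100 * (1 - prod(1 - c_l/100))`` percent of the plot.  The same
combination gives the total vegetation cover across taxa, accounting
for overlap among co-occurring species.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import DataError, Dataset, PlotObservation, TimeSeries, TraitTable

log = logging.getLogger(__name__)

__all__ = [
    "combine_layer_cover",
    "total_vegetation_cover",
    "combined_cover",
    "filter_dataset",
    "FilterReport",
    "flag_name_mismatches",
    "MismatchFlag",
    "prepare_traits",
]


def combine_layer_cover(covers: Sequence[float]) -> float:
    """Combine one taxon's percent covers across vegetation layers.

    ``100 * (1 - prod(1 - c/100))`` — independent-overlap combination;
    permutation-invariant, monotone in each layer, and capped at 100.
    """
    covers = np.asarray(list(covers), dtype=float)
    if covers.size == 0:
        return 0.0
    if np.any((covers < 0) | (covers > 100)):
        raise DataError(f"cover outside [0, 100]: {covers}")
    return float(100.0 * (1.0 - np.prod(1.0 - covers / 100.0)))


def combined_cover(covers: Iterable[float]) -> float:
    """Overlap-combined cover of a set of taxa (same formula as layers)."""
    return combine_layer_cover(list(covers))


def layer_combined_covers(obs: PlotObservation) -> dict[str, float]:
    """Per-taxon layer-combined covers for one observation.

    Records without a cover value are ignored (presence-only rows are
    removed earlier by :func:`filter_dataset`).
    """
    per_taxon: dict[str, list[float]] = {}
    for rec in obs.records:
        if rec.has_cover:
            per_taxon.setdefault(rec.taxon, []).append(float(rec.cover))
    return {t: combine_layer_cover(cs) for t, cs in sorted(per_taxon.items())}


def total_vegetation_cover(obs: PlotObservation) -> float:
    """Percent of plot area covered by vegetation, overlap-corrected."""
    return combined_cover(layer_combined_covers(obs).values())


# ----------------------------------------------------------------------
# exclusion filters

@dataclass
class FilterReport:
    """Counts of material removed per cleaning rule."""

    n_series_in: int = 0
    n_obs_in: int = 0
    n_obs_removed_manipulated: int = 0
    n_series_removed_presence_absence: int = 0
    n_series_removed_plot_size_ratio: int = 0
    n_series_removed_empty: int = 0
    n_series_flagged_partial_plot_size: int = 0
    n_series_out: int = 0
    n_obs_out: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def filter_dataset(dataset: Dataset) -> tuple[Dataset, FilterReport]:
    """Apply the cleaning rules and return a new dataset plus a report.

    Rules, in order: drop experimentally manipulated plots; drop series
    containing presence/absence-only observations (no cover data); drop
    series whose plot size changed by a factor of *more than* two
    (ratio exactly 2 is retained).  Series with plot sizes on some but
    not all observations are flagged and retained with the ratio rule
    skipped.  The operation is idempotent and never mutates its input.
    """
    rep = FilterReport(n_series_in=dataset.n_series, n_obs_in=dataset.n_observations)
    kept: dict[str, TimeSeries] = {}
    for sid in sorted(dataset.series):
        ts = dataset.series[sid]
        obs = [o for o in ts.observations if not o.manipulated]
        rep.n_obs_removed_manipulated += len(ts.observations) - len(obs)
        if not obs:
            rep.n_series_removed_empty += 1
            continue
        if any(o.is_presence_absence_only() for o in obs):
            rep.n_series_removed_presence_absence += 1
            continue
        sizes = [o.plot_size for o in obs if o.plot_size is not None]
        if sizes and len(sizes) < len(obs):
            rep.n_series_flagged_partial_plot_size += 1
            log.warning("series %s: plot size missing on some observations; "
                        "size-ratio rule skipped", sid)
        elif len(sizes) == len(obs) and sizes and min(sizes) > 0:
            if max(sizes) / min(sizes) > 2.0:
                rep.n_series_removed_plot_size_ratio += 1
                continue
        kept[sid] = TimeSeries(series_id=sid, observations=list(obs),
                               design=ts.design, trajectory=ts.trajectory)
    rep.n_series_out = len(kept)
    rep.n_obs_out = sum(len(s.observations) for s in kept.values())
    out = Dataset(series=kept, traits=dataset.traits,
                  phylogeny=dataset.phylogeny, attributes=dataset.attributes)
    return out, rep


# ----------------------------------------------------------------------
# taxonomic name-mismatch heuristic

@dataclass(frozen=True)
class MismatchFlag:
    """Advisory flag for a systematic congeneric loss/gain pair.

    Emitted when, within one research site, the same taxon was lost and
    a congeneric one gained between consecutive observations in more
    than 40% of at least five plots.  Flags are never auto-corrected.
    """

    site_id: str
    lost_taxon: str
    gained_taxon: str
    n_plots_affected: int
    n_plots_site: int
    fraction_affected: float


def _genus(taxon: str) -> str:
    return taxon.split()[0]


def flag_name_mismatches(
    dataset: Dataset,
    site_key: Mapping[str, str] | Callable[[str], str] | None = None,
) -> list[MismatchFlag]:
    """Flag probable taxonomic name mismatches within research sites.

    ``site_key`` maps a series id to its site/project group; by default
    the whole dataset is one site.  For each series, every pair of
    consecutive observations is scanned for a taxon lost and a
    different congeneric taxon gained while the genus stays present.
    A (lost, gained) pair occurring in strictly more than 40% of a
    site's plots — the site holding at least five plots — is flagged.
    """
    if site_key is None:
        keyfn = lambda sid: "dataset"
    elif callable(site_key):
        keyfn = site_key
    else:
        keyfn = lambda sid: site_key.get(sid, "dataset")

    sites: dict[str, dict[str, set[tuple[str, str]]]] = {}
    for sid in sorted(dataset.series):
        ts = dataset.series[sid]
        site = str(keyfn(sid))
        pairs = sites.setdefault(site, {}).setdefault(sid, set())
        for a, b in zip(ts.observations, ts.observations[1:]):
            lost = a.taxa - b.taxa
            gained = b.taxa - a.taxa
            for lt in lost:
                for gt in gained:
                    if lt != gt and _genus(lt) == _genus(gt):
                        # genus still present across the transition
                        genus = _genus(lt)
                        if any(_genus(t) == genus for t in b.taxa):
                            pairs.add((lt, gt))

    flags: list[MismatchFlag] = []
    for site in sorted(sites):
        per_series = sites[site]
        n_plots = len(per_series)
        if n_plots < 5:
            continue
        counts: dict[tuple[str, str], int] = {}
        for pairset in per_series.values():
            for pair in pairset:
                counts[pair] = counts.get(pair, 0) + 1
        for (lt, gt), n in sorted(counts.items()):
            frac = n / n_plots
            if frac > 0.40:
                flags.append(MismatchFlag(site, lt, gt, n, n_plots, frac))
    return flags


def mismatch_flags_frame(flags: Sequence[MismatchFlag]) -> pd.DataFrame:
    return pd.DataFrame([f.__dict__ for f in flags], columns=[
        "site_id", "lost_taxon", "gained_taxon",
        "n_plots_affected", "n_plots_site", "fraction_affected"])


# ----------------------------------------------------------------------
# trait preparation

def prepare_traits(traits: TraitTable, r_cutoff: float = 0.6,
                   keep_list: Sequence[str] | None = None) -> TraitTable:
    """Log-transform, z-score and de-correlate the trait matrix.

    Non-positive values cannot be log-transformed and become missing
    (with a warning); zero-variance columns are dropped.  Each retained
    column is standardized to mean 0 and sample variance 1 over its
    non-missing entries.  If ``keep_list`` is given the matrix is
    restricted to those traits; otherwise pairs with Pearson |r| above
    ``r_cutoff`` are resolved greedily, dropping the member with the
    larger mean |r| against all other traits (ties broken by dropping
    the lexicographically later name).
    """
    if traits.standardized:
        raise DataError("traits are already standardized")
    df = traits.values.copy()

    n_nonpos = int((df <= 0).sum().sum())
    if n_nonpos:
        log.warning("%d non-positive trait values set to missing before log", n_nonpos)
        df = df.where(df > 0)
    df = np.log(df)

    keep_cols = []
    for col in df.columns:
        v = df[col].dropna()
        if len(v) >= 2 and v.var(ddof=1) > 0:
            keep_cols.append(col)
        else:
            log.warning("trait %r dropped: zero variance or too few values", col)
    df = df[keep_cols]
    df = (df - df.mean()) / df.std(ddof=1)

    if keep_list is not None:
        missing = [t for t in keep_list if t not in df.columns]
        if missing:
            raise DataError(f"keep_list traits not available: {missing}")
        df = df[list(keep_list)]
    else:
        df = df[_prune_correlated(df, r_cutoff)]

    # re-standardize (restriction does not change columns, but be exact)
    df = (df - df.mean()) / df.std(ddof=1)
    return TraitTable(values=df, standardized=True)


def _prune_correlated(df: pd.DataFrame, r_cutoff: float) -> list[str]:
    cols = list(df.columns)
    corr = df.corr().abs()
    while True:
        sub = corr.loc[cols, cols].copy()
        np.fill_diagonal(sub.values, 0.0)
        if sub.values.size == 0 or np.nanmax(sub.values) <= r_cutoff:
            return cols
        i, j = np.unravel_index(np.nanargmax(sub.values), sub.shape)
        a, b = cols[i], cols[j]
        mean_a = sub.loc[a].mean()
        mean_b = sub.loc[b].mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        cols = [c for c in cols if c != drop]
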