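"""Core data model for vegetation-plot resurvey time series.

A *plot observation* is one survey of one vegetation plot: a calendar
year, optional plot size and EUNIS habitat codes, and a list of
species-by-layer percent-cover records.  Observations sharing a series
id form a *time series* (permanent or semi-permanent resurvey design).
A :class:`Dataset` bundles the time series with species-level side
tables: functional traits, a phylogeny, and attribute flags
(threatened, non-native, niche width).

Missing values are represented as ``None`` (scalars, codes) or ``NaN``
(numeric table cells); on disk they are empty fields.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "DataError",
    "SpeciesRecord",
    "PlotObservation",
    "TimeSeries",
    "TraitTable",
    "Phylogeny",
    "SpeciesAttributes",
    "Dataset",
    "DESIGNS",
    "TRAJECTORIES",
]

DESIGNS = ("permanent", "semi_permanent")
TRAJECTORIES = ("stable", "succession", "disturbance", "other", "unclassifiable")

YEAR_MIN, YEAR_MAX = 1900, 2100


class DataError(ValueError):
    """Raised when input data violate the model's invariants."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class SpeciesRecord:
    """Percent cover of one taxon in one vegetation layer.

    ``cover`` may be ``None``/NaN for presence-only records (these are
    filtered out before any index computation).
    """

    taxon: str
    layer: str = "all"
    cover: float | None = None

    def __post_init__(self):
        if not self.taxon or not str(self.taxon).strip():
            raise DataError("taxon name must be non-empty")
        if not _is_missing(self.cover) and not (0.0 <= float(self.cover) <= 100.0):
            raise DataError(
                f"cover must lie in [0, 100], got {self.cover!r} for {self.taxon!r}"
            )

    @property
    def has_cover(self) -> bool:
        return not _is_missing(self.cover)


@dataclass
class PlotObservation:
    """One survey of one plot: year, habitat codes and cover records."""

    obs_id: str
    series_id: str
    year: int
    records: list[SpeciesRecord] = field(default_factory=list)
    plot_size: float | None = None
    eunis_l1: str | None = None
    eunis_l3: str | None = None
    manipulated: bool = False
    plot_id: str | None = None  # pairing key for gamma decade matching

    def __post_init__(self):
        self.year = int(self.year)
        if not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise DataError(
                f"year {self.year} outside [{YEAR_MIN}, {YEAR_MAX}] (obs {self.obs_id})"
            )
        if self.eunis_l3 and not self.eunis_l1:
            raise DataError(
                f"obs {self.obs_id}: level-3 code {self.eunis_l3!r} without a level-1 code"
            )
        if self.plot_id is None:
            self.plot_id = self.series_id

    @property
    def taxa(self) -> set[str]:
        return {r.taxon for r in self.records}

    def is_presence_absence_only(self) -> bool:
        """True when the observation has records but none carries a cover value."""
        return bool(self.records) and not any(r.has_cover for r in self.records)


@dataclass
class TimeSeries:
    """Ordered observations of one (semi-)permanent plot or plot group."""

    series_id: str
    observations: list[PlotObservation]
    design: str = "permanent"
    trajectory: str | None = None  # filled by the trajectory classifier

    def __post_init__(self):
        if not self.observations:
            raise DataError(f"series {self.series_id}: needs at least one observation")
        if any(o.series_id != self.series_id for o in self.observations):
            raise DataError(f"series {self.series_id}: mixed series ids")
        if self.design not in DESIGNS:
            raise DataError(f"series {self.series_id}: unknown design {self.design!r}")
        self.observations = sorted(self.observations, key=lambda o: (o.year, o.obs_id))

    @property
    def years(self) -> list[int]:
        return [o.year for o in self.observations]

    @property
    def first(self) -> PlotObservation:
        return self.observations[0]

    @property
    def last(self) -> PlotObservation:
        return self.observations[-1]

    @property
    def span_years(self) -> int:
        return self.last.year - self.first.year


@dataclass
class TraitTable:
    """Species-by-trait matrix (rows = taxa, columns = traits).

    ``standardized`` marks that every column has been log-transformed and
    z-scored (mean 0, sample variance 1 over non-missing entries).
    """

    values: pd.DataFrame
    standardized: bool = False

    def __post_init__(self):
        self.values = self.values.astype(float)
        if self.values.index.has_duplicates:
            raise DataError("trait table has duplicated taxa")
        if self.standardized:
            self._check_standardized()

    def _check_standardized(self, tol: float = 1e-8) -> None:
        for col in self.values.columns:
            v = self.values[col].dropna()
            if len(v) < 2:
                continue
            if abs(v.mean()) > tol or abs(v.var(ddof=1) - 1.0) > tol:
                raise DataError(f"trait {col!r} is not standardized")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    @property
    def trait_names(self) -> list[str]:
        return list(self.values.columns)

    def complete_taxa(self) -> list[str]:
        """Taxa with no missing value in any retained trait."""
        return list(self.values.dropna().index)


class Phylogeny:
    """Rooted phylogeny with labelled leaves and non-negative branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` providing the two
    primitives the diversity indices need: patristic distances and
    Faith's phylogenetic diversity (branch-length sum of the subtree
    spanning a taxon set).
    """

    def __init__(self, tree: dendropy.Tree):
        tree.is_rooted = True
        self.tree = tree
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise DataError("phylogeny leaf labels are not unique")
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise DataError("phylogeny has a negative branch length")
        self._leaves = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        self._depths: dict | None = None
        self._pdm_cache: tuple[list[str], np.ndarray] | None = None

    # -- construction -------------------------------------------------
    @classmethod
    def from_newick(cls, source: str, *, is_path: bool = True) -> "Phylogeny":
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(schema="newick", **kwargs)
        return cls(tree)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick").strip()

    # -- queries ------------------------------------------------------
    @property
    def leaf_labels(self) -> list[str]:
        return sorted(self._leaves)

    def covers(self, taxa: Iterable[str]) -> bool:
        return all(t in self._leaves for t in taxa)

    def _node_depths(self) -> dict:
        if self._depths is None:
            depths = {}
            for nd in self.tree.preorder_node_iter():
                parent = nd.parent_node
                edge = nd.edge.length or 0.0
                depths[nd] = edge + (depths[parent] if parent is not None else 0.0)
            self._depths = depths
        return self._depths

    def distance_matrix(self, taxa: Sequence[str]) -> np.ndarray:
        """Pairwise patristic distances for ``taxa`` (order preserved)."""
        if self._pdm_cache is None:
            labels = self.leaf_labels
            idx = {t: i for i, t in enumerate(labels)}
            pdm = self.tree.phylogenetic_distance_matrix()
            mat = np.zeros((len(labels), len(labels)))
            for t1 in self.tree.taxon_namespace:
                for t2 in self.tree.taxon_namespace:
                    if t1.label in idx and t2.label in idx:
                        mat[idx[t1.label], idx[t2.label]] = pdm.patristic_distance(t1, t2)
            self._pdm_cache = (labels, mat)
        labels, mat = self._pdm_cache
        idx = {t: i for i, t in enumerate(labels)}
        sel = [idx[t] for t in taxa]
        return mat[np.ix_(sel, sel)]

    def faith_pd(self, taxa: Iterable[str], include_root: bool = True) -> float:
        """Branch-length sum of the minimal subtree spanning ``taxa``.

        With ``include_root`` the path from the taxa's most recent common
        ancestor up to the root is counted as well (the classical rooted
        form); without it only edges below the MRCA contribute.
        """
        taxa = list(taxa)
        if not taxa:
            return 0.0
        visited: set = set()
        for t in taxa:
            nd = self._leaves[t]
            while nd is not None and nd not in visited:
                visited.add(nd)
                nd = nd.parent_node
        total = sum(nd.edge.length or 0.0 for nd in visited)
        if not include_root and len(taxa) >= 1:
            mrca = self.tree.mrca(taxon_labels=taxa)
            nd = mrca
            while nd is not None:
                total -= nd.edge.length or 0.0
                nd = nd.parent_node
        return total


ATTRIBUTE_COLUMNS = ("threatened", "non_native", "niche_width", "niche_class")
NICHE_CLASSES = ("specialist", "generalist", "intermediate", "unscored")


@dataclass
class SpeciesAttributes:
    """Per-taxon flags: Red-List threat, non-native origin, niche width."""

    table: pd.DataFrame  # index = taxon

    def __post_init__(self):
        df = self.table.copy()
        for col, default in (
            ("threatened", False),
            ("non_native", False),
            ("niche_width", np.nan),
            ("niche_class", "unscored"),
        ):
            if col not in df.columns:
                df[col] = default
        df["threatened"] = df["threatened"].fillna(False).astype(bool)
        df["non_native"] = df["non_native"].fillna(False).astype(bool)
        df["niche_width"] = df["niche_width"].astype(float)
        df["niche_class"] = df["niche_class"].fillna("unscored")
        bad = set(df["niche_class"]) - set(NICHE_CLASSES)
        if bad:
            raise DataError(f"unknown niche classes: {sorted(bad)}")
        w = df["niche_width"].dropna()
        if ((w < 0) | (w > 1)).any():
            raise DataError("niche_width values must lie in [0, 1]")
        if df.index.has_duplicates:
            raise DataError("species attribute table has duplicated taxa")
        self.table = df[list(ATTRIBUTE_COLUMNS)]

    def group(self, name: str) -> set[str]:
        """Taxon set for one of: threatened, non_native, specialist, generalist."""
        t = self.table
        if name in ("threatened", "non_native"):
            return set(t.index[t[name]])
        if name in ("specialist", "generalist"):
            return set(t.index[t["niche_class"] == name])
        raise KeyError(name)

    def niche_widths(self) -> Mapping[str, float]:
        return self.table["niche_width"].dropna().to_dict()


@dataclass
class Dataset:
    """A resurvey dataset: time series plus species-level side tables."""

    series: dict[str, TimeSeries]
    traits: TraitTable | None = None
    phylogeny: Phylogeny | None = None
    attributes: SpeciesAttributes | None = None

    def observations(self) -> Iterator[PlotObservation]:
        for sid in sorted(self.series):
            yield from self.series[sid].observations

    @property
    def n_series(self) -> int:
        return len(self.series)

    @property
    def n_observations(self) -> int:
        return sum(len(s.observations) for s in self.series.values())

    def taxa(self) -> set[str]:
        out: set[str] = set()
        for obs in self.observations():
            out.update(obs.taxa)
        return out

    def to_community_frame(self) -> pd.DataFrame:
        """Long-format community table, one row per record (canonical order)."""
        rows = []
        for sid in sorted(self.series):
            ts = self.series[sid]
            for obs in ts.observations:
                base = dict(
                    obs_id=obs.obs_id,
                    series_id=sid,
                    plot_id=obs.plot_id,
                    year=obs.year,
                    plot_size=obs.plot_size,
                    eunis_l1=obs.eunis_l1,
                    eunis_l3=obs.eunis_l3,
                    design=ts.design,
                    manipulated=obs.manipulated,
                )
                for rec in sorted(obs.records, key=lambda r: (r.taxon, str(r.layer))):
                    rows.append(dict(base, taxon=rec.taxon, layer=rec.layer, cover=rec.cover))
        cols = [
            "obs_id", "series_id", "plot_id", "year", "plot_size",
            "eunis_l1", "eunis_l3", "design", "manipulated",
            "taxon", "layer", "cover",
        ]
        return pd.DataFrame(rows, columns=cols)
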