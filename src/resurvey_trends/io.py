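"""Readers, writers and validation for resurvey datasets.

The on-disk community format is a delimited long table (CSV or TSV):
one row per observation x taxon x layer, with the observation-level
columns repeated.  Missing values are empty fields.  Traits and
attributes are CSVs with the taxon in the first column; the phylogeny
is newick with branch lengths.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datamodel import (
    DataError,
    Dataset,
    Phylogeny,
    PlotObservation,
    SpeciesAttributes,
    SpeciesRecord,
    TimeSeries,
    TraitTable,
)

log = logging.getLogger(__name__)

COMMUNITY_COLUMNS = [
    "obs_id", "series_id", "plot_id", "year", "plot_size",
    "eunis_l1", "eunis_l3", "design", "manipulated",
    "taxon", "layer", "cover",
]
_REQUIRED = ("obs_id", "series_id", "year", "taxon", "layer", "cover")


def _read_table(path) -> pd.DataFrame:
    # sep=None sniffs comma versus tab
    return pd.read_csv(path, sep=None, engine="python", dtype=str,
                       keep_default_na=False, na_values=[""])


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "yes", "t")
    return bool(x) and not (isinstance(x, float) and np.isnan(x))


def load_community(path) -> dict[str, TimeSeries]:
    """Parse the long community table into time series.

    Raises :class:`DataError` naming 1-based file line numbers for
    malformed rows, out-of-range covers and duplicated
    (obs_id, taxon, layer) triples.
    """
    df = _read_table(path)
    missing_cols = [c for c in _REQUIRED if c not in df.columns]
    if missing_cols:
        raise DataError(f"{path}: missing required columns {missing_cols}")
    lines = df.index + 2  # header is line 1

    year = pd.to_numeric(df["year"], errors="coerce")
    bad = lines[year.isna()].tolist()
    if bad:
        raise DataError(f"{path}: malformed year on line(s) {bad[:20]}")
    cover = pd.to_numeric(df["cover"], errors="coerce")
    bad = lines[cover.isna() & df["cover"].notna()].tolist()
    if bad:
        raise DataError(f"{path}: malformed cover on line(s) {bad[:20]}")
    out_of_range = cover.notna() & ((cover < 0) | (cover > 100))
    bad = lines[out_of_range].tolist()
    if bad:
        raise DataError(f"{path}: cover outside [0, 100] on line(s) {bad[:20]}")
    dup = df.duplicated(subset=["obs_id", "taxon", "layer"], keep=False)
    if dup.any():
        raise DataError(
            f"{path}: duplicate (obs_id, taxon, layer) on line(s) {lines[dup].tolist()[:20]}"
        )
    if "plot_size" in df.columns:
        psize = pd.to_numeric(df["plot_size"], errors="coerce")
        bad = lines[psize.isna() & df["plot_size"].notna()].tolist()
        if bad:
            raise DataError(f"{path}: malformed plot_size on line(s) {bad[:20]}")
    else:
        psize = pd.Series(np.nan, index=df.index)

    df = df.assign(_year=year.astype(int), _cover=cover, _psize=psize)

    series: dict[str, TimeSeries] = {}
    for sid, sdf in df.groupby("series_id", sort=True):
        designs = set()
        obs_list = []
        for oid, odf in sdf.groupby("obs_id", sort=True):
            first = odf.iloc[0]
            records = [
                SpeciesRecord(taxon=r["taxon"], layer=str(r["layer"]),
                              cover=None if pd.isna(r["_cover"]) else float(r["_cover"]))
                for _, r in odf.iterrows()
            ]
            obs_list.append(PlotObservation(
                obs_id=str(oid),
                series_id=str(sid),
                year=int(first["_year"]),
                records=records,
                plot_size=None if pd.isna(first["_psize"]) else float(first["_psize"]),
                eunis_l1=first.get("eunis_l1") if pd.notna(first.get("eunis_l1")) else None,
                eunis_l3=first.get("eunis_l3") if pd.notna(first.get("eunis_l3")) else None,
                manipulated=_parse_bool(first.get("manipulated", False)),
                plot_id=(str(first["plot_id"])
                         if "plot_id" in odf.columns and pd.notna(first.get("plot_id"))
                         else None),
            ))
            d = first.get("design")
            if pd.notna(d) and d:
                designs.add(str(d))
        design = designs.pop() if len(designs) == 1 else "permanent"
        series[str(sid)] = TimeSeries(series_id=str(sid), observations=obs_list,
                                      design=design)
    return series


def load_traits(path) -> TraitTable:
    df = pd.read_csv(path, index_col=0)
    return TraitTable(values=df, standardized=False)


def load_attributes(path) -> SpeciesAttributes:
    df = pd.read_csv(path, index_col=0)
    for col in ("threatened", "non_native"):
        if col in df.columns:
            df[col] = df[col].map(_parse_bool)
    return SpeciesAttributes(table=df)


def load_dataset(community_path, traits_path=None, tree_path=None,
                 attributes_path=None) -> Dataset:
    """Load and validate a full dataset from delimited files + newick.

    Taxa present in the community but absent from the side tables are
    retained with missing annotations; a load report (series,
    observation and taxon counts) is logged.
    """
    series = load_community(community_path)
    traits = load_traits(traits_path) if traits_path else None
    phylo = Phylogeny.from_newick(str(tree_path)) if tree_path else None
    attrs = load_attributes(attributes_path) if attributes_path else None
    ds = Dataset(series=series, traits=traits, phylogeny=phylo, attributes=attrs)
    log.info(
        "loaded dataset: %d series, %d observations, %d taxa",
        ds.n_series, ds.n_observations, len(ds.taxa()),
    )
    return ds


# ----------------------------------------------------------------------
# writing

def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.10g}")
    return out


def write_results(tables: Mapping[str, pd.DataFrame], out_dir, *,
                  config: Mapping | None = None, seed: int | None = None) -> dict[str, Path]:
    """Write result tables as CSV plus a machine-readable run manifest.

    Missing values become empty fields; floats are rendered with ``%.10g``
    so re-running with the same config and seed reproduces the files
    byte-for-byte.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.csv"
        _format_frame(df).to_csv(p, index=False, na_rep="")
        paths[name] = p
    manifest = {
        "config": dict(config) if config else {},
        "seed": seed,
        "versions": {
            "resurvey_trends": _package_version(),
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "tables": sorted(tables),
    }
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    paths["manifest"] = mpath
    return paths


def _package_version() -> str:
    from . import __version__
    return __version__


def write_dataset(dataset: Dataset, out_dir) -> dict[str, Path]:
    """Write a dataset's community/traits/tree/attributes files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = write_results({"community": dataset.to_community_frame()}, out_dir)
    if dataset.traits is not None:
        p = out_dir / "traits.csv"
        _format_frame(dataset.traits.values.rename_axis("taxon").reset_index()).to_csv(
            p, index=False, na_rep="")
        paths["traits"] = p
    if dataset.phylogeny is not None:
        p = out_dir / "phylogeny.nwk"
        p.write_text(dataset.phylogeny.to_newick() + "\n")
        paths["phylogeny"] = p
    if dataset.attributes is not None:
        p = out_dir / "attributes.csv"
        _format_frame(dataset.attributes.table.rename_axis("taxon").reset_index()).to_csv(
            p, index=False, na_rep="")
        paths["attributes"] = p
    return paths


# ----------------------------------------------------------------------
# validation

@dataclass
class ValidationCheck:
    name: str
    passed: bool
    n_failures: int
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[ValidationCheck] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return all(c.passed for c in self.checks)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.checks])


def validate_dataset(dataset: Dataset) -> ValidationReport:
    """Report-only consistency checks; never mutates the dataset."""
    rep = ValidationReport()

    n_bad = sum(
        1 for s in dataset.series.values()
        if any(a.year > b.year for a, b in zip(s.observations, s.observations[1:]))
    )
    rep.checks.append(ValidationCheck("year_ordering", n_bad == 0, n_bad))

    n_bad = sum(
        1 for obs in dataset.observations() for r in obs.records
        if r.has_cover and not (0 <= r.cover <= 100)
    )
    rep.checks.append(ValidationCheck("cover_range", n_bad == 0, n_bad))

    known: set[str] = set()
    if dataset.traits is not None:
        known |= set(dataset.traits.taxa)
    if dataset.phylogeny is not None:
        known |= set(dataset.phylogeny.leaf_labels)
    if dataset.attributes is not None:
        known |= set(dataset.attributes.table.index)
    orphans = dataset.taxa() - known if known else set()
    rep.checks.append(ValidationCheck(
        "orphan_taxa", len(orphans) == 0, len(orphans),
        ", ".join(sorted(orphans)[:10])))

    n_bad = 0
    for obs in dataset.observations():
        if obs.eunis_l3 and obs.eunis_l1:
            if not obs.eunis_l3.startswith(obs.eunis_l1):
                n_bad += 1
    rep.checks.append(ValidationCheck("eunis_prefix_consistency", n_bad == 0, n_bad))
    return rep
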