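"""Community-level diversity indices per plot observation.

One row of the output table holds, for one plot observation:

* taxonomic indices — total vegetation cover, species richness S,
  Shannon diversity H = -sum p_i ln p_i and Pielou evenness H/ln S;
* functional indices — FRic (convex-hull volume in a pool-wide
  principal-axis trait space), FEve (regularity of abundance along the
  trait-space minimum spanning tree) and FDiv (abundance-weighted
  divergence from the trait centre of gravity);
* phylogenetic indices — Faith PD (branch-length sum of the pruned
  subtree), mean pairwise distance and mean nearest-taxon distance;
* species-group indices — richness and overlap-combined cover of
  threatened, non-native, specialist and generalist species;
* the community-weighted mean (CWM) niche width.

Completeness gates follow the source data conventions: functional
indices require species with trait data to make up at least 80% of the
total vegetation cover, phylogenetic indices require *every* co-occurring
taxon on the tree, and the CWM niche width requires width-scored
species to reach 80% of total cover.  Gated cells are missing, with
the reason recorded in a parallel table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .datamodel import DataError, Dataset, Phylogeny, PlotObservation, TraitTable
from .preprocess import combined_cover, layer_combined_covers

log = logging.getLogger(__name__)

__all__ = [
    "CommunityView",
    "community_view",
    "taxonomic_indices",
    "trait_space",
    "functional_indices",
    "phylogenetic_indices",
    "group_indices",
    "cwm_niche_width",
    "compute_diversity",
    "INDEX_COLUMNS",
    "COUNT_INDICES",
]

GROUPS = ("threatened", "nonnative", "specialist", "generalist")
COUNT_INDICES = tuple(f"n_{g}" for g in GROUPS)
INDEX_COLUMNS = (
    "total_cover", "richness", "shannon", "evenness",
    "fric", "feve", "fdiv",
    "faith_pd", "mpd", "mntd",
    "n_threatened", "cover_threatened",
    "n_nonnative", "cover_nonnative",
    "n_specialist", "cover_specialist",
    "n_generalist", "cover_generalist",
    "cwm_niche_width",
)


@dataclass
class CommunityView:
    """Layer-combined community of one plot observation."""

    taxa: list[str]
    covers: np.ndarray  # percent, layer-combined, aligned with taxa

    def __post_init__(self):
        self.covers = np.asarray(self.covers, dtype=float)
        if len(self.taxa) != len(self.covers):
            raise DataError("taxa/covers length mismatch")

    @property
    def richness(self) -> int:
        return len(self.taxa)

    @property
    def total_cover(self) -> float:
        return combined_cover(self.covers)

    @property
    def abundances(self) -> np.ndarray:
        """Relative covers p_i, summing to 1."""
        s = self.covers.sum()
        if s <= 0:
            raise DataError("community has zero total cover")
        return self.covers / s


def community_view(obs: PlotObservation) -> CommunityView:
    cov = layer_combined_covers(obs)
    return CommunityView(taxa=list(cov), covers=np.array(list(cov.values())))


# ----------------------------------------------------------------------
# taxonomic

def taxonomic_indices(view: CommunityView) -> dict[str, float]:
    """Richness, Shannon H, Pielou evenness (missing at S=1), total cover."""
    out = {"richness": float(view.richness), "total_cover": view.total_cover,
           "shannon": np.nan, "evenness": np.nan}
    if view.richness >= 1:
        p = view.abundances
        p = p[p > 0]
        h = float(-(p * np.log(p)).sum())
        out["shannon"] = h
        if view.richness > 1:
            out["evenness"] = h / np.log(view.richness)
    return out


# ----------------------------------------------------------------------
# functional

def trait_space(traits: TraitTable, m_axes: int = 4) -> pd.DataFrame:
    """Pool-wide principal-axis projection of the standardized traits.

    Computed once over all taxa with complete trait vectors and shared
    across observations so that hull volumes are comparable.  Axes are
    principal components of the standardized matrix (SVD, deterministic
    sign convention: largest-magnitude loading positive).
    """
    if not traits.standardized:
        raise DataError("trait_space expects a standardized TraitTable")
    X = traits.values.dropna()
    if X.shape[0] <= m_axes:
        raise DataError("fewer complete-trait taxa than requested axes")
    m_axes = min(m_axes, X.shape[1])
    centred = X.values - X.values.mean(axis=0)
    u, s, vt = np.linalg.svd(centred, full_matrices=False)
    coords = u[:, :m_axes] * s[:m_axes]
    for j in range(coords.shape[1]):  # sign convention for determinism
        k = np.argmax(np.abs(vt[j]))
        if vt[j, k] < 0:
            coords[:, j] = -coords[:, j]
    return pd.DataFrame(coords, index=X.index,
                        columns=[f"axis{j + 1}" for j in range(m_axes)])


def _fric(points: np.ndarray) -> tuple[float, ConvexHull | None, str]:
    m = points.shape[1]
    if points.shape[0] <= m:
        return np.nan, None, "too_few_species_for_hull"
    try:
        hull = ConvexHull(points)
    except QhullError:
        return np.nan, None, "degenerate_hull"
    return float(hull.volume), hull, ""


def _feve(points: np.ndarray, w: np.ndarray) -> float:
    """Villeger functional evenness over the trait-space MST."""
    s = len(w)
    if s < 3:
        return np.nan
    d = squareform(pdist(points))
    mst = minimum_spanning_tree(d).tocoo()
    ew = np.array([d[i, j] / (w[i] + w[j]) for i, j in zip(mst.row, mst.col)])
    if ew.sum() == 0:
        return np.nan
    pew = ew / ew.sum()
    thr = 1.0 / (s - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def _fdiv(points: np.ndarray, w: np.ndarray, hull: ConvexHull) -> float:
    g = points[hull.vertices].mean(axis=0)
    d = np.linalg.norm(points - g, axis=1)
    d_mean = d.mean()
    delta_d = float((w * (d - d_mean)).sum())
    delta_abs = float((w * np.abs(d - d_mean)).sum())
    denom = delta_abs + d_mean
    if denom == 0:
        return np.nan
    return (delta_d + d_mean) / denom


def functional_indices(view: CommunityView, axes: pd.DataFrame,
                       coverage_threshold: float = 0.80
                       ) -> tuple[dict[str, float], dict[str, str]]:
    """FRic, FEve and FDiv in the shared trait space, with coverage gate.

    Gate first: if the overlap-combined cover of species with trait
    coordinates falls below ``coverage_threshold`` of the total
    vegetation cover, all three indices are missing.  Abundances are
    relative covers renormalized over the trait-covered species.
    """
    vals = {"fric": np.nan, "feve": np.nan, "fdiv": np.nan}
    reasons: dict[str, str] = {}
    have = [i for i, t in enumerate(view.taxa) if t in axes.index]
    total = view.total_cover
    if total <= 0:
        reasons = {k: "zero_total_cover" for k in vals}
        return vals, reasons
    covered = combined_cover(view.covers[have]) if have else 0.0
    if covered < coverage_threshold * total:
        reasons = {k: "trait_coverage_below_threshold" for k in vals}
        return vals, reasons
    taxa = [view.taxa[i] for i in have]
    pts = axes.loc[taxa].values
    w = view.covers[have]
    w = w / w.sum()

    fric, hull, why = _fric(pts)
    vals["fric"] = fric
    if why:
        reasons["fric"] = why

    feve = _feve(pts, w)
    vals["feve"] = feve
    if np.isnan(feve):
        reasons["feve"] = "fewer_than_three_species"

    if hull is not None:
        vals["fdiv"] = _fdiv(pts, w, hull)
    else:
        reasons["fdiv"] = why or "degenerate_hull"
    return vals, reasons


# ----------------------------------------------------------------------
# phylogenetic

def phylogenetic_indices(view: CommunityView, phylogeny: Phylogeny,
                         abundance_weighted: bool = False,
                         include_root: bool = True
                         ) -> tuple[dict[str, float], dict[str, str]]:
    """Faith PD, MPD and MNTD for one community.

    All three are missing unless every co-occurring taxon is on the
    tree.  Unweighted MPD averages patristic distances over unordered
    pairs and MNTD averages each taxon's distance to its nearest
    relative; the abundance-weighted variants weight by relative
    covers p_i.  MPD/MNTD are missing at S = 1.
    """
    vals = {"faith_pd": np.nan, "mpd": np.nan, "mntd": np.nan}
    reasons: dict[str, str] = {}
    if not view.taxa:
        return vals, {k: "empty_community" for k in vals}
    if not phylogeny.covers(view.taxa):
        return vals, {k: "taxon_missing_from_tree" for k in vals}
    vals["faith_pd"] = phylogeny.faith_pd(view.taxa, include_root=include_root)
    if view.richness < 2:
        reasons["mpd"] = reasons["mntd"] = "single_species"
        return vals, reasons
    d = phylogeny.distance_matrix(view.taxa)
    iu = np.triu_indices(view.richness, k=1)
    nearest = np.min(d + np.diag(np.full(view.richness, np.inf)), axis=1)
    if abundance_weighted:
        p = view.abundances
        wmat = np.outer(p, p)
        vals["mpd"] = float((wmat[iu] * d[iu]).sum() / wmat[iu].sum())
        vals["mntd"] = float((p * nearest).sum() / p.sum())
    else:
        vals["mpd"] = float(d[iu].mean())
        vals["mntd"] = float(nearest.mean())
    return vals, reasons


# ----------------------------------------------------------------------
# species groups and CWM niche width

def group_indices(view: CommunityView, groups: Mapping[str, set]
                  ) -> dict[str, float]:
    """Richness and overlap-combined cover per species group."""
    out = {}
    for name, members in groups.items():
        idx = [i for i, t in enumerate(view.taxa) if t in members]
        out[f"n_{name}"] = float(len(idx))
        out[f"cover_{name}"] = combined_cover(view.covers[idx]) if idx else 0.0
    return out


def cwm_niche_width(view: CommunityView, widths: Mapping[str, float],
                    coverage_threshold: float = 0.80) -> tuple[float, str]:
    """Cover-weighted mean niche width, gated on scored-species coverage."""
    idx = [i for i, t in enumerate(view.taxa) if t in widths]
    total = view.total_cover
    if total <= 0:
        return np.nan, "zero_total_cover"
    if not idx or combined_cover(view.covers[idx]) < coverage_threshold * total:
        return np.nan, "niche_coverage_below_threshold"
    c = view.covers[idx]
    w = np.array([widths[view.taxa[i]] for i in idx])
    return float((c * w).sum() / c.sum()), ""


# ----------------------------------------------------------------------
# table assembly

def compute_diversity(dataset: Dataset, m_axes: int = 4,
                      coverage_threshold: float = 0.80,
                      abundance_weighted_phylo: bool = False,
                      include_root: bool = True,
                      indices: Sequence[str] | None = None
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the full diversity table (and a missing-reason table).

    ``indices`` restricts computation to index families — any subset of
    ``{"taxonomic", "functional", "phylogenetic", "groups", "cwm"}`` —
    which keeps large simulation studies that only need e.g. richness
    cheap.  Rows are plot observations (index ``obs_id``), with
    ``series_id`` and ``year`` carried along for the trend stage.
    """
    fams = set(indices) if indices is not None else {
        "taxonomic", "functional", "phylogenetic", "groups", "cwm"}

    axes = None
    if "functional" in fams:
        if dataset.traits is None or not dataset.traits.standardized:
            raise DataError("functional indices need standardized traits "
                            "(run prepare_traits first)")
        axes = trait_space(dataset.traits, m_axes=m_axes)
    if "phylogenetic" in fams and dataset.phylogeny is None:
        raise DataError("phylogenetic indices need a phylogeny")
    groups = widths = None
    if "groups" in fams or "cwm" in fams:
        if dataset.attributes is None:
            raise DataError("group indices need species attributes")
        groups = {"threatened": dataset.attributes.group("threatened"),
                  "nonnative": dataset.attributes.group("non_native"),
                  "specialist": dataset.attributes.group("specialist"),
                  "generalist": dataset.attributes.group("generalist")}
        widths = dataset.attributes.niche_widths()

    rows, reason_rows = [], []
    for sid in sorted(dataset.series):
        ts = dataset.series[sid]
        for obs in ts.observations:
            view = community_view(obs)
            row: dict = {"obs_id": obs.obs_id, "series_id": sid, "year": obs.year}
            reasons: dict = {"obs_id": obs.obs_id}
            if view.richness == 0:
                row.update({"richness": 0.0, "total_cover": 0.0})
                reasons["all"] = "empty_observation"
            else:
                if "taxonomic" in fams:
                    row.update(taxonomic_indices(view))
                if "functional" in fams:
                    vals, why = functional_indices(view, axes, coverage_threshold)
                    row.update(vals)
                    reasons.update(why)
                if "phylogenetic" in fams:
                    vals, why = phylogenetic_indices(
                        view, dataset.phylogeny,
                        abundance_weighted=abundance_weighted_phylo,
                        include_root=include_root)
                    row.update(vals)
                    reasons.update(why)
                if "groups" in fams:
                    row.update(group_indices(view, groups))
                if "cwm" in fams:
                    val, why = cwm_niche_width(view, widths, coverage_threshold)
                    row["cwm_niche_width"] = val
                    if why:
                        reasons["cwm_niche_width"] = why
            rows.append(row)
            reason_rows.append(reasons)
    table = pd.DataFrame(rows).set_index("obs_id")
    reason_table = pd.DataFrame(reason_rows).set_index("obs_id")
    return table, reason_table
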