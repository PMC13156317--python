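"""Co-occurrence niche widths via multiple-site Simpson dissimilarity.

A habitat generalist co-occurs, across the plots it inhabits, with a
wider array of species than a specialist restricted to one community
type.  Following the co-occurrence approach, a species' *niche width*
is the mean multiple-site Simpson dissimilarity among random subsets of
the plots in which it occurs.  The Simpson (turnover) component is used
because it is independent of species richness and nestedness: plots
holding fewer but the same species count as compositionally similar.
"""

from __future__ import annotations

import itertools
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import DataError, Dataset

log = logging.getLogger(__name__)

__all__ = [
    "multiple_simpson",
    "estimate_niche_widths",
    "classify_niche_categories",
]


def multiple_simpson(communities: Sequence[set]) -> float:
    """Multiple-site Simpson dissimilarity of >= 2 species sets.

    ``sum_{i<j} min(b_ij, b_ji) / ((sum_i S_i - S_T) + sum_{i<j} min(b_ij, b_ji))``
    where ``S_i`` is site richness, ``S_T`` pooled richness and
    ``b_ij = |site_i \\ site_j|``.  Returns 0 when every pairwise
    minimum-turnover term is 0 (identical or fully nested sites); with
    exactly two sites this reduces to pairwise Simpson dissimilarity
    ``min(b, c) / (a + min(b, c))``.
    """
    sets = [frozenset(c) for c in communities]
    if len(sets) < 2:
        raise DataError("multiple_simpson needs at least two communities")
    if any(len(s) == 0 for s in sets):
        raise DataError("multiple_simpson got an empty community")
    min_turnover = 0
    for a, b in itertools.combinations(sets, 2):
        shared = len(a & b)
        min_turnover += min(len(a) - shared, len(b) - shared)
    if min_turnover == 0:
        return 0.0
    pooled = len(frozenset().union(*sets))
    nestedness_term = sum(len(s) for s in sets) - pooled
    return min_turnover / (nestedness_term + min_turnover)


def estimate_niche_widths(dataset: Dataset, n_plots: int = 20, n_reps: int = 100,
                          min_occ: int = 50, seed: int | None = None,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Monte-Carlo niche widths for all sufficiently frequent species.

    For every species with at least ``min_occ`` plot occurrences spread
    over at least ``n_plots`` distinct time series, ``n_reps``
    replicates each draw ``n_plots`` of its occurrence observations —
    at most one per time series, without replacement — and compute the
    multiple-site Simpson dissimilarity over the full species lists of
    those observations.  The niche width is the replicate mean.

    Species failing either threshold get a missing width and a recorded
    reason; this missingness is part of the contract, not an error.

    Returns a DataFrame indexed by taxon with columns
    ``n_occurrences, n_series, niche_width, n_reps, niche_class, reason``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)

    communities: dict[str, frozenset] = {}
    occ: dict[str, dict[str, list[str]]] = {}  # taxon -> series -> [obs_id]
    for obs in dataset.observations():
        taxa = frozenset(obs.taxa)
        if not taxa:
            continue
        communities[obs.obs_id] = taxa
        for t in taxa:
            occ.setdefault(t, {}).setdefault(obs.series_id, []).append(obs.obs_id)

    rows = []
    for taxon in sorted(occ):
        by_series = occ[taxon]
        n_occurrences = sum(len(v) for v in by_series.values())
        n_series = len(by_series)
        width, reason, reps_used = np.nan, "", 0
        if n_occurrences < min_occ:
            reason = "below_min_occurrences"
        elif n_series < n_plots:
            reason = "too_few_distinct_series"
            log.info("taxon %s: %d occurrences but only %d series; skipped",
                     taxon, n_occurrences, n_series)
        else:
            series_ids = sorted(by_series)
            vals = np.empty(n_reps)
            for r in range(n_reps):
                chosen = rng.choice(len(series_ids), size=n_plots, replace=False)
                sets = []
                for i in chosen:
                    obs_ids = by_series[series_ids[i]]
                    oid = obs_ids[rng.integers(len(obs_ids))] if len(obs_ids) > 1 else obs_ids[0]
                    sets.append(communities[oid])
                vals[r] = multiple_simpson(sets)
            width = float(vals.mean())
            reps_used = n_reps
        rows.append(dict(taxon=taxon, n_occurrences=n_occurrences, n_series=n_series,
                         niche_width=width, n_reps=reps_used,
                         niche_class="unscored", reason=reason))
    table = pd.DataFrame(rows).set_index("taxon")
    return classify_niche_categories(table)


def classify_niche_categories(table: pd.DataFrame, lower_q: float = 0.10,
                              upper_q: float = 0.10) -> pd.DataFrame:
    """Label the bottom/top deciles of scored widths as specialists/generalists.

    The classification depends only on width ranks (monotone relabelling
    of widths leaves it unchanged); ties are broken by taxon name so the
    result is deterministic, and the specialist and generalist sets are
    always disjoint.  Unscored species keep the ``unscored`` label.
    """
    table = table.copy()
    scored = table.index[table["niche_width"].notna()]
    table.loc[:, "niche_class"] = "unscored"
    n = len(scored)
    if n == 0:
        return table
    order = sorted(scored, key=lambda t: (table.at[t, "niche_width"], t))
    k_lo = int(n * lower_q)
    k_hi = int(n * upper_q)
    k_hi = min(k_hi, n - k_lo)  # never overlap the specialist set
    table.loc[order, "niche_class"] = "intermediate"
    if k_lo:
        table.loc[order[:k_lo], "niche_class"] = "specialist"
    if k_hi:
        table.loc[order[n - k_hi:], "niche_class"] = "generalist"
    return table
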