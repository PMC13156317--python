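"""Decadal gamma-diversity trends with sample-size-matched decade pairing.

Gamma diversity here is the pooled count of unique taxa across a group
of plots (typically one level-1 habitat x trajectory group).  Naive
decade-by-decade counts would be biased by shifting numbers of plots,
so every ordered pair of calendar decades (d1 < d2) is evaluated on the
*same* plots: only plots observed in both decades enter, keeping the
first observation in the earlier and the last in the later decade.
The trend of a pair is the gamma difference divided by the temporal
distance in decades.  Across a group's decade pairs, a two-sided
one-sample t-test probes the mean trend and an exact binomial sign
test the balance of positive versus negative trends (zero trends are
excluded from the sign test).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .datamodel import TimeSeries

log = logging.getLogger(__name__)

__all__ = ["DecadalTrend", "decadal_gamma_trends", "GammaTestResult",
           "test_gamma_trends", "gamma_difference"]


@dataclass(frozen=True)
class DecadalTrend:
    decade_1: int          # decade start years, e.g. 1920
    decade_2: int
    n_plots: int
    gamma_1: int
    gamma_2: int

    @property
    def trend(self) -> float:
        """Taxa gained per decade between the paired decades."""
        return gamma_difference(self.gamma_1, self.gamma_2,
                                (self.decade_2 - self.decade_1) / 10.0)


def gamma_difference(gamma_1: float, gamma_2: float, distance_decades: float) -> float:
    """(gamma_2 - gamma_1) / distance; antisymmetric under order swap."""
    return (gamma_2 - gamma_1) / distance_decades


def _decade(year: int) -> int:
    return (year // 10) * 10


def decadal_gamma_trends(series_group: Iterable[TimeSeries]) -> list[DecadalTrend]:
    """All decade-pair gamma trends for one group of time series.

    Plots are matched by their ``plot_id`` (series id for N-to-N
    designs).  For each ordered decade pair the qualifying plots are
    those with at least one observation in both decades; within a plot
    the first observation of the earlier and the last observation of
    the later decade contribute their taxa.  Pairs with no qualifying
    plot are skipped.
    """
    # plot -> decade -> list of (year, obs_order, taxa), observation order
    # breaks ties among same-year observations deterministically
    per_plot: dict[str, dict[int, list[tuple[int, int, frozenset]]]] = {}
    for ts in series_group:
        for k, obs in enumerate(ts.observations):
            d = _decade(obs.year)
            per_plot.setdefault(obs.plot_id, {}).setdefault(d, []).append(
                (obs.year, k, frozenset(obs.taxa)))

    decades = sorted({d for by_dec in per_plot.values() for d in by_dec})
    out: list[DecadalTrend] = []
    for i, d1 in enumerate(decades):
        for d2 in decades[i + 1:]:
            taxa_1: set = set()
            taxa_2: set = set()
            n_plots = 0
            for by_dec in per_plot.values():
                if d1 in by_dec and d2 in by_dec:
                    n_plots += 1
                    taxa_1 |= min(by_dec[d1])[2]   # first obs in earlier decade
                    taxa_2 |= max(by_dec[d2])[2]   # last obs in later decade
            if n_plots == 0:
                continue
            out.append(DecadalTrend(decade_1=d1, decade_2=d2, n_plots=n_plots,
                                    gamma_1=len(taxa_1), gamma_2=len(taxa_2)))
    return out


@dataclass
class GammaTestResult:
    mean_trend: float
    n_trends: int
    t_p: float          # two-sided one-sample t-test vs 0 (NaN if skipped)
    n_positive: int
    n_negative: int
    binomial_p: float   # exact two-sided sign test (NaN if skipped)
    note: str = ""


def test_gamma_trends(trends: Sequence[DecadalTrend | float]) -> GammaTestResult:
    """t-test and sign test of a group's decadal gamma trends.

    Degenerate cases follow fixed conventions: a single trend skips the
    t-test; identical nonzero trends (zero variance) are reported as
    p < 1e-12; all-zero trends skip both tests.
    """
    vals = np.array([t.trend if isinstance(t, DecadalTrend) else float(t)
                     for t in trends], dtype=float)
    n = len(vals)
    mean = float(vals.mean()) if n else np.nan
    note = ""

    t_p = np.nan
    if n >= 2:
        if np.allclose(vals.std(), 0.0):
            if mean == 0.0:
                note = "all_trends_zero"
            else:
                t_p = 1e-13  # zero-variance nonzero mean: report p < 1e-12
                note = "zero_variance_t"
        else:
            t_p = float(stats.ttest_1samp(vals, 0.0).pvalue)
    elif n == 1:
        note = "single_trend_t_skipped"

    n_pos = int((vals > 0).sum())
    n_neg = int((vals < 0).sum())
    if n_pos + n_neg > 0:
        binom_p = float(stats.binomtest(n_pos, n_pos + n_neg, 0.5).pvalue)
    else:
        binom_p = np.nan
        note = (note + ";" if note else "") + "binomial_skipped_no_nonzero_trends"
    return GammaTestResult(mean_trend=mean, n_trends=n, t_p=t_p,
                           n_positive=n_pos, n_negative=n_neg,
                           binomial_p=binom_p, note=note)


test_gamma_trends.__test__ = False  # not a pytest case despite the name
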