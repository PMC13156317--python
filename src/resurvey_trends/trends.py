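"""Per-series diversity trends.

For every time series and diversity index, an ordinary least squares
regression of the (log) index value on calendar year yields

* the annual percentage change ``(e^slope_log - 1) * 100`` from the
  log-scale fit, and
* the absolute annual change ``slope_raw`` from the raw-scale fit.

A constant 0.5 is added before the log for the four *count* indices
(numbers of threatened, non-native, specialist and generalist species)
so that zero counts remain usable; any other index with a non-positive
value is excluded from the log fit, with the exclusion reason recorded.
With exactly two observations the slope is the difference quotient, so
the percentage change equals the relative change divided by the
timespan under the log formulation.  Each record carries the pooling
weight ln(n_obs).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import DataError, Dataset
from .diversity import COUNT_INDICES, INDEX_COLUMNS

log = logging.getLogger(__name__)

__all__ = ["fit_series_trend", "compute_all_trends", "count_offset", "pct_from_slope"]

LOG_OFFSET = 0.5


def count_offset(index: str) -> float:
    """0.5 for the four count indices, else 0."""
    return LOG_OFFSET if index in COUNT_INDICES else 0.0


def pct_from_slope(slope_log: float) -> float:
    """Annual percent change from a log-scale slope: (e^s - 1) * 100."""
    return float((np.exp(slope_log) - 1.0) * 100.0)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    return float((xc * y).sum() / (xc * xc).sum())


def fit_series_trend(points: Sequence[tuple[float, float]], scale: str = "log",
                     offset: float = 0.0) -> dict:
    """OLS trend of one series for one index.

    ``points`` are (year, value) pairs; missing values must already be
    dropped.  On the log scale, values are shifted by ``offset`` before
    the log; any non-positive shifted value excludes the fit with reason
    ``nonpositive_on_log_scale``.  Fewer than two points, or no spread
    in years, also exclude the fit.  Returns a dict with ``slope``
    (NaN when excluded), ``pct`` (log scale only), ``n_obs``, ``span``
    and ``reason``.
    """
    if scale not in ("log", "raw"):
        raise DataError(f"unknown scale {scale!r}")
    pts = [(float(x), float(v)) for x, v in points if not np.isnan(v)]
    out = {"slope": np.nan, "pct": np.nan, "n_obs": len(pts),
           "span": 0.0, "reason": ""}
    if len(pts) < 2:
        out["reason"] = "fewer_than_two_observations"
        return out
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    out["span"] = float(x.max() - x.min())
    if len(np.unique(x)) < 2:
        out["reason"] = "no_time_variation"
        return out
    if scale == "log":
        shifted = y + offset
        if np.any(shifted <= 0):
            out["reason"] = "nonpositive_on_log_scale"
            return out
        slope = _ols_slope(x, np.log(shifted))
        out["slope"] = slope
        out["pct"] = pct_from_slope(slope)
    else:
        out["slope"] = _ols_slope(x, y)
    return out


def compute_all_trends(diversity_table: pd.DataFrame,
                       dataset: Dataset | None = None,
                       indices: Sequence[str] | None = None) -> pd.DataFrame:
    """One trend record per (series, index) from a diversity table.

    ``diversity_table`` is the observation-level table from
    :func:`~resurvey_trends.diversity.compute_diversity` (must carry
    ``series_id`` and ``year``).  Observations missing an index value
    are dropped for that index only, so ``n_obs`` is per index.  When
    ``dataset`` is given, each record also carries the series' design,
    trajectory and habitat codes for the synthesis stage.

    Returns a long DataFrame with one row per series x index:
    ``series_id, index, n_obs, span, slope_log, pct_per_year,
    slope_raw, weight, reason`` (+ metadata columns).
    """
    if indices is None:
        indices = [c for c in INDEX_COLUMNS if c in diversity_table.columns]
    meta: dict[str, dict] = {}
    if dataset is not None:
        for sid, ts in dataset.series.items():
            meta[sid] = {
                "design": ts.design,
                "trajectory": ts.trajectory,
                "eunis_l1_initial": ts.first.eunis_l1,
                "eunis_l3_initial": ts.first.eunis_l3,
                "last_obs_year": ts.last.year,
                "plot_size_rel_change": _rel_plot_size_change(ts),
            }

    rows = []
    for sid, sdf in diversity_table.groupby("series_id", sort=True):
        for index in indices:
            if index not in sdf.columns:
                continue
            pts = list(zip(sdf["year"].astype(float), sdf[index].astype(float)))
            logfit = fit_series_trend(pts, scale="log", offset=count_offset(index))
            rawfit = fit_series_trend(pts, scale="raw")
            n_obs = max(logfit["n_obs"], rawfit["n_obs"])
            row = {
                "series_id": sid,
                "index": index,
                "n_obs": n_obs,
                "span": max(logfit["span"], rawfit["span"]),
                "slope_log": logfit["slope"],
                "pct_per_year": logfit["pct"],
                "slope_raw": rawfit["slope"],
                "weight": np.log(n_obs) if n_obs >= 2 else np.nan,
                "reason": logfit["reason"] or rawfit["reason"],
            }
            row.update(meta.get(sid, {}))
            rows.append(row)
    return pd.DataFrame(rows)


def _rel_plot_size_change(ts) -> float:
    first, last = ts.first.plot_size, ts.last.plot_size
    if first is None or last is None or first <= 0:
        return np.nan
    return (last - first) / first
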