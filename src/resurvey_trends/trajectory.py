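"""Habitat-change trajectory classification.

Each time series is classified from the EUNIS level-3 codes of its
first and last observation into one of five categories:

* ``stable`` — same (or map-declared similar) level-3 type throughout;
* ``succession`` — shift toward higher vegetation biomass/complexity;
* ``disturbance`` — the reverse shift;
* ``other`` — an undirected or incomparable shift (e.g. between
  habitat groups ranked on separate scales);
* ``unclassifiable`` — the first and/or last observation carries no
  level-3 code.

Explicit expert rules are read from a prefix-mapping table; where no
rule applies the classifier falls back to a level-1 complexity ranking
(sparse/man-made < grassland < shrubland/heathland < forest, with
waters, coastal habitats and mires each ranked on their own scale).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .datamodel import DataError, Dataset, TRAJECTORIES

__all__ = [
    "TrajectoryMap",
    "classify_trajectory",
    "assign_trajectories",
    "trajectory_shares",
    "share_report",
]

# level-1 letter -> (rank group, complexity rank); groups are mutually
# incomparable, shifts across groups fall back to "other"
DEFAULT_RANKS: dict[str, tuple[str, int]] = {
    "U": ("terrestrial", 0),   # inland sparsely vegetated
    "V": ("terrestrial", 0),   # vegetated man-made
    "R": ("terrestrial", 1),   # grasslands
    "S": ("terrestrial", 2),   # shrublands & heathlands
    "T": ("terrestrial", 3),   # forests
    "N": ("coastal", 0),
    "P": ("waters", 0),        # inland waters
    "MA": ("marine", 0),
    "Q": ("mires", 0),         # mires, bogs & fens
}


def eunis_l1(code: str) -> str:
    """Leading level-1 letters of an EUNIS code (``MA`` is two letters)."""
    code = code.strip()
    if not code or not code[0].isalpha():
        raise DataError(f"malformed EUNIS code: {code!r}")
    if code.upper().startswith("MA"):
        return "MA"
    return code[0].upper()


@dataclass
class TrajectoryMap:
    """Pluggable expert mapping plus the rank-based fallback.

    ``rules`` map (initial_prefix, final_prefix) pairs to a category;
    the most specific matching rule (longest combined prefix) wins.
    An expert table mirroring the real classification scheme can be
    loaded from CSV with columns (initial_prefix, final_prefix,
    category); the default map ships no rules, so everything resolves
    through the rank fallback.
    """

    rules: list[tuple[str, str, str]] = field(default_factory=list)
    ranks: Mapping[str, tuple[str, int]] = field(default_factory=lambda: dict(DEFAULT_RANKS))

    def __post_init__(self):
        for ip, fp, cat in self.rules:
            if cat not in TRAJECTORIES:
                raise DataError(f"unknown trajectory category {cat!r} in map rule")

    @classmethod
    def from_csv(cls, path) -> "TrajectoryMap":
        rules = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                rules.append((row["initial_prefix"].strip(),
                              row["final_prefix"].strip(),
                              row["category"].strip()))
        return cls(rules=rules)

    def lookup(self, initial: str, final: str) -> str | None:
        best, best_len = None, -1
        for ip, fp, cat in self.rules:
            if initial.startswith(ip) and final.startswith(fp):
                score = len(ip) + len(fp)
                if score > best_len:
                    best, best_len = cat, score
        return best


def classify_trajectory(initial_l3: str | None, final_l3: str | None,
                        tmap: TrajectoryMap | None = None) -> str:
    """Classify one series from its first and last level-3 codes."""
    tmap = tmap or TrajectoryMap()
    if not initial_l3 or not final_l3:
        return "unclassifiable"
    initial_l3, final_l3 = initial_l3.strip(), final_l3.strip()
    if initial_l3 == final_l3:
        return "stable"
    ruled = tmap.lookup(initial_l3, final_l3)
    if ruled is not None:
        return ruled
    g1, r1 = tmap.ranks.get(eunis_l1(initial_l3), ("?", 0))
    g2, r2 = tmap.ranks.get(eunis_l1(final_l3), ("??", 0))
    if g1 != g2:
        return "other"
    if r2 > r1:
        return "succession"
    if r2 < r1:
        return "disturbance"
    return "other"


def assign_trajectories(dataset: Dataset, tmap: TrajectoryMap | None = None) -> Dataset:
    """Fill ``TimeSeries.trajectory`` for every series (in place)."""
    tmap = tmap or TrajectoryMap()
    for ts in dataset.series.values():
        ts.trajectory = classify_trajectory(ts.first.eunis_l3, ts.last.eunis_l3, tmap)
    return dataset


def trajectory_shares(dataset: Dataset) -> dict[str, int]:
    """Count series per trajectory category (classifier must have run)."""
    counts = {c: 0 for c in TRAJECTORIES}
    for ts in dataset.series.values():
        cat = ts.trajectory or "unclassifiable"
        counts[cat] += 1
    return counts


def share_report(counts: Mapping[str, int], total: int | None = None,
                 decimals: int = 1) -> dict[str, float]:
    """Percentage shares of category counts, rounded for reporting.

    ``total`` defaults to the sum of the counts; pass it explicitly when
    the denominator includes material outside the tabulated categories.
    """
    if total is None:
        total = sum(counts.values())
    if total <= 0:
        raise DataError("share_report needs a positive total")
    return {k: round(100.0 * v / total, decimals) for k, v in counts.items()}
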