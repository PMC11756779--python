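"""Rank-score aggregation across generators and measure categories.

Each measure ranks the generators (1 = best under the declared orientation,
ties averaged).  Ranks are averaged per category and min-max normalized to
[0, 1], lower is better; the overall score applies the same procedure to
all measures pooled.  Run-level values are averaged into the matrix before
ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ArgumentError

CATEGORIES = ("resemblance", "utility", "privacy")
ORIENTATIONS = ("lower_better", "higher_better")


@dataclass(frozen=True)
class Measure:
    name: str
    category: str
    orientation: str

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ArgumentError(f"unknown category {self.category!r}")
        if self.orientation not in ORIENTATIONS:
            raise ArgumentError(f"unknown orientation {self.orientation!r}")


@dataclass
class MetricMatrix:
    generators: list[str]
    measures: list[Measure]
    values: pd.DataFrame  # generators x measure names, averaged over runs

    def __post_init__(self):
        expected = [m.name for m in self.measures]
        if list(self.values.columns) != expected or list(self.values.index) != self.generators:
            self.values = self.values.loc[self.generators, expected]
        if self.values.isna().any().any():
            raise ArgumentError("metric matrix has missing cells")


@dataclass
class RankReport:
    per_category: dict[str, pd.Series] = field(default_factory=dict)
    overall: pd.Series = field(default_factory=pd.Series)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"generator": g, "category": cat, "score": s}
            for cat, series in self.per_category.items()
            for g, s in series.items()
        ]
        rows += [{"generator": g, "category": "overall", "score": s} for g, s in self.overall.items()]
        return pd.DataFrame(rows)


def rank_measure(values, orientation: str) -> np.ndarray:
    """Ranks 1..G with 1 = best under the orientation; ties averaged."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ArgumentError("need at least 2 generators to rank")
    if orientation not in ORIENTATIONS:
        raise ArgumentError(f"unknown orientation {orientation!r}")
    return rankdata(v if orientation == "lower_better" else -v, method="average")


def _normalize(mean_ranks: pd.Series) -> pd.Series:
    lo, hi = mean_ranks.min(), mean_ranks.max()
    if hi - lo < 1e-12:
        return pd.Series(0.0, index=mean_ranks.index)  # degenerate: all tied
    return (mean_ranks - lo) / (hi - lo)


def aggregate_ranks(m: MetricMatrix) -> RankReport:
    """Mean rank per category per generator, min-max normalized to [0, 1];
    overall = same procedure across all measures."""
    ranks = pd.DataFrame(index=m.generators)
    for meas in m.measures:
        ranks[meas.name] = rank_measure(m.values[meas.name].to_numpy(), meas.orientation)
    if not m.measures:
        raise ArgumentError("metric matrix has no measures")
    report = RankReport()
    present = [cat for cat in CATEGORIES if any(meas.category == cat for meas in m.measures)]
    if not present:
        raise ArgumentError("no non-empty measure category")
    for cat in present:
        names = [meas.name for meas in m.measures if meas.category == cat]
        report.per_category[cat] = _normalize(ranks[names].mean(axis=1))
    report.overall = _normalize(ranks.mean(axis=1))
    return report
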