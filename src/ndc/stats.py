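"""Linear-association and contingency statistics.

Point-biserial correlation (the Pearson correlation of expression against the
0/1 label encoding) supplies the R and R² terms of the NDC score; the Welch
t-test is the linear-ranking comparator; the Yates-corrected chi-square test
backs the 2x2 contingency analyses (expression group vs. tumor grade or vital
status).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .mic import SampleSeries

__all__ = [
    "LinearAssoc",
    "ContingencyTable2x2",
    "ConstantGeneError",
    "point_biserial",
    "welch_t",
    "chi2_yates",
]


class ConstantGeneError(ValueError):
    """Raised when a correlation is requested for a constant expression vector."""


@dataclass(frozen=True)
class LinearAssoc:
    r: float
    r2: float
    abs_r: float


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts a, b / c, d (rows = groups, columns = outcomes)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(v) != v or v < 0 for v in cells):
            raise ValueError(f"cells must be non-negative integers, got {cells}")
        if sum(cells) < 1:
            raise ValueError("table total must be >= 1")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


def point_biserial(series: SampleSeries) -> LinearAssoc:
    """Point-biserial correlation of expression against the binary label.

    Identical to the Pearson product-moment correlation of x with the 0/1
    encoding of y (sample-SD convention; the n vs. n-1 choice cancels in r).
    """
    x, y = series.x, series.y.astype(float)
    if np.ptp(x) == 0.0:
        raise ConstantGeneError("correlation undefined for a constant gene")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    r = min(max(r, -1.0), 1.0)
    return LinearAssoc(r=r, r2=r * r, abs_r=abs(r))


def welch_t(series: SampleSeries, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test of class-0 vs. class-1 expression.

    Welch unequal-variance form with Welch–Satterthwaite df by default;
    ``equal_var=True`` selects the pooled-variance Student test.  The sign
    convention is mean(class 0) - mean(class 1).
    """
    x0 = series.x[series.y == 0]
    x1 = series.x[series.y == 1]
    if len(x0) < 2 or len(x1) < 2:
        raise ValueError(
            f"each class needs >= 2 samples, got {len(x0)} and {len(x1)}"
        )
    res = sps.ttest_ind(x0, x1, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def chi2_yates(table: ContingencyTable2x2) -> tuple[float, float]:
    """Pearson chi-square with Yates continuity correction on a 2x2 table.

    Statistic = sum over cells of (max(|O - E| - 0.5, 0))² / E; p-value from
    the upper tail of chi-square with 1 df.  All four marginals must be
    positive.
    """
    t = table.as_array()
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("all row and column marginals must be positive")
    stat, p, _, _ = sps.chi2_contingency(t, correction=True)
    return float(stat), float(p)
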