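"""Maximal information coefficient (MIC) for continuous expression vs. a binary phenotype.

With a binary label the MIC characteristic matrix collapses: the normalizer
``log2 min(k_x, k_y)`` equals ``log2 2 = 1`` for every admissible grid, and the
label axis admits only its natural two-level partition.  MIC therefore reduces
to the maximum, over partitions of the expression axis, of the mutual
information between bin membership and the label.  The exact maximum is found
by dynamic programming over cut positions in the expression-sorted order; a
brute-force enumeration of every cut subset serves as an independent oracle on
small inputs.

Grid budget follows the MINE convention ``B(n) = n**alpha`` with the strict
admissibility ``k_x * 2 < B(n)``, i.e. ``2 <= k_x <= ceil(B/2) - 1``.  For
8 <= n <= 10 this admits no grid at all, so the single-cut family ``k_x = 2``
is always allowed once ``n >= 8`` (documented deviation; see docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.special import xlogy
from scipy.stats import chi2 as _chi2_dist

__all__ = [
    "MIN_SAMPLES",
    "SampleSeries",
    "MICConfig",
    "MICResult",
    "max_grid_size",
    "mutual_information_binned",
    "mic_binary",
    "brute_force_mic",
]

MIN_SAMPLES = 8
_LN2 = math.log(2.0)


def _xlog2(a: np.ndarray) -> np.ndarray:
    """Elementwise ``a * log2(a)`` with the entropy convention 0*log 0 = 0."""
    return xlogy(a, a) / _LN2


@dataclass(frozen=True)
class SampleSeries:
    """One gene's expression values paired with binary class labels.

    Parameters
    ----------
    x : array-like of float, length n
        Expression values (arbitrary normalized units).  Must be finite.
    y : array-like of {0, 1}, length n
        Class labels; both classes must be present and n >= 8.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y)
        if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
            raise ValueError("x and y must be 1-D vectors of equal length")
        if len(x) < MIN_SAMPLES:
            raise ValueError(
                f"need at least {MIN_SAMPLES} samples, got {len(x)}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("x contains non-finite values (NaN or inf)")
        yi = y.astype(int)
        if np.any(yi != y) or not set(np.unique(yi)) <= {0, 1}:
            raise ValueError("y must contain only binary codes 0/1")
        if len(np.unique(yi)) < 2:
            raise ValueError("y must contain both classes at least once")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", yi)

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class MICConfig:
    """MIC estimation settings.

    alpha : grid-size exponent, B(n) = n**alpha (MINE convention, default 0.6).
    termination : ``"exhaustive"`` (exact DP maximum, default) or
        ``"chi_square"`` (greedy cut insertion with a chi-square local stopping
        rule in the spirit of ChiMIC; an approximation flag).
    chi_level : significance level of the stopping test, used only by
        ``chi_square`` termination.
    """

    alpha: float = 0.6
    termination: str = "exhaustive"
    chi_level: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.termination not in ("exhaustive", "chi_square"):
            raise ValueError(f"unknown termination mode {self.termination!r}")
        if not 0.0 < self.chi_level < 1.0:
            raise ValueError(f"chi_level must be in (0, 1), got {self.chi_level}")


@dataclass(frozen=True)
class MICResult:
    """MIC score with the optimizing expression-axis grid.

    ``cuts`` are positions in the x-sorted sample order: a cut at position c
    separates sorted samples [0, c) from [c, n).  Cuts never split tied values.
    """

    mic: float
    n_bins_x: int
    cuts: tuple[int, ...] = field(default_factory=tuple)


def max_grid_size(n: int, alpha: float = 0.6) -> float:
    """MINE grid budget B(n) = n**alpha; grids must satisfy k_x * k_y < B."""
    if n < MIN_SAMPLES:
        raise ValueError(f"need at least {MIN_SAMPLES} samples, got {n}")
    return float(n) ** alpha


def max_x_bins(n: int, alpha: float = 0.6) -> int:
    """Largest admissible number of x-bins for a binary y (k=2 floor, see module docs)."""
    b = max_grid_size(n, alpha)
    return max(math.ceil(b / 2) - 1, 2)


def mutual_information_binned(counts) -> float:
    """Mutual information (bits) of a 2 x k table of label counts per x-bin.

    Rows index the two label values, columns the k >= 2 bins.  Computed as
    I = H(Y) + H(bin) - H(Y, bin) with 0*log 0 = 0.
    """
    t = np.asarray(counts, dtype=float)
    if t.size == 0:
        raise ValueError("empty contingency table")
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError(f"expected a 2 x k (k >= 2) table, got shape {t.shape}")
    if np.any(t < 0):
        raise ValueError("counts must be non-negative")
    n = t.sum()
    if n < 1:
        raise ValueError("table total must be >= 1")
    i = (
        _xlog2(t).sum()
        - _xlog2(t.sum(axis=1)).sum()
        - _xlog2(t.sum(axis=0)).sum()
        + _xlog2(n)
    ) / n
    return float(max(i, 0.0))


def _sorted_blocks(x: np.ndarray, y: np.ndarray):
    """Boundary positions and cumulative class-1 counts of the tie blocks.

    Returns (bnd, cum1): ``bnd`` holds 0, every position between strictly
    different consecutive sorted x-values, and n; ``cum1[i]`` is the number of
    class-1 samples among the first ``bnd[i]`` sorted samples.
    """
    order = np.argsort(x, kind="stable")
    xs = x[order]
    ys = y[order]
    inner = np.flatnonzero(np.diff(xs) > 0) + 1
    bnd = np.concatenate(([0], inner, [len(x)]))
    csum = np.concatenate(([0], np.cumsum(ys)))
    return bnd, csum[bnd]


def _label_entropy(n1: int, n: int) -> float:
    n0 = n - n1
    return float((_xlog2(np.array(float(n))) - _xlog2(np.array(float(n1)))
                  - _xlog2(np.array(float(n0)))) / n)


def _bin_weights(bnd: np.ndarray, cum1: np.ndarray) -> np.ndarray:
    """F[i, j] = n * (negative conditional-entropy contribution) of bin (i, j].

    The mutual information of a partition with boundaries i0=0 < i1 < ... < ik=m
    is H(Y) + sum_b F[i_{b-1}, i_b] / n.  Entries with j <= i are -inf.
    """
    nb = bnd[None, :] - bnd[:, None]
    c1 = cum1[None, :] - cum1[:, None]
    valid = nb > 0
    nb_f = np.where(valid, nb, 1).astype(float)
    c1_f = np.where(valid, c1, 0).astype(float)
    c0_f = nb_f - c1_f
    f = _xlog2(c1_f) + _xlog2(c0_f) - _xlog2(nb_f)
    return np.where(valid, f, -np.inf)


def mic_binary(series: SampleSeries, config: MICConfig | None = None) -> MICResult:
    """Exact MIC of expression against a binary label.

    Maximizes the binned mutual information over all partitions of the
    x-sorted order into 2..k_max bins (cuts only between distinct values), by
    dynamic programming over the last-cut position.  The result depends only on
    the ordering and tie structure of ``x``, hence is exactly invariant under
    strictly increasing transforms.  A constant ``x`` yields mic = 0 with a
    single degenerate bin.
    """
    cfg = config or MICConfig()
    x, y = series.x, series.y
    n = series.n
    bnd, cum1 = _sorted_blocks(x, y)
    m = len(bnd) - 1  # number of tie blocks
    if m == 1:
        return MICResult(0.0, 1, ())
    kmax = min(max_x_bins(n, cfg.alpha), m)
    f = _bin_weights(bnd, cum1)
    hy = _label_entropy(int(cum1[-1]), n)
    if cfg.termination == "chi_square":
        return _mic_chi_square(bnd, cum1, f, hy, n, kmax, cfg.chi_level)

    # dp[j] = best weight-sum of a partition of the first bnd[j] samples into
    # the current number of bins; parents enable grid backtracking.
    dp = f[0].copy()
    parents = np.zeros((kmax + 1, m + 1), dtype=np.intp)
    best_mic, best_k = -np.inf, 2
    for k in range(2, kmax + 1):
        s = dp[:, None] + f
        parents[k] = np.argmax(s, axis=0)
        dp = np.max(s, axis=0)
        score = hy + dp[m] / n
        if score > best_mic + 1e-15:
            best_mic, best_k = score, k
    cuts = []
    j = m
    for k in range(best_k, 1, -1):
        j = int(parents[k][j])
        cuts.append(int(bnd[j]))
    cuts.reverse()
    mic = min(max(best_mic, 0.0), 1.0)
    return MICResult(float(mic), best_k, tuple(cuts))


def _split_pvalue(n1_left: int, n_left: int, n1_right: int, n_right: int) -> float:
    """Pearson chi-square (df=1, no correction) p-value for a bin split's 2x2 table."""
    table = np.array(
        [[n1_left, n_left - n1_left], [n1_right, n_right - n1_right]], dtype=float
    )
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    if np.any(cols == 0):  # one class absent from both sub-bins: no association
        return 1.0
    expected = np.outer(rows, cols) / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    return float(_chi2_dist.sf(stat, 1))


def _mic_chi_square(bnd, cum1, f, hy, n, kmax, chi_level) -> MICResult:
    """Greedy cut insertion stopped by a local chi-square test (ChiMIC-style).

    Approximation mode: repeatedly inserts the information-maximizing cut; the
    split is kept only while the two new sub-bins' label counts differ
    significantly at ``chi_level``.
    """
    m = len(bnd) - 1
    boundaries = [0, m]
    while len(boundaries) - 1 < kmax:
        best_gain, best_pos, best_slot = -np.inf, None, None
        for slot in range(len(boundaries) - 1):
            i, j = boundaries[slot], boundaries[slot + 1]
            if j - i < 2:
                continue
            cands = np.arange(i + 1, j)
            gains = f[i, cands] + f[cands, j] - f[i, j]
            a = int(np.argmax(gains))
            if gains[a] > best_gain:
                best_gain, best_pos, best_slot = float(gains[a]), int(cands[a]), slot
        if best_pos is None:
            break
        i, j = boundaries[best_slot], boundaries[best_slot + 1]
        p = _split_pvalue(
            int(cum1[best_pos] - cum1[i]),
            int(bnd[best_pos] - bnd[i]),
            int(cum1[j] - cum1[best_pos]),
            int(bnd[j] - bnd[best_pos]),
        )
        if p >= chi_level:
            break
        boundaries.insert(best_slot + 1, best_pos)
    k = len(boundaries) - 1
    if k < 2:
        return MICResult(0.0, 1, ())
    total = sum(f[boundaries[b], boundaries[b + 1]] for b in range(k))
    mic = min(max(hy + total / n, 0.0), 1.0)
    cuts = tuple(int(bnd[b]) for b in boundaries[1:-1])
    return MICResult(float(mic), k, cuts)


def brute_force_mic(series: SampleSeries, config: MICConfig | None = None) -> MICResult:
    """Exhaustive-enumeration MIC oracle for small inputs (n <= 30).

    Enumerates every admissible cut-point subset directly and scores each
    partition with :func:`mutual_information_binned`; independent of the
    dynamic program in :func:`mic_binary`, which it must match to 1e-12.
    """
    cfg = config or MICConfig()
    n = series.n
    if n > 30:
        raise ValueError(f"brute force limited to n <= 30, got {n}")
    bnd, cum1 = _sorted_blocks(series.x, series.y)
    m = len(bnd) - 1
    if m == 1:
        return MICResult(0.0, 1, ())
    kmax = min(max_x_bins(n, cfg.alpha), m)
    best = MICResult(0.0, 1, ())
    for k in range(2, kmax + 1):
        for inner in combinations(range(1, m), k - 1):
            edges = (0, *inner, m)
            c1 = np.diff(cum1[list(edges)])
            nb = np.diff(bnd[list(edges)])
            table = np.vstack([nb - c1, c1])  # rows: class 0, class 1
            i = mutual_information_binned(table)
            if i > best.mic + 1e-15:
                best = MICResult(i, k, tuple(int(bnd[e]) for e in inner))
    return best
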