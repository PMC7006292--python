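"""The NDC (normalized differential correlation) statistic and gene ranking.

NDC highlights genes whose expression separates a binary phenotype
nonlinearly — e.g. one class unimodal, the other bimodal around it — which
mean-shift statistics miss.  Per gene,

    NDC = (MIC - R^2 - Thre_MIC) / |R|

where MIC is the maximal information coefficient against the labels, R the
point-biserial correlation, and Thre_MIC the 95% fractile of MIC scores under
label-vs-shuffled-expression permutations (the finite-sample significance
floor).  Large positive NDC means strong nonlinear but weak linear
association.  Ranking is two-stage: all genes by NDC descending, then the top
pool (default 1000) re-sorted by MIC descending.
"""

from __future__ import annotations

import logging
import math
import time
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .io import ExpressionMatrix, RunConfig
from .mic import MICConfig, SampleSeries, mic_binary

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistribution",
    "GeneScore",
    "perm_threshold",
    "ndc_score",
    "score_all",
    "final_ranking",
    "rank_genes",
]

#: sentinel NDC for constant genes: always ranked last, row still emitted
CONSTANT_SENTINEL = -math.inf


@dataclass(frozen=True)
class NullDistribution:
    """Permutation null of MIC scores and its nearest-rank fractile threshold."""

    values: np.ndarray  # ascending
    n_perm: int
    level: float
    threshold: float
    seed: int


@dataclass
class GeneScore:
    """Per-gene record of every quantity entering the ranking."""

    gene_id: str
    mic: float
    r: float
    r2: float
    ndc: float
    t_stat: float
    t_p: float
    rank_ndc: int | None = None
    rank_final: int | None = None


def _matrix_values(matrix) -> np.ndarray:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.values
    return np.asarray(matrix, dtype=float)


def nearest_rank_index(level: float, count: int) -> int:
    """0-based index of the nearest-rank fractile (1-based ceil(level*count))."""
    return math.ceil(level * count) - 1


def perm_threshold(
    matrix,
    labels,
    n_perm: int = 1000,
    level: float = 0.95,
    seed: int = 42,
    mic_config: MICConfig | None = None,
) -> NullDistribution:
    """Estimate Thre_MIC by gene-resampled sample-order permutation.

    Each iteration draws one gene uniformly at random (with replacement),
    shuffles its sample order, and computes MIC against the unshuffled labels;
    the threshold is the nearest-rank ``level`` fractile of the ascending-sorted
    scores.  Fully reproducible given ``seed``.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100 for a stable fractile, got {n_perm}")
    vals = _matrix_values(matrix)
    if vals.ndim != 2 or vals.shape[0] < 1:
        raise ValueError("matrix must contain at least one gene row")
    labels = np.asarray(labels, dtype=int)
    if np.all(np.ptp(vals, axis=1) == 0):
        raise ValueError("degenerate matrix: every gene is constant")
    cfg = mic_config or MICConfig()
    rng = np.random.default_rng(seed)
    n_genes = vals.shape[0]
    scores = np.empty(n_perm)
    for i in range(n_perm):
        gi = int(rng.integers(n_genes))
        xp = rng.permutation(vals[gi])
        scores[i] = mic_binary(SampleSeries(xp, labels), cfg).mic
    scores.sort()
    threshold = float(scores[nearest_rank_index(level, n_perm)])
    return NullDistribution(
        values=scores, n_perm=n_perm, level=level, threshold=threshold, seed=seed
    )


def ndc_score(mic: float, r: float, threshold: float, eps: float = 1e-8) -> float:
    """NDC = (MIC - r² - threshold) / max(|r|, eps).

    The ``eps`` floor guards the |r| → 0 limit: a truly nonlinear gene has
    near-zero r with a positive numerator, so the floor preserves its top rank
    instead of producing a non-finite score.
    """
    return (mic - r * r - threshold) / max(abs(r), eps)


def _stage1_key(s: GeneScore):
    return (-s.ndc, -s.mic, s.gene_id)


def _stage2_key(s: GeneScore):
    return (-s.mic, -s.ndc, s.gene_id)


def score_all(
    matrix,
    labels,
    null: NullDistribution,
    eps: float = 1e-8,
    mic_config: MICConfig | None = None,
) -> list[GeneScore]:
    """Score every gene: MIC, point-biserial r/r², Welch t, and NDC.

    Constant genes receive the rank-last NDC sentinel (with a logged warning)
    so output row count always equals input gene count.  Output preserves the
    input gene order; ``rank_ndc`` is the position in the NDC-descending
    ordering (ties: MIC descending, then gene ID).
    """
    vals = _matrix_values(matrix)
    if isinstance(matrix, ExpressionMatrix):
        gene_ids = list(matrix.gene_ids)
    else:
        gene_ids = [f"g{i}" for i in range(vals.shape[0])]
    labels = np.asarray(labels, dtype=int)
    if vals.shape[1] != len(labels):
        raise ValueError(
            f"matrix has {vals.shape[1]} samples but labels has {len(labels)}"
        )
    cfg = mic_config or MICConfig()
    n = len(labels)
    y = labels.astype(float)

    # vectorized point-biserial r across genes
    xc = vals - vals.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    ssx = np.einsum("ij,ij->i", xc, xc)
    constant = ssx == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r_all = (xc @ yc) / np.sqrt(ssx * (yc @ yc))
    r_all = np.clip(r_all, -1.0, 1.0)

    # vectorized Welch t (class 0 minus class 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_res = sps.ttest_ind(
            vals[:, labels == 0], vals[:, labels == 1], axis=1, equal_var=False
        )
    t_stat = np.asarray(t_res.statistic, dtype=float)
    t_p = np.asarray(t_res.pvalue, dtype=float)

    scores: list[GeneScore] = []
    for gi, gene in enumerate(gene_ids):
        if constant[gi]:
            logger.warning("gene %s is constant; assigned rank-last sentinel", gene)
            scores.append(
                GeneScore(gene, 0.0, math.nan, math.nan, CONSTANT_SENTINEL,
                          math.nan, math.nan)
            )
            continue
        mic = mic_binary(SampleSeries(vals[gi], labels), cfg).mic
        r = float(r_all[gi])
        scores.append(
            GeneScore(
                gene_id=gene,
                mic=mic,
                r=r,
                r2=r * r,
                ndc=ndc_score(mic, r, null.threshold, eps),
                t_stat=float(t_stat[gi]),
                t_p=float(t_p[gi]),
            )
        )
    for rank, s in enumerate(sorted(scores, key=_stage1_key), start=1):
        s.rank_ndc = rank
    logger.info(
        "scored %d genes on %d samples (classes %d/%d), threshold %.6f",
        len(scores), n, int((labels == 0).sum()), int((labels == 1).sum()),
        null.threshold,
    )
    return scores


def final_ranking(scores: list[GeneScore], top_pool: int = 1000) -> list[GeneScore]:
    """Two-stage ranking: NDC descending, then top pool re-sorted by MIC.

    Stage 1 orders all genes by NDC descending (ties: MIC desc, gene ID asc);
    stage 2 re-sorts the first ``min(top_pool, n)`` of that ordering by MIC
    descending (ties: NDC desc, gene ID asc).  Genes outside the pool keep
    their stage-1 order and have no ``rank_final``.
    """
    if not scores:
        raise ValueError("scores must be non-empty")
    if top_pool < 1:
        raise ValueError(f"top_pool must be >= 1, got {top_pool}")
    stage1 = sorted(scores, key=_stage1_key)
    for rank, s in enumerate(stage1, start=1):
        s.rank_ndc = rank
    pool = sorted(stage1[:top_pool], key=_stage2_key)
    for rank, s in enumerate(pool, start=1):
        s.rank_final = rank
    for s in stage1[top_pool:]:
        s.rank_final = None
    return pool + stage1[top_pool:]


def rank_genes(matrix, labels, config: RunConfig | None = None):
    """Full pipeline: permutation threshold, per-gene scores, final ranking.

    Returns ``(ranked_scores, null)`` where ``ranked_scores`` is the
    final-ranking order.  With ``config.log2p1`` the matrix is log2(x+1)
    transformed first (for raw-scale inputs; r and r² are not scale-invariant).
    """
    cfg = (config or RunConfig()).validate()
    vals = _matrix_values(matrix)
    t0 = time.perf_counter()
    if cfg.log2p1:
        vals = np.log2(vals + 1.0)
        if isinstance(matrix, ExpressionMatrix):
            matrix = ExpressionMatrix(matrix.gene_ids, matrix.sample_ids, vals)
        else:
            matrix = vals
    mic_cfg = MICConfig(
        alpha=cfg.alpha, termination=cfg.termination, chi_level=cfg.chi_level
    )
    null = perm_threshold(
        matrix, labels, n_perm=cfg.n_perm, level=cfg.level, seed=cfg.seed,
        mic_config=mic_cfg,
    )
    scores = score_all(matrix, labels, null, eps=cfg.eps, mic_config=mic_cfg)
    ranked = final_ranking(scores, top_pool=cfg.top_pool)
    logger.info("ranking finished in %.1f s", time.perf_counter() - t0)
    return ranked, null
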