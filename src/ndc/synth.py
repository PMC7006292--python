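"""Synthetic expression matrices with planted nonlinear patterns.

Emulates, on the log2 scale, the expression archetypes that motivate NDC in
paired tumor/adjacent-tissue designs:

* ``null`` — no association: both classes N(base_mean, base_sd).
* ``linear_de`` — ordinary differential expression: class 1 mean-shifted.
* ``bimodal`` — one class unimodal at the center, the other a two-component
  mixture flanking it (near-zero point-biserial r, high MIC).
* ``stratified`` — four distinct expression levels: class 0 a mixture at
  base_mean ± gap/2, class 1 at base_mean ± 3·gap/2 (the ERAP2-like pattern).

Every gene carries a ground-truth record for recovery testing.  Values are
clipped at 0 (log2(x+1) floor) and fully reproducible given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExpressionMatrix

__all__ = [
    "KINDS",
    "PatternSpec",
    "SyntheticTruth",
    "generate",
    "paired_layout",
    "decode_sample_id",
    "default_recovery_specs",
]

KINDS = ("null", "linear_de", "bimodal", "stratified")


@dataclass(frozen=True)
class PatternSpec:
    """Generation parameters for a block of genes sharing one pattern.

    base_mean/base_sd are the log2-scale location and within-component spread;
    shift is the linear_de class-1 mean difference; gap the mixture-component
    separation; mix_weight the probability of the upper component.
    """

    kind: str
    count: int
    base_mean: float = 8.0
    base_sd: float = 0.5
    shift: float = 1.5
    gap: float = 4.0
    mix_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        if self.base_sd <= 0:
            raise ValueError(f"base_sd must be positive, got {self.base_sd}")
        if self.gap <= 0:
            raise ValueError(f"gap must be positive, got {self.gap}")
        if not 0.0 < self.mix_weight < 1.0:
            raise ValueError(
                f"mix_weight must be in (0, 1), got {self.mix_weight}"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    gene_id: str
    kind: str


def default_recovery_specs(
    n_null: int = 1940, n_linear: int = 40, n_bimodal: int = 20
) -> list[PatternSpec]:
    """The standard recovery-benchmark composition (2,000 genes by default)."""
    return [
        PatternSpec("bimodal", n_bimodal),
        PatternSpec("linear_de", n_linear),
        PatternSpec("null", n_null),
    ]


def _mixture(rng, n, lo, hi, sd, w_hi):
    upper = rng.random(n) < w_hi
    return np.where(upper, rng.normal(hi, sd, n), rng.normal(lo, sd, n))


def _gene_values(rng, spec: PatternSpec, n0: int, n1: int) -> np.ndarray:
    m, sd, g = spec.base_mean, spec.base_sd, spec.gap
    if spec.kind == "null":
        return rng.normal(m, sd, n0 + n1)
    if spec.kind == "linear_de":
        return np.concatenate(
            [rng.normal(m, sd, n0), rng.normal(m + spec.shift, sd, n1)]
        )
    if spec.kind == "bimodal":
        x0 = _mixture(rng, n0, m - g / 2, m + g / 2, sd, spec.mix_weight)
        x1 = rng.normal(m, sd, n1)
        return np.concatenate([x0, x1])
    # stratified: class 0 inner pair of levels, class 1 outer pair
    x0 = _mixture(rng, n0, m - g / 2, m + g / 2, sd, spec.mix_weight)
    x1 = _mixture(rng, n1, m - 3 * g / 2, m + 3 * g / 2, sd, spec.mix_weight)
    return np.concatenate([x0, x1])


def generate(
    n_per_class: int, specs: list[PatternSpec], seed: int = 0
) -> tuple[ExpressionMatrix, np.ndarray, list[SyntheticTruth]]:
    """Generate a planted-pattern matrix with paired-design sample IDs.

    Returns (matrix, labels, truths): labels are 0 for paracarcinoma and 1 for
    tumor (lexicographic encoding, matching the label-file convention); gene
    order follows the spec list.  Class-0 columns hold each gene's class-0
    draws regardless of column interleaving.
    """
    if n_per_class < 10:
        raise ValueError(f"n_per_class must be >= 10, got {n_per_class}")
    total = sum(s.count for s in specs)
    if total < 1:
        raise ValueError("specs must plant at least one gene in total")
    rng = np.random.default_rng(seed)
    sample_ids, label_names = paired_layout(n_per_class, seed=seed)
    labels = np.array([1 if l == "tumor" else 0 for l in label_names], dtype=int)
    order0 = np.flatnonzero(labels == 0)
    order1 = np.flatnonzero(labels == 1)
    gene_ids: list[str] = []
    truths: list[SyntheticTruth] = []
    values = np.empty((total, 2 * n_per_class))
    counters = dict.fromkeys(KINDS, 0)
    row = 0
    for spec in specs:
        for _ in range(spec.count):
            counters[spec.kind] += 1
            gid = f"{spec.kind}_{counters[spec.kind]:05d}"
            gene_ids.append(gid)
            truths.append(SyntheticTruth(gid, spec.kind))
            draws = _gene_values(rng, spec, n_per_class, n_per_class)
            values[row, order0] = draws[:n_per_class]
            values[row, order1] = draws[n_per_class:]
            row += 1
    np.clip(values, 0.0, None, out=values)
    matrix = ExpressionMatrix(tuple(gene_ids), tuple(sample_ids), values)
    return matrix, labels, truths


def paired_layout(n_patients: int, seed: int = 0) -> tuple[list[str], list[str]]:
    """Sample IDs and labels for a paired tumor/paracarcinoma design.

    Emits 2·n_patients samples, two per patient with tissue encoded in the ID
    suffix (``-T`` tumor, ``-P`` paracarcinoma), interleaved per patient.
    Patient barcodes are drawn reproducibly from the seed.
    """
    if n_patients < 10:
        raise ValueError(f"n_patients must be >= 10, got {n_patients}")
    rng = np.random.default_rng(seed)
    codes = rng.choice(np.arange(1000, 10000), size=n_patients, replace=False)
    sample_ids: list[str] = []
    labels: list[str] = []
    for c in codes:
        sample_ids.extend([f"PT{c:04d}-T", f"PT{c:04d}-P"])
        labels.extend(["tumor", "paracarcinoma"])
    return sample_ids, labels


def decode_sample_id(sample_id: str) -> tuple[str, str]:
    """Split a generated sample ID into (patient, tissue)."""
    patient, _, suffix = sample_id.rpartition("-")
    tissue = {"T": "tumor", "P": "paracarcinoma"}.get(suffix)
    if not patient or tissue is None:
        raise ValueError(f"unrecognized sample ID format: {sample_id!r}")
    return patient, tissue
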