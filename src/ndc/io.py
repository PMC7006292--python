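"""File formats and run configuration.

Expression matrices use the Xena genomicMatrix dialect: tab-separated text,
genes as rows, a header row of sample IDs whose first cell is arbitrary
(Xena writes ``sample``), optionally gzipped.  Labels are a two-column TSV of
``sample_id<TAB>label`` with exactly two distinct label values.  Ranked output
is a commented-header TSV with fixed 6-decimal formatting so re-runs diff
byte-identically.
"""

from __future__ import annotations

import dataclasses
import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "RunConfig",
    "LabelAlignment",
    "read_expression",
    "write_expression",
    "read_labels",
    "write_ranked",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of normalized expression values."""

    gene_ids: tuple[str, ...]
    sample_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        genes = tuple(str(g) for g in self.gene_ids)
        samples = tuple(str(s) for s in self.sample_ids)
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(genes), len(samples)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(genes)} genes x {len(samples)} samples"
            )
        for name, ids in (("gene", genes), ("sample", samples)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(f"duplicate {name} IDs: {', '.join(dupes)}")
        if not np.all(np.isfinite(vals)):
            raise ValueError("matrix contains non-finite values")
        object.__setattr__(self, "gene_ids", genes)
        object.__setattr__(self, "sample_ids", samples)
        object.__setattr__(self, "values", vals)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, keep: Iterable[str]) -> "ExpressionMatrix":
        keep = list(keep)
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in keep]
        return ExpressionMatrix(self.gene_ids, tuple(keep), self.values[:, cols])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=float))


@dataclass
class RunConfig:
    """All pipeline tunables with their defaults; echoed into output headers."""

    n_perm: int = 1000
    seed: int = 42
    alpha: float = 0.6
    level: float = 0.95
    eps: float = 1e-8
    top_pool: int = 1000
    log2p1: bool = False
    termination: str = "exhaustive"
    chi_level: float = 0.05
    strict: bool = False

    def validate(self) -> "RunConfig":
        if self.n_perm < 100:
            raise ValueError(f"n_perm must be >= 100, got {self.n_perm}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.0 < self.level < 1.0:
            raise ValueError(f"level must be in (0, 1), got {self.level}")
        if self.eps <= 0:
            raise ValueError(f"eps must be positive, got {self.eps}")
        if self.top_pool < 1:
            raise ValueError(f"top_pool must be >= 1, got {self.top_pool}")
        if self.termination not in ("exhaustive", "chi_square"):
            raise ValueError(f"unknown termination mode {self.termination!r}")
        if not 0.0 < self.chi_level < 1.0:
            raise ValueError(f"chi_level must be in (0, 1), got {self.chi_level}")
        return self

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(sorted(unknown))}")
        return cls(**data).validate()


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _looks_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def read_expression(path, nan_policy: str = "drop") -> ExpressionMatrix:
    """Load a Xena-dialect genomicMatrix TSV (plain or .gz).

    ``nan_policy="drop"`` removes genes with any non-numeric cell and logs a
    warning; ``"strict"`` raises instead.
    """
    if nan_policy not in ("drop", "strict"):
        raise ValueError(f"nan_policy must be 'drop' or 'strict', got {nan_policy!r}")
    genes: list[str] = []
    rows: list[list[str]] = []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ValueError(f"{path}: header must list at least one sample ID")
        samples = header[1:]
        width = len(header)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(fields)} fields, expected {width})"
                )
            genes.append(fields[0])
            rows.append(fields[1:])
    if not genes:
        raise ValueError(f"{path}: no gene rows found")
    numeric_ids = sum(_looks_numeric(g) for g in genes)
    if numeric_ids > 0.5 * len(genes):
        raise ValueError(
            f"{path}: most first-column tokens are numeric — the matrix looks "
            "transposed (expected genes as rows, Xena genomicMatrix layout)"
        )
    for name, ids in (("gene", genes), ("sample", samples)):
        seen, dupes = set(), []
        for i in ids:
            if i in seen:
                dupes.append(i)
            seen.add(i)
        if dupes:
            raise ValueError(
                f"{path}: duplicate {name} IDs: {', '.join(sorted(set(dupes)))}"
            )
    frame = pd.DataFrame(rows, index=genes, columns=samples)
    frame = frame.apply(pd.to_numeric, errors="coerce")
    bad = frame.index[frame.isna().any(axis=1)]
    if len(bad):
        if nan_policy == "strict":
            raise ValueError(
                f"{path}: non-numeric values in genes: {', '.join(bad[:10])}"
            )
        logger.warning(
            "%s: dropped %d gene(s) with non-numeric values: %s",
            path, len(bad), ", ".join(bad[:10]),
        )
        frame = frame.drop(index=bad)
    if frame.empty:
        raise ValueError(f"{path}: no usable gene rows after NaN filtering")
    return ExpressionMatrix.from_dataframe(frame)


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write the Xena-dialect TSV (gzip if the path ends in .gz)."""
    df = matrix.to_dataframe()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.6f")


@dataclass(frozen=True)
class LabelAlignment:
    """Binary labels aligned to a (possibly column-subset) expression matrix."""

    labels: np.ndarray            # 0/1 codes, one per retained matrix column
    matrix: ExpressionMatrix      # columns restricted to labelled samples
    mapping: dict                 # original label value -> 0/1 code


def read_labels(path, matrix: ExpressionMatrix) -> LabelAlignment:
    """Load a two-column sample→label TSV and align it to the matrix columns.

    Exactly two distinct label values must occur among matched samples; codes
    are assigned by lexicographic label order (logged).  Samples present on
    only one side are reported and dropped; at least 8 matched samples are
    required.
    """
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#").dropna()
    if df.shape[1] != 2:
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    sample_set = set(matrix.sample_ids)
    # tolerate a header row ("sample<TAB>label" etc.)
    if len(df) and df.iloc[0, 0] not in sample_set and any(
        s in sample_set for s in df.iloc[1:, 0]
    ):
        logger.info("%s: first row treated as header (%s)", path, tuple(df.iloc[0]))
        df = df.iloc[1:]
    lab = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    if len(lab) != len(df):
        dupes = df.iloc[:, 0][df.iloc[:, 0].duplicated()].unique()
        raise ValueError(f"{path}: duplicate sample IDs: {', '.join(dupes)}")
    matched = [s for s in matrix.sample_ids if s in lab]
    only_matrix = [s for s in matrix.sample_ids if s not in lab]
    only_labels = sorted(set(lab) - sample_set)
    if only_matrix:
        logger.warning("%d matrix sample(s) without labels: %s",
                       len(only_matrix), ", ".join(only_matrix[:10]))
    if only_labels:
        logger.warning("%d labelled sample(s) absent from matrix: %s",
                       len(only_labels), ", ".join(only_labels[:10]))
    if len(matched) < 8:
        raise ValueError(
            f"only {len(matched)} samples match between matrix and labels; need >= 8"
        )
    values = sorted({lab[s] for s in matched})
    if len(values) != 2:
        raise ValueError(
            f"{path}: need exactly two distinct labels among matched samples, "
            f"got {len(values)}: {', '.join(values)}"
        )
    mapping = {values[0]: 0, values[1]: 1}
    logger.info("label encoding: %s→0, %s→1", values[0], values[1])
    labels = np.array([mapping[lab[s]] for s in matched], dtype=int)
    sub = matrix if len(matched) == matrix.n_samples else matrix.subset_samples(matched)
    return LabelAlignment(labels=labels, matrix=sub, mapping=mapping)


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, float):
        return f"{v:.6f}"
    return str(v)


def write_ranked(path, scores, config: RunConfig, null) -> None:
    """Write the ranked TSV: commented config/threshold header, then one row
    per gene in final-ranking order (pool first, remainder by NDC rank)."""
    cols = ["gene", "mic", "r", "r2", "ndc", "rank_ndc", "rank_final", "t_stat", "t_p"]
    with open(path, "w") as fh:
        fh.write("# ndc ranked gene list\n")
        fh.write(f"# threshold = {null.threshold:.6f}\n")
        fh.write(f"# n_perm = {null.n_perm}, level = {null.level}, seed = {null.seed}\n")
        cfg = ", ".join(
            f"{f.name} = {getattr(config, f.name)}"
            for f in dataclasses.fields(config)
        )
        fh.write(f"# config: {cfg}\n")
        fh.write("\t".join(cols) + "\n")
        for s in scores:
            fh.write("\t".join([
                s.gene_id, _fmt(s.mic), _fmt(s.r), _fmt(s.r2), _fmt(s.ndc),
                _fmt(s.rank_ndc), _fmt(s.rank_final), _fmt(s.t_stat), _fmt(s.t_p),
            ]) + "\n")
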