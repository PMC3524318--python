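"""Preprocessing of time-course expression tables.

Turns a raw probe-level intensity table into the standardized
log-concentration-ratio (LCR) matrix consumed by the spline and
time-order modules. The processing stages mirror a typical
time-course microarray workflow:

1. average duplicated probes per gene,
2. drop genes with low coefficient of variation (sd/mean) across time,
3. convert intensities to LCRs, ``log(C_t / C_0)``,
4. standardize each time-point column to mean 0 / sd 1.

Each :class:`ExpressionTable` carries a ``stage`` tag so downstream
code can verify it receives data at the expected processing stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionTable",
    "read_expression_table",
    "write_expression_table",
    "average_duplicate_probes",
    "filter_variable_genes",
    "compute_lcr",
    "standardize_per_timepoint",
]

STAGES = ("raw", "lcr", "standardized_lcr")


class ExpressionFormatError(ValueError):
    """Raised when an input file violates the expression-table format."""


@dataclass(frozen=True)
class ExpressionTable:
    """A genes x time-points expression matrix with a processing-stage tag.

    Parameters
    ----------
    gene_ids
        Unique gene (or probe) identifiers, one per row.
    times
        Strictly increasing sampling times in hours. The first time point
        is the baseline ``C_0`` for LCR computation.
    values
        ``(n_genes, n_times)`` float matrix.
    stage
        One of ``"raw"`` (intensities), ``"lcr"`` (log ratios to baseline)
        or ``"standardized_lcr"`` (per-time-point z-scored LCRs).
    """

    gene_ids: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray
    stage: str = "raw"

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "gene_ids", tuple(str(g) for g in self.gene_ids))
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if times.ndim != 1 or np.any(np.diff(times) <= 0):
            raise ValueError("times must be a strictly increasing 1-D vector")
        if values.shape != (len(self.gene_ids), times.size):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"{len(self.gene_ids)} genes x {times.size} times"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("values must be finite (no missing cells)")
        if self.stage in ("lcr", "standardized_lcr") and values.size:
            if not np.allclose(values[:, 0], 0.0, atol=1e-12):
                raise ValueError("baseline column of an LCR table must be zero")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return self.times.size

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.gene_ids), columns=self.times)


def read_expression_table(path: str | Path, delimiter: str = "\t") -> ExpressionTable:
    """Read a delimited genes x times table.

    The first column holds gene ids; the remaining column headers must
    parse as numeric hours. Columns are reordered to ascending time.
    """
    path = Path(path)
    with open(path) as fh:  # pandas mangles duplicate headers, so check raw
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    try:
        times = np.array([float(c) for c in header])
    except ValueError as exc:
        raise ExpressionFormatError(
            f"{path}: time-column headers must be numeric hours ({exc})"
        ) from exc
    if np.unique(times).size != times.size:
        raise ExpressionFormatError(f"{path}: duplicated time columns")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    order = np.argsort(times)
    df = df.iloc[:, order]
    times = times[order]
    values = np.empty(df.shape, dtype=float)
    for i, (gene, row) in enumerate(df.iterrows()):
        for j, cell in enumerate(row):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) or str(cell).strip() == "":
                raise ExpressionFormatError(
                    f"{path}: missing value at gene {gene!r}, time {times[j]:g}"
                )
            try:
                values[i, j] = float(cell)
            except ValueError as exc:
                raise ExpressionFormatError(
                    f"{path}: unparseable value {cell!r} at gene {gene!r}, time {times[j]:g}"
                ) from exc
    return ExpressionTable(tuple(df.index), times, values, stage="raw")


def write_expression_table(
    table: ExpressionTable, path: str | Path, delimiter: str = "\t", id_header: str = "gene"
) -> None:
    """Write a table so that :func:`read_expression_table` round-trips it."""
    df = table.to_frame()
    df.columns = [f"{t:g}" for t in table.times]
    df.index.name = id_header
    df.to_csv(path, sep=delimiter, float_format="%.12g")


def _require_stage(table: ExpressionTable, stage: str, op: str) -> None:
    if table.stage != stage:
        raise ValueError(f"{op} expects a {stage!r} table, got {table.stage!r}")


def average_duplicate_probes(
    table: ExpressionTable, probe_to_gene: Mapping[str, str]
) -> ExpressionTable:
    """Collapse probe rows to gene rows by per-time-point arithmetic mean.

    Gene order follows the first occurrence of each gene among the probes.
    """
    _require_stage(table, "raw", "average_duplicate_probes")
    missing = [p for p in table.gene_ids if p not in probe_to_gene]
    if missing:
        raise KeyError(f"probes with no gene mapping: {missing[:5]}")
    order: list[str] = []
    rows: dict[str, list[int]] = {}
    for i, probe in enumerate(table.gene_ids):
        gene = str(probe_to_gene[probe])
        if gene not in rows:
            rows[gene] = []
            order.append(gene)
        rows[gene].append(i)
    values = np.vstack([table.values[rows[g]].mean(axis=0) for g in order])
    return ExpressionTable(tuple(order), table.times, values, stage="raw")


def filter_variable_genes(table: ExpressionTable, cv_threshold: float = 0.15) -> ExpressionTable:
    """Keep genes whose coefficient of variation across time exceeds the threshold.

    CV = sample standard deviation / mean, computed per gene on the raw
    intensity scale; genes at or below the threshold are considered not
    differentially expressed and dropped. Default threshold 0.15.
    """
    _require_stage(table, "raw", "filter_variable_genes")
    if np.any(table.values <= 0):
        raise ValueError("CV filtering requires strictly positive intensities")
    sd = table.values.std(axis=1, ddof=1)
    mean = table.values.mean(axis=1)
    keep = sd / mean > cv_threshold
    ids = tuple(g for g, k in zip(table.gene_ids, keep) if k)
    return ExpressionTable(ids, table.times, table.values[keep], stage="raw")


def compute_lcr(table: ExpressionTable) -> ExpressionTable:
    """Convert intensities to log concentration ratios ln(C_t / C_0).

    The natural log is used; after per-time-point standardization the
    base is immaterial (a base change rescales each column by a positive
    constant, which the z-score absorbs).
    """
    _require_stage(table, "raw", "compute_lcr")
    if np.any(table.values <= 0):
        raise ValueError("LCR requires strictly positive concentrations")
    lcr = np.log(table.values / table.values[:, [0]])
    lcr[:, 0] = 0.0
    return ExpressionTable(table.gene_ids, table.times, lcr, stage="lcr")


def standardize_per_timepoint(table: ExpressionTable) -> ExpressionTable:
    """Z-score each time-point column across genes.

    Columns with zero spread — notably the all-zero baseline column —
    are left unchanged, since a z-score is undefined there and zero is
    the semantically correct LCR at t=0.
    """
    _require_stage(table, "lcr", "standardize_per_timepoint")
    if table.n_genes < 2:
        raise ValueError("standardization needs at least 2 genes")
    values = table.values.copy()
    sd = values.std(axis=0, ddof=1)
    mean = values.mean(axis=0)
    nz = sd > 0
    values[:, nz] = (values[:, nz] - mean[nz]) / sd[nz]
    return ExpressionTable(table.gene_ids, table.times, values, stage="standardized_lcr")


def preprocess_pipeline(
    table: ExpressionTable,
    probe_to_gene: Mapping[str, str] | None = None,
    cv_threshold: float = 0.15,
) -> ExpressionTable:
    """Run the full raw -> standardized-LCR preprocessing chain."""
    if probe_to_gene is not None:
        table = average_duplicate_probes(table, probe_to_gene)
    table = filter_variable_genes(table, cv_threshold)
    table = compute_lcr(table)
    return standardize_per_timepoint(table)
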