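"""TPM expression matrices and per-column group metadata.

The container every stage consumes: a gene x column (cell or bulk sample)
table of non-negative TPM values, plus a group label per column.  Genes are
rows and cells/samples are columns throughout, matching the convention of
deposited TPM matrices.  Values live on one of two scales, linear TPM or
log2(TPM+1); the scale is tracked explicitly so a matrix is never silently
double-transformed.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import coo_matrix


class Scale(str, enum.Enum):
    """Scale of the stored values."""

    LINEAR_TPM = "linear_tpm"
    LOG2_TPM_PLUS1 = "log2_tpm_plus1"


class MatrixValidationError(ValueError):
    """Raised when a matrix or its metadata violates an invariant."""


@dataclass(frozen=True)
class GroupDesign:
    """Partition of column ids into named experimental groups."""

    groups: tuple[str, ...]
    columns_per_group: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            cols = self.columns_per_group[g]
            if seen.intersection(cols):
                raise MatrixValidationError(
                    f"group {g!r} shares columns with another group"
                )
            seen.update(cols)

    @property
    def column_to_group(self) -> dict[str, str]:
        return {c: g for g in self.groups for c in self.columns_per_group[g]}

    def sizes(self) -> dict[str, int]:
        return {g: len(self.columns_per_group[g]) for g in self.groups}


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x column non-negative TPM matrix with group labels.

    Parameters
    ----------
    gene_ids
        Ordered, unique gene symbols (row labels).
    column_ids
        Ordered, unique cell or sample identifiers.
    values
        Dense array of shape ``(len(gene_ids), len(column_ids))``.
    scale
        Whether values are linear TPM or log2(TPM+1).
    column_groups
        Group label for every column.
    """

    gene_ids: tuple[str, ...]
    column_ids: tuple[str, ...]
    values: np.ndarray
    scale: Scale = Scale.LINEAR_TPM
    column_groups: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "column_ids", tuple(self.column_ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.column_ids, "column")
        if vals.shape != (len(self.gene_ids), len(self.column_ids)):
            raise MatrixValidationError(
                f"values shape {vals.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        if not np.all(np.isfinite(vals)):
            bad = np.argwhere(~np.isfinite(vals))[0]
            raise MatrixValidationError(
                f"non-finite value at gene {self.gene_ids[bad[0]]!r}, "
                f"column {self.column_ids[bad[1]]!r}"
            )
        if vals.size and vals.min() < 0:
            bad = np.argwhere(vals < 0)[0]
            raise MatrixValidationError(
                f"negative value {vals[bad[0], bad[1]]} at gene "
                f"{self.gene_ids[bad[0]]!r}, column {self.column_ids[bad[1]]!r}"
            )
        if self.column_groups:
            missing = [c for c in self.column_ids if c not in self.column_groups]
            if missing:
                raise MatrixValidationError(
                    f"columns missing from metadata: {missing[:5]}"
                )

    # -- basic accessors ---------------------------------------------------

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.gene_ids), columns=list(self.column_ids)
        )

    def group_of(self, column_id: str) -> str:
        return self.column_groups[column_id]

    def group_design(self) -> GroupDesign:
        order: list[str] = []
        per: dict[str, list[str]] = {}
        for c in self.column_ids:
            g = self.column_groups[c]
            if g not in per:
                per[g] = []
                order.append(g)
            per[g].append(c)
        return GroupDesign(tuple(order), {g: tuple(v) for g, v in per.items()})

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        idx = [self.gene_index(g) for g in genes]
        return replace(self, gene_ids=tuple(genes), values=self.values[idx, :])

    def subset_columns(self, columns: Iterable[str]) -> "ExpressionMatrix":
        columns = list(columns)
        pos = {c: i for i, c in enumerate(self.column_ids)}
        idx = [pos[c] for c in columns]
        groups = {c: self.column_groups[c] for c in columns} if self.column_groups else {}
        return replace(
            self,
            column_ids=tuple(columns),
            values=self.values[:, idx],
            column_groups=groups,
        )


def _check_unique(ids: tuple[str, ...], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        for x in ids:
            if x in seen:
                raise MatrixValidationError(f"duplicate {kind} id {x!r}")
            seen.add(x)


# -- transforms -----------------------------------------------------------


def log_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Return the matrix with every TPM value v replaced by log2(v + 1).

    The unique-gene threshold log2(TPM+1) > 2 is equivalent to TPM > 3 on
    the linear scale.
    """
    if m.scale is not Scale.LINEAR_TPM:
        raise MatrixValidationError("matrix is already log2(TPM+1) scaled")
    return replace(m, values=np.log2(m.values + 1.0), scale=Scale.LOG2_TPM_PLUS1)


def delog_transform(m: ExpressionMatrix) -> ExpressionMatrix:
    """Inverse of :func:`log_transform`: v -> 2**v - 1."""
    if m.scale is not Scale.LOG2_TPM_PLUS1:
        raise MatrixValidationError("matrix is not log2(TPM+1) scaled")
    vals = np.exp2(m.values) - 1.0
    vals[vals < 0] = 0.0  # clamp float noise at zero
    return replace(m, values=vals, scale=Scale.LINEAR_TPM)


def as_linear(m: ExpressionMatrix) -> ExpressionMatrix:
    return m if m.scale is Scale.LINEAR_TPM else delog_transform(m)


def as_log(m: ExpressionMatrix) -> ExpressionMatrix:
    return m if m.scale is Scale.LOG2_TPM_PLUS1 else log_transform(m)


# -- i/o ------------------------------------------------------------------


def read_group_metadata(path: str | Path) -> dict[str, str]:
    """Read a two-column [column_id, group] TSV into a mapping."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise MatrixValidationError(
            f"metadata {path} must have columns [column_id, group]"
        )
    col_id, group = df.columns[0], df.columns[1]
    if df[col_id].duplicated().any():
        dup = df[col_id][df[col_id].duplicated()].iloc[0]
        raise MatrixValidationError(f"duplicate column id {dup!r} in metadata")
    return dict(zip(df[col_id], df[group]))


def write_group_metadata(groups: Mapping[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"column_id": list(groups), "group": [groups[c] for c in groups]}
    ).to_csv(path, sep="\t", index=False)


def read_tpm_matrix(
    path: str | Path,
    metadata_path: str | Path | None = None,
    scale: Scale = Scale.LINEAR_TPM,
) -> ExpressionMatrix:
    """Read a TPM matrix (TSV or MatrixMarket) plus group metadata.

    TSV layout: header row of column ids, first column of gene ids.
    MatrixMarket layout: ``x.mtx`` with ``x.mtx.rownames`` / ``x.mtx.colnames``
    sidecar files (one id per line).  File column order is preserved.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        mat = mmread(path)
        vals = np.asarray(mat.todense() if hasattr(mat, "todense") else mat)
        genes = Path(str(path) + ".rownames").read_text().split()
        cols = Path(str(path) + ".colnames").read_text().split()
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise MatrixValidationError(f"duplicate gene id {dup!r} in {path}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise MatrixValidationError(f"duplicate column id {dup!r} in {path}")
        genes = [str(g) for g in df.index]
        cols = [str(c) for c in df.columns]
        vals = df.to_numpy(dtype=float)
    groups: dict[str, str] = {}
    if metadata_path is not None:
        meta = read_group_metadata(metadata_path)
        missing = [c for c in cols if c not in meta]
        if missing:
            raise MatrixValidationError(
                f"columns missing from metadata: {missing[:5]}"
            )
        groups = {c: meta[c] for c in cols}
    return ExpressionMatrix(tuple(genes), tuple(cols), vals, scale, groups)


def write_matrix(m: ExpressionMatrix, path: str | Path) -> None:
    """Write a matrix as TSV (genes as rows) at full numeric precision.

    Output is byte-deterministic for identical input, so reruns of a stage
    can be compared by file digest.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("gene\t" + "\t".join(m.column_ids) + "\n")
        for i, g in enumerate(m.gene_ids):
            row = "\t".join(np.format_float_positional(v, precision=12, trim="0")
                            for v in m.values[i])
            fh.write(g + ("\t" + row if m.n_columns else "") + "\n")


def write_matrix_mtx(m: ExpressionMatrix, path: str | Path) -> None:
    """Write as MatrixMarket triplet with rownames/colnames sidecars."""
    path = Path(path)
    mmwrite(str(path), coo_matrix(m.values))
    Path(str(path) + ".rownames").write_text("\n".join(m.gene_ids) + "\n")
    Path(str(path) + ".colnames").write_text("\n".join(m.column_ids) + "\n")


def align_genes(
    m: ExpressionMatrix, genes: Iterable[str]
) -> ExpressionMatrix:
    """Subset to ``genes``, padding genes absent from ``m`` with zero rows.

    Bulk and single-cell matrices need not share a gene universe; a missing
    gene is treated as undetected (all-zero) with a warning.
    """
    genes = list(genes)
    have = set(m.gene_ids)
    missing = [g for g in genes if g not in have]
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) absent from matrix treated as zero: "
            f"{missing[:5]}"
        )
    vals = np.zeros((len(genes), m.n_columns))
    pos = {g: i for i, g in enumerate(m.gene_ids)}
    for j, g in enumerate(genes):
        if g in pos:
            vals[j] = m.values[pos[g]]
    return replace(m, gene_ids=tuple(genes), values=vals)
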