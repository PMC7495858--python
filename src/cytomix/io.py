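"""Readers and writers for expression matrices and covariate tables.

CSV/TSV are the canonical tabular formats (read/write); FCS is read-only.
An optional arcsinh(x / cofactor) transform is available for raw cytometry
scales but is off by default — the model is otherwise fit on values as given.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .fcs import read_fcs
from .types import DesignMatrix, MarkerMatrix, ValidationError

ARCSINH_COFACTOR = 5.0


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt.lower()
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".tsv", ".txt", ".tab"):
        return "tsv"
    if suffix == ".fcs":
        return "fcs"
    raise ValidationError(f"cannot infer format from {path.name!r}; pass format=")


def read_expression(
    path: str | Path,
    format: Optional[str] = None,
    channels: Optional[Sequence[str]] = None,
    arcsinh: bool = False,
    cofactor: float = ARCSINH_COFACTOR,
    censored: bool = False,
) -> MarkerMatrix:
    """Read a cell-by-marker matrix from CSV, TSV, or FCS.

    ``channels`` selects a subset of markers by name; ``arcsinh`` applies
    x -> arcsinh(x / cofactor).  ``censored=True`` asserts mass-cytometry
    semantics (all values nonnegative, zeros read as censored).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    fmt = _infer_format(path, format)
    if fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            raise ValidationError(
                f"{path.name}: non-numeric values in column(s) {list(bad[:10])}"
            )
        values = df.to_numpy(dtype=float)
        names = list(df.columns)
    elif fmt == "fcs":
        values, names, _ = read_fcs(path)
    else:
        raise ValidationError(f"unknown format {fmt!r}; expected csv, tsv, or fcs")

    if channels is not None:
        missing = [c for c in channels if c not in names]
        if missing:
            raise ValidationError(f"{path.name}: unknown channel(s) {missing[:10]}")
        cols = [names.index(c) for c in channels]
        values = values[:, cols]
        names = list(channels)
    if arcsinh:
        values = np.arcsinh(values / cofactor)
    return MarkerMatrix(values, marker_names=names, is_censored=censored)


def write_expression(path: str | Path, Y: MarkerMatrix, format: Optional[str] = None) -> None:
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt not in ("csv", "tsv"):
        raise ValidationError("expression matrices are written as CSV or TSV only")
    pd.DataFrame(Y.values, columns=Y.marker_names).to_csv(
        path, sep="," if fmt == "csv" else "\t", index=False
    )


def read_covariates(
    path: str | Path,
    formula_columns: Sequence[str],
    id_column: Optional[str] = None,
    cell_ids: Optional[Sequence] = None,
) -> DesignMatrix:
    """Build a dummy-coded design matrix from a covariate table.

    Each requested column is treated as categorical and dummy-coded with its
    first level (in sorted order) as the reference; an intercept column is
    prepended.  Rows map to cells by ``id_column`` matched against
    ``cell_ids`` (broadcasting a per-sample table to cells), or by file
    order when no ID column is given.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in formula_columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing covariate column(s) {missing}")

    if id_column is not None:
        if cell_ids is None:
            raise ValidationError("id_column given but no cell_ids to match against")
        if id_column not in df.columns:
            raise ValidationError(f"{path.name}: missing ID column {id_column!r}")
        table = df.set_index(id_column)
        unmatched = [i for i in pd.unique(pd.Series(cell_ids)) if i not in table.index]
        if unmatched:
            raise ValidationError(
                f"{len(unmatched)} cell ID(s) not found in {path.name}; "
                f"first 10: {unmatched[:10]}"
            )
        df = table.loc[list(cell_ids), list(formula_columns)].reset_index(drop=True)
    else:
        df = df[list(formula_columns)]

    blocks = [pd.Series(1.0, index=df.index, name="intercept")]
    for col in formula_columns:
        cat = pd.Categorical(df[col].astype(str))
        dummies = pd.get_dummies(cat, prefix=col, drop_first=True, dtype=float)
        blocks.append(dummies)
    design = pd.concat(blocks, axis=1)
    return DesignMatrix(design.to_numpy(dtype=float), list(design.columns))
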