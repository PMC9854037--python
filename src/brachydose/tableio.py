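"""CSV readers/writers for dosimetric tables.

Two layouts: ``long`` (one row per cell, doubles at 17 significant digits so
write/read round-trips are bit-exact) and ``matrix`` (first column is the row
coordinate, header row the column coordinate — mirroring the printed table
layout and its precision).  Missing entries are empty fields, never zeros.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["write_table", "read_table", "matrix_to_long", "long_to_matrix"]


def write_table(df: pd.DataFrame, path, layout: str = "long") -> None:
    """Write a table; ``long`` preserves doubles exactly, ``matrix`` mirrors
    the printed row/column ordering."""
    path = Path(path)
    if layout == "long":
        df.to_csv(path, index=False, float_format="%.17g")
    elif layout == "matrix":
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown layout {layout!r}")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), float_precision="round_trip")


def matrix_to_long(df: pd.DataFrame, row_name: str, col_name: str,
                   value_name: str = "value") -> pd.DataFrame:
    """Melt a matrix-layout table into (row, col, value) rows (drops missing)."""
    rows = df.iloc[:, 0].to_numpy(dtype=float)
    out = []
    for col in df.columns[1:]:
        vals = df[col].to_numpy(dtype=float)
        for rv, v in zip(rows, vals):
            if np.isfinite(v):
                out.append((rv, float(col), v))
    return pd.DataFrame(out, columns=[row_name, col_name, value_name])


def long_to_matrix(df: pd.DataFrame, row_name: str, col_name: str,
                   value_name: str = "value") -> pd.DataFrame:
    pivot = df.pivot(index=row_name, columns=col_name, values=value_name)
    pivot = pivot.sort_index().sort_index(axis=1)
    out = pd.DataFrame(pivot.to_numpy(),
                       columns=[repr(float(c)) for c in pivot.columns])
    out.insert(0, row_name, pivot.index.to_numpy())
    return out
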