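"""Reading regression problems from delimited text tables."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import RegressionProblem

__all__ = ["read_problem", "ReadReport"]


@dataclass(frozen=True)
class ReadReport:
    problem: RegressionProblem
    n_dropped: int  # rows removed because of missing values


def read_problem(path, y: str, x, z=None, sep=None,
                 add_intercept: bool = True) -> ReadReport:
    """Read a RegressionProblem from a delimited text file with a header.

    Parameters
    ----------
    path : file path or buffer
    y : name of the response column
    x : name (or list of names) of the covariate(s) of interest
    z : list of control-column names; by default every remaining numeric
        column is used
    sep : field separator; inferred by pandas when None
    add_intercept : append a constant column to Z unless Z already
        contains one

    Rows with missing values in the selected columns are dropped (the
    count is reported); non-numeric cells raise an error naming the row
    and column.
    """
    df = pd.read_csv(path, sep=sep, engine="python")
    x_cols = [x] if isinstance(x, str) else list(x)
    for col in [y, *x_cols]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {list(df.columns)}")
    if z is None:
        z_cols = [c for c in df.columns if c not in {y, *x_cols}]
    else:
        z_cols = [z] if isinstance(z, str) else list(z)
        missing = [c for c in z_cols if c not in df.columns]
        if missing:
            raise ValueError(f"control columns not found: {missing}")
    used = df[[y, *x_cols, *z_cols]]
    numeric = used.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & used.notna()
    if bad.any().any():
        col = bad.any()[bad.any()].index[0]
        row = int(bad[col].idxmax())
        raise ValueError(f"non-numeric value in column {col!r}, row {row}: {used.loc[row, col]!r}")
    keep = numeric.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    numeric = numeric[keep]
    if numeric.shape[0] == 0:
        raise ValueError("no usable rows after dropping missing values")
    Y = numeric[y].to_numpy(dtype=float)
    X = numeric[x_cols].to_numpy(dtype=float)
    Z = numeric[z_cols].to_numpy(dtype=float) if z_cols else np.empty((len(Y), 0))
    has_const = Z.shape[1] > 0 and np.any(np.ptp(Z, axis=0) == 0)
    if add_intercept and not has_const:
        Z = np.column_stack([np.ones(len(Y)), Z])
    if Z.shape[1] == 0:
        raise ValueError("no control columns; pass z= or enable add_intercept")
    return ReadReport(problem=RegressionProblem(Y, X, Z), n_dropped=n_dropped)
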