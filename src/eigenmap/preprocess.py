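"""Covariate residualization and per-gene standardization.

Expression is adjusted for sex, age at death and sequencing batch (plus any
further covariates named in config) by ordinary least squares before any
correlation-based network step; downstream math consumes residualized,
standardized rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def _design_matrix(
    cov: pd.DataFrame, covariate_names: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Intercept + centered quantitative + indicator-contrast categorical."""
    cols = [np.ones(len(cov))]
    names = ["intercept"]
    for name in covariate_names:
        if name not in cov.columns:
            raise KeyError(f"covariate {name!r} not in table")
        col = cov[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float) - float(col.mean()))
            names.append(name)
        else:
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:  # first level is the reference
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{name}[{lev}]")
    X = np.column_stack(cols)
    return X, names


def residualize(
    expr: pd.DataFrame, cov: pd.DataFrame, covariate_names: list[str]
) -> pd.DataFrame:
    """Replace each gene by its OLS residuals on the covariate design.

    Samples are matched by id; categorical covariates expand to indicator
    contrasts and quantitative ones are centered. A rank-deficient design
    raises with the collinear columns named.
    """
    missing = [s for s in expr.columns if s not in cov.index]
    if missing:
        raise KeyError(f"samples missing from covariate table: {missing}")
    cov = cov.loc[list(expr.columns)]
    X, names = _design_matrix(cov, covariate_names)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns not adding rank, left to right
        bad, kept = [], np.ones((X.shape[0], 0))
        for j, nm in enumerate(names):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(nm)
            else:
                kept = cand
        raise ValueError(f"rank-deficient covariate design; collinear: {bad}")
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = pd.DataFrame(resid.T, index=expr.index, columns=expr.columns)
    out.attrs["covariates_used"] = list(covariate_names)
    return out


def standardize(expr: pd.DataFrame) -> pd.DataFrame:
    """Scale every gene to mean 0, variance 1 (n-1 denominator)."""
    vals = expr.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=1)
    const = expr.index[sd == 0].tolist()
    if const:
        raise ValueError(f"constant genes cannot be standardized: {const}")
    out = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)
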