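"""Design-matrix construction shared by the SOV, differential and
network-adjustment stages.

Categorical covariates are dummy-coded against a first-level reference;
numeric covariates with more than a handful of distinct values enter
linearly.  All per-lipid model fits reuse one QR factorization of the
common design, which is what makes fitting hundreds of lipids cheap.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def is_categorical(x: pd.Series) -> bool:
    return not pd.api.types.is_numeric_dtype(x) or x.nunique() <= 5


def build_design(clinical: pd.DataFrame, factors: list[str]):
    """Return ``(X, blocks)``: the n x q design with intercept, and a map
    factor -> column indices within X."""
    cols = [np.ones(len(clinical))]
    names = ["Intercept"]
    blocks: dict[str, list[int]] = {}
    idx = 1
    for f in factors:
        if f not in clinical.columns:
            raise KeyError(f"factor {f!r} not in clinical table")
        x = clinical[f]
        if is_categorical(x):
            levels = sorted(map(str, x.unique()))
            block = []
            for lvl in levels[1:]:   # first level = reference
                cols.append((x.astype(str) == lvl).to_numpy(dtype=float))
                names.append(f"{f}[{lvl}]")
                block.append(idx)
                idx += 1
            blocks[f] = block
        else:
            cols.append(x.to_numpy(dtype=float))
            names.append(f)
            blocks[f] = [idx]
            idx += 1
    X = np.column_stack(cols)
    return X, blocks, names


def find_aliased(X: np.ndarray, blocks: dict[str, list[int]]) -> list[str]:
    """Factors whose columns add nothing to the design's rank."""
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return []
    aliased = []
    for f, cols in blocks.items():
        if not cols:
            continue
        others = [c for c in range(X.shape[1]) if c not in cols]
        if np.linalg.matrix_rank(X[:, others]) == rank:
            aliased.append(f)
    return aliased


def prune_aliased(clinical: pd.DataFrame, factors: list[str]) -> tuple[list[str], list[str]]:
    """Drop factors (last first) until the design has full rank."""
    kept = list(factors)
    dropped = []
    while kept:
        X, blocks, _ = build_design(clinical, kept)
        bad = find_aliased(X, blocks)
        if not bad:
            break
        victim = bad[-1]
        kept.remove(victim)
        dropped.append(victim)
    return kept, dropped


def check_full_rank(X: np.ndarray, blocks: dict[str, list[int]]) -> None:
    """Raise naming the aliased factors if the design is singular."""
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    aliased = find_aliased(X, blocks)
    raise ValueError(f"singular design; aliased factors: {aliased or 'unknown'}")


def rss_multi(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares of OLS of each column of Y on X."""
    Q, _ = np.linalg.qr(X)
    fitted_ss = np.sum((Q.T @ Y) ** 2, axis=0)
    return np.sum(Y ** 2, axis=0) - fitted_ss


def ols_multi(X: np.ndarray, Y: np.ndarray):
    """OLS of each column of Y on X.

    Returns ``(beta, rss, xtx_inv)`` with ``beta`` of shape (q, n_lipids).
    """
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    rss = np.sum(resid ** 2, axis=0)
    xtx_inv = np.linalg.inv(X.T @ X)
    return beta, rss, xtx_inv
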