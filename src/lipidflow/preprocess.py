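"""Lipid matrix preprocessing: KNN imputation, log transform, median
normalization.

Imputation runs on the raw scale with samples as neighbours: a missing
value for lipid *l* in sample *s* is the unweighted mean of *l* in the
``k`` samples nearest to *s*, where distance is plain Euclidean over the
lipids both samples observed, computed on per-lipid z-scores so
high-abundance species do not dominate.  Observed cells are never touched
and the original missingness mask is retained for audit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import LipidMatrix


def knn_impute(matrix: LipidMatrix, k: int = 10) -> LipidMatrix:
    """Impute missing cells by the k-nearest-sample mean, per lipid.

    Raises if ``k`` is not smaller than the number of samples, if any lipid
    is missing in every sample, or if a lipid has fewer than ``k`` observed
    values (too few candidate neighbours to honour ``k``).
    """
    if matrix.scale_state not in ("raw", "log"):
        raise ValueError("impute before median normalization")
    X = matrix.values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    n, p = X.shape
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_samples={n}")
    if not obs.any(axis=0).all():
        bad = matrix.lipid_ids[~obs.any(axis=0)].tolist()
        raise ValueError(f"lipids missing in all samples: {bad}")
    n_obs = obs.sum(axis=0)
    if (n_obs < k).any():
        bad = matrix.lipid_ids[n_obs < k].tolist()
        raise ValueError(f"fewer than k={k} observed values for: {bad}")
    if obs.all():
        return matrix

    # z-score per lipid over observed entries, for the distance metric only
    mean = np.nanmean(X, axis=0)
    sd = np.nanstd(X, axis=0, ddof=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    Z0 = np.where(obs, Z, 0.0)

    # squared Euclidean distance over mutually observed lipids, vectorized:
    # d2[i,j] = sum_m obs_i obs_j (z_i - z_j)^2
    sq = Z0 ** 2
    o = obs.astype(float)
    d2 = (sq @ o.T) + (o @ sq.T) - 2.0 * (Z0 @ Z0.T)
    np.maximum(d2, 0.0, out=d2)
    shared = o @ o.T
    d2[shared == 0] = np.inf     # no mutually observed lipids
    np.fill_diagonal(d2, np.inf)

    out = X.copy()
    for j in np.flatnonzero(~obs.all(axis=0)):
        donors = np.flatnonzero(obs[:, j])
        for i in np.flatnonzero(~obs[:, j]):
            d = d2[i, donors]
            order = np.argsort(d, kind="stable")[:k]
            out[i, j] = X[donors[order], j].mean()
    return matrix.with_values(
        pd.DataFrame(out, index=matrix.sample_ids, columns=matrix.lipid_ids))


def log_median_normalize(matrix: LipidMatrix, log_base: float = 2.0) -> LipidMatrix:
    """Log-transform, then shift each sample so its median matches the
    grand median of per-sample medians.

    The additive shift on the log scale makes the result invariant to
    per-sample multiplicative scaling of raw abundances while keeping the
    values at an interpretable abundance level (centering at the grand
    median rather than zero).
    """
    X = matrix.values.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("impute missing values before normalization")
    if (X <= 0).any():
        i, j = np.argwhere(X <= 0)[0]
        raise ValueError(
            f"non-positive abundance at sample {matrix.sample_ids[i]!r}, "
            f"lipid {matrix.lipid_ids[j]!r}")
    L = np.log(X) / np.log(log_base)
    med = np.median(L, axis=1, keepdims=True)
    L = L - med + np.median(med)
    return matrix.with_values(
        pd.DataFrame(L, index=matrix.sample_ids, columns=matrix.lipid_ids),
        scale_state="log-median-normalized", log_base=log_base)


def preprocess(matrix: LipidMatrix, k: int = 10, log_base: float = 2.0) -> LipidMatrix:
    """Impute (if needed) then log-median-normalize; the standard entry
    point for downstream stages."""
    if matrix.values.isna().any().any():
        matrix = knn_impute(matrix, k=k)
    return log_median_normalize(matrix, log_base=log_base)
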