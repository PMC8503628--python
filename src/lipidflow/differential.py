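"""Confounder-adjusted differential lipid discovery.

Each lipid is modelled by ordinary least squares on case/control status
plus the screened confounders.  Residual variances are then shrunk
toward a pooled prior by empirical Bayes: the prior degrees of freedom
``d0`` and prior variance ``s0^2`` are estimated by moment-matching the
scaled-F distribution of the log sample variances, the posterior
variance is ``(d0*s0^2 + d*s^2) / (d0 + d)``, and the status t statistic
uses this posterior variance with ``d + d0`` degrees of freedom.

The final list applies a dual-cohort rule: a lipid must be significant
(raw p below ``alpha``) for status and significant for no confounder in
both the full cohort and a subset free of case-only confounders
(non-smokers without gestational diabetes); the intersection of the two
per-cohort lists is the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma

from ._design import build_design, check_full_rank, ols_multi
from .containers import LipidMatrix


def _trigamma_inverse(y: float, tol: float = 1e-10) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = float(polygamma(1, x))
        step = (tri - y) / float(polygamma(2, x))
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < tol * x:
            break
    return x


def estimate_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-matching estimate of the variance prior ``(d0, s0^2)``.

    Under the hierarchical model the log sample variances follow a shifted
    log-F; matching their mean and excess variance over the trigamma(df/2)
    sampling term yields closed-form estimates.  When the observed spread
    does not exceed the sampling spread, ``d0`` is infinite (all lipids
    share one variance).
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, 1e-300)
    z = np.log(s2)
    e = z - float(polygamma(0, df / 2.0)) + math.log(df / 2.0)
    n = len(e)
    if n < 2:
        return math.inf, float(np.exp(e.mean()))
    var_e = float(e.var(ddof=1))
    excess = var_e - float(polygamma(1, df / 2.0))
    if excess <= 0:
        return math.inf, float(np.exp(e.mean()))
    half_d0 = _trigamma_inverse(excess)
    d0 = 2.0 * half_d0
    log_s0 = float(e.mean()) + float(polygamma(0, half_d0)) - math.log(half_d0)
    return d0, float(np.exp(log_s0))


@dataclass
class DifferentialResult:
    """Per-lipid moderated differential statistics.

    ``table`` columns: ``coef`` (status effect, log units), ``se``,
    ``s2`` (residual variance), ``s2_post`` (posterior variance), ``t``
    (moderated), ``p`` (status), one ``conf_p_<factor>`` per confounder
    (smallest coefficient p within the factor), and boolean
    ``significant`` / ``confounded`` flags at ``alpha``.
    """
    table: pd.DataFrame
    prior_df: float
    prior_var: float
    resid_df: int
    alpha: float
    covariates: list = field(default_factory=list)

    @property
    def significant_unconfounded(self) -> list:
        t = self.table
        return t.index[t["significant"] & ~t["confounded"]].tolist()


def fit_moderated(matrix: LipidMatrix, clinical: pd.DataFrame,
                  covariates: list[str], status: str = "status",
                  alpha: float = 0.01, prior_df: float | None = None,
                  adjust: str = "none") -> DifferentialResult:
    """Moderated per-lipid linear models of status plus confounders.

    ``prior_df`` overrides the estimated prior degrees of freedom; 0
    disables moderation entirely (ordinary t tests).  ``adjust="bh"``
    applies Benjamini-Hochberg to the status p-values before flagging
    significance (off by default; the primary rule is raw p < alpha).
    """
    clinical = clinical.loc[matrix.sample_ids]
    factors = [status] + [c for c in covariates if c != status]
    X, blocks, names = build_design(clinical, factors)
    check_full_rank(X, blocks)
    n, q = X.shape
    d = n - q
    if d <= 1:
        raise ValueError("not enough residual degrees of freedom")
    Y = matrix.values.to_numpy(dtype=float)
    beta, rss, xtx_inv = ols_multi(X, Y)
    s2 = rss / d

    if prior_df is None:
        d0, s02 = estimate_prior(s2, d)
    elif prior_df == 0:
        d0, s02 = 0.0, float(np.mean(s2))
    else:
        d0 = float(prior_df)
        _, s02 = estimate_prior(s2, d)
    if math.isinf(d0):
        if np.ptp(s2) == 0:
            # degenerate: literally identical variances carry no pooling
            # information; keep the ordinary t (flagged by infinite d0)
            s2_post = s2.copy()
            df_total = d
        else:
            # homogeneous variances: complete shrinkage to the pooled
            # prior; the moderated t is effectively normal
            s2_post = np.full_like(s2, s02)
            df_total = 1e6
    else:
        s2_post = (d0 * s02 + d * s2) / (d0 + d)
        df_total = d0 + d

    v = np.diag(xtx_inv)
    status_col = blocks[status][0]

    def coef_p(col: int) -> tuple[np.ndarray, np.ndarray]:
        se = np.sqrt(s2_post * v[col])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = beta[col] / se
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
        return t, p

    t_status, p_status = coef_p(status_col)
    table = pd.DataFrame({
        "coef": beta[status_col],
        "se": np.sqrt(s2_post * v[status_col]),
        "s2": s2,
        "s2_post": s2_post,
        "t": t_status,
        "p": p_status,
    }, index=matrix.lipid_ids)

    conf_cols = []
    for f in factors:
        if f == status:
            continue
        ps = np.column_stack([coef_p(c)[1] for c in blocks[f]]) if blocks[f] \
            else np.full((matrix.n_lipids, 1), 1.0)
        table[f"conf_p_{f}"] = ps.min(axis=1)
        conf_cols.append(f"conf_p_{f}")

    p_flag = table["p"].to_numpy()
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        p_flag = multipletests(p_flag, method="fdr_bh")[1]
    elif adjust != "none":
        raise ValueError(f"unknown adjust {adjust!r}")
    table["significant"] = p_flag < alpha
    table["confounded"] = (table[conf_cols] < alpha).any(axis=1) if conf_cols \
        else False
    return DifferentialResult(table=table, prior_df=d0, prior_var=s02,
                              resid_df=d, alpha=alpha,
                              covariates=[f for f in factors if f != status])


def confounder_free_subset(clinical: pd.DataFrame,
                           exclude: dict | None = None) -> pd.Index:
    """Sample ids free of case-only confounders.

    ``exclude`` maps column -> level to drop; the default removes smokers
    and gestational-diabetes pregnancies.
    """
    exclude = exclude or {"smoker": "yes", "gestational_diabetes": "yes"}
    keep = pd.Series(True, index=clinical.index)
    for col, level in exclude.items():
        if col in clinical.columns:
            keep &= clinical[col].astype(str) != str(level)
    return clinical.index[keep]


def dual_cohort_intersect(full: DifferentialResult, subset: DifferentialResult,
                          alpha: float = 0.01) -> pd.DataFrame:
    """Intersect the per-cohort significant-and-unconfounded lists.

    ``alpha`` thresholds the status p-value; the confounder-association
    flag is the one computed at fit time (so the final list is monotone
    non-increasing as ``alpha`` shrinks).  Returns a frame over the final
    lipids with per-cohort provenance (status p in each cohort and the
    direction of change).
    """
    if not full.table.index.equals(subset.table.index):
        raise ValueError("mismatched lipid universes between cohorts")

    def clean_list(res: DifferentialResult) -> pd.Index:
        t = res.table
        return t.index[(t["p"] < alpha) & ~t["confounded"]]

    l1, l2 = clean_list(full), clean_list(subset)
    final = [lip for lip in full.table.index if lip in set(l1) & set(l2)]
    out = pd.DataFrame({
        "coef_full": full.table.loc[final, "coef"],
        "p_full": full.table.loc[final, "p"],
        "p_subset": subset.table.loc[final, "p"],
        "direction": np.where(full.table.loc[final, "coef"] > 0, "up", "down"),
    }, index=pd.Index(final, name="lipid"))
    return out
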