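"""Source-of-variation (SOV) screen.

For every lipid, an additive linear model on all clinical factors is
fitted and each factor's Type II sum of squares (its marginal SS given
all other factors) is converted to an F statistic against the residual
mean square.  Lipids whose case/control F exceeds 1 — equivalently,
whose status mean square exceeds the error mean square — pass the screen
that the downstream differential and network stages consume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._design import build_design, check_full_rank, rss_multi
from .containers import LipidMatrix


@dataclass
class SovResult:
    """Per-lipid, per-factor variance decomposition.

    ``F``, ``ss`` are lipids x factors frames; ``df`` maps factor to its
    degrees of freedom; ``error_ss``/``error_df`` describe the residual.
    ``ranking`` orders factors by mean F across lipids (descending).
    """
    F: pd.DataFrame
    ss: pd.DataFrame
    df: dict
    error_ss: pd.Series
    error_df: int
    ranking: list

    @property
    def factors(self) -> list:
        return list(self.F.columns)


def sov_decompose(matrix: LipidMatrix, clinical: pd.DataFrame,
                  factors: list[str]) -> SovResult:
    """Type II ANOVA decomposition of every lipid over ``factors``."""
    if matrix.values.isna().any().any():
        raise ValueError("SOV requires a complete (imputed) matrix")
    clinical = clinical.loc[matrix.sample_ids]
    X, blocks, _ = build_design(clinical, factors)
    constant = [f for f in factors if not blocks[f]]
    if constant:
        import warnings
        warnings.warn(f"constant factors excluded from SOV: {constant}")
        factors = [f for f in factors if blocks[f]]
    check_full_rank(X, blocks)
    Y = matrix.values.to_numpy(dtype=float)
    n, q = X.shape
    rss_full = rss_multi(X, Y)
    error_df = n - q
    if error_df <= 0:
        raise ValueError("more coefficients than samples")
    ss = {}
    df = {}
    for f in factors:
        keep = [c for c in range(q) if c not in blocks[f]]
        rss_red = rss_multi(X[:, keep], Y)
        ss[f] = np.maximum(rss_red - rss_full, 0.0)
        df[f] = len(blocks[f])
    ss_frame = pd.DataFrame(ss, index=matrix.lipid_ids)
    mse = rss_full / error_df
    F = ss_frame.div(pd.Series(df)) \
                .div(pd.Series(mse, index=matrix.lipid_ids), axis=0)
    ranking = F.mean(axis=0).sort_values(ascending=False).index.tolist()
    return SovResult(F=F, ss=ss_frame, df=df,
                     error_ss=pd.Series(rss_full, index=matrix.lipid_ids),
                     error_df=error_df, ranking=ranking)


def screen_lipids(sov: SovResult, factor: str = "status",
                  threshold: float = 1.0, rule: str = "f") -> list:
    """Lipids whose ``factor`` F statistic exceeds ``threshold``.

    ``rule="f"`` compares the mean-square ratio F (the primary rule);
    ``rule="ss_ratio"`` instead requires the factor's sum of squares to
    exceed ``threshold`` times the error sum of squares — the two differ
    whenever the factor and error degrees of freedom differ.  Matrix
    order is preserved.
    """
    if factor not in sov.F.columns:
        raise KeyError(f"unknown factor {factor!r}")
    if rule == "f":
        keep = sov.F[factor] > threshold
    elif rule == "ss_ratio":
        keep = sov.ss[factor] > threshold * sov.error_ss
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return sov.F.index[keep].tolist()
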