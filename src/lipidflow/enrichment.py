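"""Lipid-class over/under-representation in a lipid set.

For every class, the member set is crossed with class membership in a
2x2 table against the universe and tested with one-sided Fisher exact
tests: the greater tail for enrichment (odds ratio above 1) and the
lesser tail for depletion (odds ratio below 1).  Odds ratios are sample
cross-product ratios; no multiplicity correction is applied by default,
a Benjamini-Hochberg option is available.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats


def class_enrichment(members, universe, classes: pd.Series,
                     alternative: str = "one-sided",
                     adjust: str = "none") -> pd.DataFrame:
    """Per-class enrichment/depletion of ``members`` within ``universe``.

    Returns a frame indexed by class with columns ``in_set``, ``in_universe``,
    ``odds_ratio``, ``p_enrich``, ``p_deplete``, ``p`` (the direction-
    appropriate one-sided p, or the two-sided p if requested) and
    ``direction``.  Classes absent from the universe are skipped.
    """
    members = list(members)
    universe = list(universe)
    mset = set(members)
    if not mset <= set(universe):
        raise ValueError("members must be a subset of the universe")
    missing = [l for l in universe if l not in classes.index]
    if missing:
        raise ValueError(f"lipids without class annotation: {missing[:5]}")
    cls = classes.loc[universe]
    n_set = len(mset)
    n_uni = len(universe)
    in_set = pd.Series([l in mset for l in universe], index=universe)
    rows = []
    for c in sorted(cls.unique()):
        in_class = cls == c
        a = int((in_set & in_class).sum())        # in set, in class
        b = n_set - a                             # in set, other class
        c_ = int(in_class.sum()) - a              # out of set, in class
        d = n_uni - n_set - c_
        table = [[a, b], [c_, d]]
        p_gr = float(stats.fisher_exact(table, alternative="greater")[1])
        p_ls = float(stats.fisher_exact(table, alternative="less")[1])
        p_two = float(stats.fisher_exact(table, alternative="two-sided")[1])
        odds = math.inf if b * c_ == 0 and a * d > 0 else (
            math.nan if b * c_ == 0 else (a * d) / (b * c_))
        direction = "enriched" if (math.isinf(odds) or odds > 1) else "depleted"
        p = p_two if alternative == "two-sided" else (
            p_gr if direction == "enriched" else p_ls)
        rows.append({"class": c, "in_set": a, "in_universe": a + c_,
                     "odds_ratio": odds, "p_enrich": p_gr, "p_deplete": p_ls,
                     "p": p, "direction": direction})
    out = pd.DataFrame(rows).set_index("class")
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    elif adjust != "none":
        raise ValueError(f"unknown adjust {adjust!r}")
    return out
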