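"""Pseudo-time Granger causality among lipids and the outcome.

Samples are ordered by gestational age (pseudo-time); for a directed
pair x -> y the restricted model regresses y on its own first ``lag``
lags and the unrestricted model adds the lags of x.  The F statistic

    F = ((RSS_r - RSS_u) / lag) / (RSS_u / (T' - 2*lag - 1))

with T' usable observations is compared to the F distribution.  All
ordered pairs among the selected lipids and the binary outcome (treated
as a numeric 0/1 series, a deliberate replication of the published
procedure despite its statistical awkwardness) form the candidate edge
set; edges with p below alpha are kept and mediator patterns (a node
with an inbound lipid edge and an outbound edge to the outcome) are
annotated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import LipidMatrix


def order_pseudotime(clinical: pd.DataFrame,
                     by: str = "gestational_age") -> pd.Index:
    """Sample ids sorted ascending by the ordering variable.

    Ties are broken by the stable input order of sample ids.  A constant
    ordering variable preserves the input order with a warning.
    """
    if by not in clinical.columns:
        raise KeyError(by)
    x = clinical[by]
    if x.isna().any():
        missing = clinical.index[x.isna()].tolist()
        raise ValueError(f"missing {by!r} for samples: {missing}")
    if not np.isfinite(x.to_numpy(dtype=float)).all():
        raise ValueError(f"non-finite {by!r} values")
    if x.nunique() == 1:
        warnings.warn(f"{by!r} is constant; input order preserved")
        return clinical.index
    order = np.argsort(x.to_numpy(), kind="stable")
    return clinical.index[order]


def _lag_matrix(series: np.ndarray, lag: int) -> np.ndarray:
    return np.column_stack([series[lag - j - 1: len(series) - j - 1]
                            for j in range(lag)])


def granger_test(x: np.ndarray, y: np.ndarray, lag: int = 1) -> tuple[float, float]:
    """Test whether ``x`` Granger-causes ``y`` at the given lag.

    Both models include an intercept; the restricted model uses the lags
    of ``y`` only.  Returns ``(F, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("series lengths differ")
    T = len(y)
    if T <= 2 * lag + 2:
        raise ValueError(f"series too short for lag {lag}")
    yt = y[lag:]
    Tp = len(yt)
    Xr = np.column_stack([np.ones(Tp), _lag_matrix(y, lag)])
    Xu = np.column_stack([Xr, _lag_matrix(x, lag)])
    if np.linalg.matrix_rank(Xu) < Xu.shape[1]:
        raise ValueError("perfect collinearity in lagged regressors "
                         "(constant or duplicated series)")
    rss_r = float(np.sum((yt - Xr @ np.linalg.lstsq(Xr, yt, rcond=None)[0]) ** 2))
    rss_u = float(np.sum((yt - Xu @ np.linalg.lstsq(Xu, yt, rcond=None)[0]) ** 2))
    df_denom = Tp - 2 * lag - 1
    if rss_u <= 0:
        raise ValueError("degenerate fit: zero unrestricted residual")
    F = ((rss_r - rss_u) / lag) / (rss_u / df_denom)
    p = float(stats.f.sf(F, lag, df_denom))
    return float(F), p


@dataclass
class CausalGraph:
    """Directed p<alpha Granger edges among lipids and the outcome."""
    nodes: list
    edges: pd.DataFrame            # columns: from, to, lag, F, p
    alpha: float
    lag: int
    mediators: list = field(default_factory=list)

    def adjacency_list(self) -> dict:
        adj = {n: [] for n in self.nodes}
        for _, row in self.edges.iterrows():
            adj[row["from"]].append(row["to"])
        return adj

    def write_edges(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.edges.to_csv(path, sep="\t", index=False)
        return path

    def to_graphml(self, path: str | Path) -> Path:
        import networkx as nx
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["from"], row["to"], F=float(row["F"]),
                       p=float(row["p"]), lag=int(row["lag"]))
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        nx.write_graphml(g, path)
        return path


def causal_graph(matrix: LipidMatrix, clinical: pd.DataFrame, lipids: list,
                 outcome: str = "status", order_by: str = "gestational_age",
                 alpha: float = 0.05, lag: int = 1) -> CausalGraph:
    """All-pairs Granger tests among ``lipids`` and the outcome.

    Tests every ordered pair of series (lipid profiles along pseudo-time
    plus the 0/1 outcome), keeps edges with p below ``alpha``, and
    annotates mediators: nodes with at least one inbound lipid edge and
    an outbound edge to the outcome.
    """
    missing = [l for l in lipids if l not in matrix.lipid_ids]
    if missing:
        raise KeyError(f"lipids not in matrix: {missing}")
    order = order_pseudotime(clinical, by=order_by)
    series = {l: matrix.values.loc[order, l].to_numpy(dtype=float) for l in lipids}
    series[outcome] = clinical.loc[order, outcome].to_numpy(dtype=float)
    nodes = list(lipids) + [outcome]
    rows = []
    for src in nodes:
        for dst in nodes:
            if src == dst:
                continue
            try:
                F, p = granger_test(series[src], series[dst], lag=lag)
            except ValueError:
                continue
            if p < alpha:
                rows.append({"from": src, "to": dst, "lag": lag, "F": F, "p": p})
    edges = pd.DataFrame(rows, columns=["from", "to", "lag", "F", "p"])
    has_out_to_outcome = set(edges.loc[edges["to"] == outcome, "from"])
    mediators = []
    for node in lipids:
        inbound = edges[(edges["to"] == node) & (edges["from"] != outcome)]
        if len(inbound) and node in has_out_to_outcome:
            mediators.append(node)
    return CausalGraph(nodes=nodes, edges=edges, alpha=alpha, lag=lag,
                       mediators=mediators)
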