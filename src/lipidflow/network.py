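"""Condition-specific weighted correlation networks on lipid profiles.

The construction follows the weighted coexpression-network recipe:
unsigned adjacency ``A_ij = |cor(x_i, x_j)|^beta`` with the soft
threshold ``beta`` chosen as the smallest power whose scale-free
topology fit reaches a target R-squared; topological overlap

    TOM_ij = (sum_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 - A_ij)

with connectivity ``k_i = sum_{j != i} A_ij``; modules from
average-linkage hierarchical clustering of ``1 - TOM`` with a fixed-
height candidate cut, a minimum-size filter (small clusters fall into
the unassigned "grey" pool) and eigenlipid-based merging.  Case and
control networks built with a shared ``beta`` have comparable
connectivities, which is what the differential-connectivity rule
(|delta k| > 5) relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._design import build_design, check_full_rank, ols_multi
from .containers import LipidMatrix


@dataclass
class NetworkConfig:
    """Tunable parameters of network construction and module detection."""
    power: int | None = None          # None = pick by scale-free fit
    rsq_cut: float = 0.85
    min_module_size: int = 10
    merge_cut_height: float = 0.25
    cut_height_frac: float = 0.95     # candidate cut, fraction of max merge height
                                      # (intermediate-split preset)
    edge_retention_tom: float = 0.5
    connectivity_delta: float = 5.0

    def __post_init__(self):
        if not 0 < self.rsq_cut < 1:
            raise ValueError("rsq_cut must be in (0, 1)")
        if not 0 <= self.merge_cut_height <= 1:
            raise ValueError("merge_cut_height must be in [0, 1]")


@dataclass
class NetworkModel:
    """One condition's network: adjacency, TOM, connectivity, modules."""
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    connectivity: pd.Series
    beta: int
    modules: pd.Series | None = None          # lipid -> label ("grey" = none)
    eigenlipids: pd.DataFrame | None = None   # samples x modules

    @property
    def lipid_ids(self) -> pd.Index:
        return self.adjacency.index

    def module_members(self, module: str) -> list:
        if self.modules is None:
            raise ValueError("modules not detected yet")
        return self.modules.index[self.modules == module].tolist()


def adjust_for_confounders(matrix: LipidMatrix, clinical: pd.DataFrame,
                           keep: str = "status",
                           confounders: list[str] | None = None) -> LipidMatrix:
    """Regress out everything except ``keep``.

    Per lipid, fit ``keep`` + confounders jointly; the adjusted value is
    the ``keep`` coefficient times the (centered) ``keep`` variable plus
    the residual, i.e. confounder contributions and the intercept are
    removed while the condition effect is preserved.
    """
    clinical = clinical.loc[matrix.sample_ids]
    if confounders is None:
        confounders = [c for c in clinical.columns if c != keep]
    factors = [keep] + [c for c in confounders if c != keep]
    X, blocks, _ = build_design(clinical, factors)
    check_full_rank(X, blocks)
    Y = matrix.values.to_numpy(dtype=float)
    beta, _, _ = ols_multi(X, Y)
    resid = Y - X @ beta
    keep_cols = blocks[keep]
    kept = X[:, keep_cols] - X[:, keep_cols].mean(axis=0)
    adjusted = kept @ beta[keep_cols] + resid
    return matrix.with_values(
        pd.DataFrame(adjusted, index=matrix.sample_ids, columns=matrix.lipid_ids))


def _correlation(values: np.ndarray, lipid_ids: pd.Index) -> np.ndarray:
    sd = values.std(axis=0, ddof=0)
    if (sd == 0).any():
        bad = lipid_ids[sd == 0].tolist()
        raise ValueError(f"zero-variance lipids: {bad}")
    return np.corrcoef(values, rowvar=False)


def scale_free_fit(k: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Signed scale-free topology fit of a connectivity distribution.

    Bins ``k``, regresses ``log10 p(k)`` on ``log10 mean-k`` per bin and
    returns ``(signed_r2, slope)`` where the sign of the R-squared is
    flipped positive only for the decreasing (scale-free-like) direction.
    """
    k = np.asarray(k, dtype=float)
    k = k[k > 0]
    if len(k) < 4:
        return 0.0, 0.0
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    which = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    logk, logp = [], []
    for b in range(n_bins):
        kb = k[which == b]
        if len(kb) == 0:
            continue
        logk.append(np.log10(kb.mean()))
        logp.append(np.log10(len(kb) / len(k)))
    if len(logk) < 3:
        return 0.0, 0.0
    slope, _, r, _, _ = stats.linregress(logk, logp)
    return float(-np.sign(slope) * r ** 2), float(slope)


def pick_soft_threshold(matrix: LipidMatrix, powers=range(1, 21),
                        rsq_cut: float = 0.85) -> int:
    """Smallest power whose signed scale-free fit reaches ``rsq_cut``.

    Zero-variance lipids are excluded with a warning.  If no candidate
    reaches the cut, the power with the best fit is returned with a
    warning.
    """
    values = matrix.values.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=0)
    if (sd == 0).any():
        warnings.warn(f"excluding {int((sd == 0).sum())} zero-variance lipids")
        values = values[:, sd > 0]
    absr = np.abs(np.corrcoef(values, rowvar=False))
    np.fill_diagonal(absr, 0.0)
    best_power, best_fit = None, -np.inf
    for b in powers:
        k = (absr ** b).sum(axis=0)
        fit, _ = scale_free_fit(k)
        if fit >= rsq_cut:
            return int(b)
        if fit > best_fit:
            best_power, best_fit = int(b), fit
    warnings.warn(
        f"no power reached scale-free fit {rsq_cut}; using power "
        f"{best_power} (fit {best_fit:.3f})")
    return best_power


def build_network(matrix: LipidMatrix, beta: int) -> NetworkModel:
    """Unsigned adjacency, topological overlap and connectivity."""
    values = matrix.values.to_numpy(dtype=float)
    r = _correlation(values, matrix.lipid_ids)
    A = np.abs(r) ** beta
    np.fill_diagonal(A, 1.0)
    k = A.sum(axis=0) - 1.0
    # sum over u != i,j of A_iu A_uj; diag(A)=1 contributes A_ij twice
    L = A @ A - 2.0 * A
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (L + A) / (kmin + 1.0 - A)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    ids = matrix.lipid_ids
    return NetworkModel(
        adjacency=pd.DataFrame(A, index=ids, columns=ids),
        tom=pd.DataFrame(tom, index=ids, columns=ids),
        connectivity=pd.Series(k, index=ids, name="connectivity"),
        beta=int(beta))


def _eigenlipid(values: np.ndarray) -> np.ndarray:
    """First principal-component score of standardized member profiles,
    oriented so its mean correlation with the members is positive."""
    z = (values - values.mean(axis=0)) / values.std(axis=0, ddof=0)
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    score = u[:, 0] * s[0]
    cors = np.array([np.corrcoef(score, z[:, j])[0, 1] for j in range(z.shape[1])])
    if cors.mean() < 0:
        score = -score
    return score


def detect_modules(network: NetworkModel, matrix: LipidMatrix,
                   config: NetworkConfig | None = None) -> pd.Series:
    """Average-linkage clustering of ``1 - TOM`` into labelled modules.

    Candidate clusters come from cutting the dendrogram at a fixed
    fraction of its maximum merge height; clusters below the minimum size
    are pooled into "grey"; modules whose eigenlipids are closer than the
    merge cut height (correlation distance) are merged.  Labels are
    deterministic, ordered by module size (``M1`` largest).
    """
    config = config or NetworkConfig()
    ids = network.lipid_ids
    dist = 1.0 - network.tom.to_numpy()
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    cut = config.cut_height_frac * link[:, 2].max()
    labels = hierarchy.fcluster(link, t=cut, criterion="distance")

    values = matrix.values[ids].to_numpy(dtype=float)
    groups = {}
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) >= config.min_module_size:
            groups[len(groups)] = list(members)

    # eigenlipid merge: closest pair first, until all pairs are farther
    # apart than the merge cut height
    def eig(members):
        return _eigenlipid(values[:, members])

    merged = True
    while merged and len(groups) > 1:
        merged = False
        keys = list(groups)
        eigs = {g: eig(groups[g]) for g in keys}
        best = (None, None, np.inf)
        for i, gi in enumerate(keys):
            for gj in keys[i + 1:]:
                d = 1.0 - np.corrcoef(eigs[gi], eigs[gj])[0, 1]
                if d < best[2]:
                    best = (gi, gj, d)
        if best[2] < config.merge_cut_height:
            gi, gj, _ = best
            groups[gi] = groups[gi] + groups.pop(gj)
            merged = True

    if not groups:
        warnings.warn("no module reached the minimum size; all lipids grey")
    assignment = pd.Series("grey", index=ids, name="module")
    ordered = sorted(groups.values(), key=len, reverse=True)
    eigenframe = {}
    for rank, members in enumerate(ordered, start=1):
        label = f"M{rank}"
        assignment.iloc[members] = label
        eigenframe[label] = eig(members)
    network.modules = assignment
    network.eigenlipids = pd.DataFrame(eigenframe, index=matrix.sample_ids) \
        if eigenframe else pd.DataFrame(index=matrix.sample_ids)
    return assignment


def module_density(network: NetworkModel, module: str) -> float:
    """Mean off-diagonal topological overlap among module members."""
    members = network.module_members(module)
    if len(members) == 0:
        raise ValueError(f"module {module!r} is empty")
    if len(members) == 1:
        raise ValueError(f"module {module!r} is a singleton; density undefined")
    sub = network.tom.loc[members, members].to_numpy()
    n = len(members)
    return float((sub.sum() - n) / (n * (n - 1)))


def connectivity_diff(net_case: NetworkModel, net_ctrl: NetworkModel,
                      delta: float = 5.0) -> tuple[list, list, pd.Series]:
    """Lipids with case-minus-control connectivity above ``delta`` /
    below ``-delta``; also returns the full delta-k series."""
    if not net_case.lipid_ids.equals(net_ctrl.lipid_ids):
        raise ValueError("networks cover different lipid sets")
    dk = net_case.connectivity - net_ctrl.connectivity
    increased = dk.index[dk > delta].tolist()
    decreased = dk.index[dk < -delta].tolist()
    return increased, decreased, dk.rename("delta_k")


def module_overlap(modules_a: pd.Series, modules_b: pd.Series) -> pd.DataFrame:
    """Joint-membership counts and one-sided Fisher enrichment p per
    module pair (grey excluded as a module of interest)."""
    if not modules_a.index.equals(modules_b.index):
        raise ValueError("partitions cover different lipid universes")
    n = len(modules_a)
    rows = []
    for ma in sorted(set(modules_a) - {"grey"}):
        in_a = modules_a == ma
        for mb in sorted(set(modules_b) - {"grey"}):
            in_b = modules_b == mb
            both = int((in_a & in_b).sum())
            a_only = int(in_a.sum()) - both
            b_only = int(in_b.sum()) - both
            rest = n - both - a_only - b_only
            p = float(stats.fisher_exact([[both, a_only], [b_only, rest]],
                                         alternative="greater")[1])
            rows.append({"module_a": ma, "module_b": mb,
                         "overlap": both, "p": p})
    return pd.DataFrame(rows)


def module_trait_association(network: NetworkModel, trait: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each module eigenlipid with a numeric or
    0/1 trait, with a two-sided t-based p at n-2 degrees of freedom."""
    if network.eigenlipids is None:
        raise ValueError("modules not detected yet")
    t = pd.to_numeric(trait.loc[network.eigenlipids.index], errors="raise")
    if t.nunique() <= 1:
        raise ValueError("constant trait")
    n = len(t)
    rows = []
    for module in network.eigenlipids.columns:
        r = float(np.corrcoef(network.eigenlipids[module], t)[0, 1])
        tt = r * np.sqrt((n - 2) / max(1e-12, 1 - r ** 2))
        p = 2.0 * float(stats.t.sf(abs(tt), n - 2))
        rows.append({"module": module, "correlation": r, "p": p})
    return pd.DataFrame(rows).set_index("module")


def edge_list(network: NetworkModel, tom_cut: float = 0.5) -> pd.DataFrame:
    """Upper-triangle TOM edges retained above ``tom_cut``."""
    tom = network.tom.to_numpy()
    ids = network.lipid_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    keep = tom[iu, ju] > tom_cut
    return pd.DataFrame({"lipid_i": ids[iu[keep]], "lipid_j": ids[ju[keep]],
                         "tom": tom[iu[keep], ju[keep]]})


def to_graphml(network: NetworkModel, path: str | Path,
               tom_cut: float = 0.5) -> Path:
    import networkx as nx
    g = nx.Graph()
    for lip in network.lipid_ids:
        g.add_node(str(lip), connectivity=float(network.connectivity[lip]),
                   module=str(network.modules[lip]) if network.modules is not None else "")
    for _, row in edge_list(network, tom_cut).iterrows():
        g.add_edge(str(row["lipid_i"]), str(row["lipid_j"]), tom=float(row["tom"]))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(g, path)
    return path
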