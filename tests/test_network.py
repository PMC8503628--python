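"""Weighted correlation networks: adjacency, TOM, modules, delta-k."""

import numpy as np
import pandas as pd
import pytest

from lipidflow import network as nm
from lipidflow.simulate import ModuleSpec, SimConfig, simulate_cohort
from conftest import toy_matrix


def hand_tom(A: np.ndarray) -> np.ndarray:
    """Term-by-term oracle for the topological overlap formula."""
    p = A.shape[0]
    k = A.sum(axis=0) - 1.0
    out = np.eye(p)
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(p)
                         if u not in (i, j))
            out[i, j] = (shared + A[i, j]) / (min(k[i], k[j]) + 1 - A[i, j])
    return out


def log_cohort(cfg):
    m, clin, truth = simulate_cohort(cfg)
    return m.with_values(np.log2(m.values), scale_state="log"), clin, truth


class TestBuildNetwork:
    def test_two_identical_lipids(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        net = nm.build_network(toy_matrix(np.column_stack([x, x])), beta=4)
        assert net.adjacency.iloc[0, 1] == pytest.approx(1.0)
        assert net.tom.iloc[0, 1] == pytest.approx(1.0)

    def test_tom_matches_hand_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 4))
        X[:, 1] += 0.8 * X[:, 0]
        X[:, 3] += 0.5 * X[:, 2]
        net = nm.build_network(toy_matrix(X), beta=2)
        np.testing.assert_allclose(net.tom.to_numpy(),
                                   hand_tom(net.adjacency.to_numpy()),
                                   rtol=1e-10)

    def test_null_mean_adjacency_matches_expected_abs_correlation(self):
        # |r| of independent normals; empirical oracle at the same n
        rng = np.random.default_rng(2)
        n = 50
        net = nm.build_network(toy_matrix(rng.normal(size=(n, 60))), beta=1)
        A = net.adjacency.to_numpy()
        observed = A[np.triu_indices_from(A, k=1)].mean()
        sims = []
        for _ in range(400):
            x, y = rng.normal(size=(2, n))
            sims.append(abs(np.corrcoef(x, y)[0, 1]))
        assert observed == pytest.approx(np.mean(sims), abs=0.02)

    def test_symmetry_and_range(self, small_cohort):
        matrix, _, _ = small_cohort
        logm = matrix.with_values(np.log2(matrix.values), scale_state="log")
        net = nm.build_network(logm, beta=4)
        A, T = net.adjacency.to_numpy(), net.tom.to_numpy()
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        np.testing.assert_allclose(T, T.T, atol=1e-10)
        assert ((A >= 0) & (A <= 1)).all() and ((T >= 0) & (T <= 1)).all()
        np.testing.assert_allclose(np.diag(A), 1.0)

    def test_connectivity_monotone_in_power(self, small_cohort):
        matrix, _, _ = small_cohort
        logm = matrix.with_values(np.log2(matrix.values), scale_state="log")
        k_prev = None
        for beta in (1, 2, 4, 8):
            k = nm.build_network(logm, beta).connectivity
            if k_prev is not None:
                assert (k <= k_prev + 1e-9).all()
            k_prev = k

    def test_zero_variance_lipid_named(self):
        X = np.random.default_rng(3).normal(size=(20, 3))
        X[:, 1] = 2.5
        with pytest.raises(ValueError, match="L1"):
            nm.build_network(toy_matrix(X), beta=4)


class TestSoftThreshold:
    def test_zero_cut_returns_smallest_power(self, small_cohort):
        matrix, _, _ = small_cohort
        logm = matrix.with_values(np.log2(matrix.values), scale_state="log")
        assert nm.pick_soft_threshold(logm, rsq_cut=1e-6) == 1

    def test_noise_matrix_exercises_warning_path(self):
        rng = np.random.default_rng(4)
        m = toy_matrix(rng.normal(size=(30, 40)))
        with pytest.warns(UserWarning, match="no power"):
            nm.pick_soft_threshold(m, rsq_cut=0.99)

    def test_selection_stable_across_seeds(self):
        # hub-and-spoke loadings give a broad, scale-free-ish degree
        # distribution for which the fit criterion is attainable
        picks = []
        for s in range(8):
            rng = np.random.default_rng(800 + s)
            n, p = 64, 150
            hubs = rng.normal(size=(n, 4))
            load = rng.uniform(0.2, 0.8, size=p)
            which = rng.integers(0, 4, size=p)
            X = (load * hubs[:, which]
                 + np.sqrt(1 - load ** 2) * rng.normal(size=(n, p)))
            picks.append(nm.pick_soft_threshold(toy_matrix(X)))
        mode = max(set(picks), key=picks.count)
        assert picks.count(mode) >= 3
        assert max(picks) - min(picks) <= 4


class TestModules:
    @pytest.fixture(scope="class")
    def planted(self):
        cfg = SimConfig(n_lipids=80,
                        modules=[ModuleSpec(20, 0.8, 0.8),
                                 ModuleSpec(20, 0.8, 0.8)],
                        effect_lipids=[], causal_chain=[],
                        causal_coefficients=[], missing_rate=0, seed=404)
        logm, clin, truth = log_cohort(cfg)
        net = nm.build_network(logm, 4)
        nm.detect_modules(net, logm)
        return logm, net, truth

    def test_planted_blocks_recovered(self, planted):
        logm, net, truth = planted
        labels = set(net.modules) - {"grey"}
        assert len(labels) == 2
        for mod in ("module_0", "module_1"):
            members = {l for l, t in truth.true_modules.items() if t == mod}
            best = max(len(members & set(net.modules.index[net.modules == lab]))
                       for lab in labels)
            assert best >= 18     # >= 90% of a 20-lipid block

    def test_oversized_min_module_all_grey(self, planted):
        logm, net, _ = planted
        with pytest.warns(UserWarning, match="grey"):
            mods = nm.detect_modules(net, logm,
                                     nm.NetworkConfig(min_module_size=500))
        assert (mods == "grey").all()

    def test_zero_merge_height_keeps_collinear_blocks_apart(self):
        # two blocks driven by the same latent factor merge by default
        rng = np.random.default_rng(5)
        latent = rng.normal(size=60)
        X = np.column_stack([
            np.column_stack([latent + rng.normal(scale=0.5, size=60)
                             for _ in range(12)]),
            np.column_stack([latent + rng.normal(scale=0.55, size=60)
                             for _ in range(12)]),
        ])
        m = toy_matrix(X)
        net = nm.build_network(m, 4)
        merged = nm.detect_modules(net, m, nm.NetworkConfig(
            min_module_size=5, cut_height_frac=0.5))
        unmerged = nm.detect_modules(net, m, nm.NetworkConfig(
            min_module_size=5, cut_height_frac=0.5, merge_cut_height=0.0))
        assert unmerged.nunique() >= merged.nunique()

    def test_density_of_identical_lipids_is_one(self):
        # mutually identical profiles: adjacency and TOM are exactly one
        rng = np.random.default_rng(6)
        x = rng.normal(size=40)
        m = toy_matrix(np.column_stack([x] * 12))
        net = nm.build_network(m, 4)
        nm.detect_modules(net, m)
        module = net.modules.iloc[0]
        assert module != "grey"
        assert nm.module_density(net, module) == pytest.approx(1.0, abs=1e-9)

    def test_density_ordering_tracks_planted_correlation(self):
        cfg = SimConfig(n_lipids=60,
                        modules=[ModuleSpec(15, 0.8, 0.8),
                                 ModuleSpec(15, 0.4, 0.4)],
                        effect_lipids=[], causal_chain=[],
                        causal_coefficients=[], seed=901)
        logm, _, truth = log_cohort(cfg)
        net = nm.build_network(logm, 4)
        ids = net.lipid_ids
        tight = [l for l in ids if truth.true_modules[l] == "module_0"]
        loose = [l for l in ids if truth.true_modules[l] == "module_1"]
        net.modules = pd.Series("grey", index=ids)
        net.modules[tight] = "T"
        net.modules[loose] = "L"
        assert nm.module_density(net, "T") > nm.module_density(net, "L")

    def test_singleton_module_density_undefined(self, planted):
        _, net, _ = planted
        net.modules.iloc[-1] = "lonely"
        with pytest.raises(ValueError, match="singleton"):
            nm.module_density(net, "lonely")


class TestConnectivityDiff:
    def test_identical_networks_give_empty_lists(self, small_cohort):
        matrix, _, _ = small_cohort
        logm = matrix.with_values(np.log2(matrix.values), scale_state="log")
        net = nm.build_network(logm, 4)
        inc, dec, dk = nm.connectivity_diff(net, net, 5.0)
        assert inc == [] and dec == []
        assert (dk == 0).all()

    def test_infinite_delta_empty(self, small_cohort):
        matrix, clinical, _ = small_cohort
        logm = matrix.with_values(np.log2(matrix.values), scale_state="log")
        a = nm.build_network(logm.subset_samples(clinical.index[:40]), 4)
        b = nm.build_network(logm.subset_samples(clinical.index[24:]), 4)
        inc, dec, _ = nm.connectivity_diff(a, b, np.inf)
        assert inc == [] and dec == []

    def test_rewired_block_lands_in_increased_list(self):
        cfg = SimConfig(n_lipids=200, modules=[ModuleSpec(30, 0.8, 0.3)],
                        effect_lipids=[], causal_chain=[],
                        causal_coefficients=[], seed=902)
        logm, clin, truth = log_cohort(cfg)
        case = nm.build_network(logm.subset_samples(clin.index[clin.status == 1]), 4)
        ctrl = nm.build_network(logm.subset_samples(clin.index[clin.status == 0]), 4)
        inc, _, _ = nm.connectivity_diff(case, ctrl, 5.0)
        block = {l for l, t in truth.true_modules.items() if t == "module_0"}
        assert len(block & set(inc)) / len(block) >= 0.8
        background = set(logm.lipid_ids) - block
        assert len(background & set(inc)) / len(background) <= 0.05

    def test_mismatched_lipid_sets_rejected(self, small_cohort):
        matrix, _, _ = small_cohort
        logm = matrix.with_values(np.log2(matrix.values), scale_state="log")
        a = nm.build_network(logm, 4)
        b = nm.build_network(logm.subset_lipids(logm.lipid_ids[:50]), 4)
        with pytest.raises(ValueError, match="different lipid sets"):
            nm.connectivity_diff(a, b)


class TestOverlapAndTraits:
    def test_identical_partitions_diagonal_overlap(self):
        ids = [f"L{j}" for j in range(40)]
        part = pd.Series(["A"] * 20 + ["B"] * 20, index=ids)
        out = nm.module_overlap(part, part)
        diag = out[out.module_a == out.module_b]
        off = out[out.module_a != out.module_b]
        assert (off["overlap"] == 0).all()
        assert (diag["p"] < 1e-6).all()

    def test_relabeling_preserves_overlap_counts(self):
        ids = [f"L{j}" for j in range(30)]
        part = pd.Series(["A"] * 10 + ["B"] * 10 + ["grey"] * 10, index=ids)
        relabeled = part.map({"A": "X", "B": "Y", "grey": "grey"})
        a = nm.module_overlap(part, relabeled)
        assert sorted(a["overlap"]) == sorted(nm.module_overlap(part, part)["overlap"])

    def test_trait_equal_to_members_gives_unit_correlation(self):
        rng = np.random.default_rng(7)
        trait = rng.normal(size=50)
        X = np.column_stack([trait + rng.normal(scale=0.01, size=50)
                             for _ in range(12)]
                            + [rng.normal(size=50) for _ in range(20)])
        m = toy_matrix(X)
        net = nm.build_network(m, 4)
        nm.detect_modules(net, m)
        assoc = nm.module_trait_association(
            net, pd.Series(trait, index=m.sample_ids))
        assert assoc["correlation"].abs().max() > 0.99
        # eigenlipid orientation makes the association positive
        assert assoc["correlation"].max() > 0.99

    def test_constant_trait_rejected(self, small_cohort):
        matrix, _, _ = small_cohort
        logm = matrix.with_values(np.log2(matrix.values), scale_state="log")
        net = nm.build_network(logm, 4)
        nm.detect_modules(net, logm)
        with pytest.raises(ValueError, match="constant"):
            nm.module_trait_association(
                net, pd.Series(1.0, index=logm.sample_ids))


class TestAdjustForConfounders:
    def test_keep_only_returns_centered_values(self, small_cohort):
        matrix, clinical, _ = small_cohort
        logm = matrix.with_values(np.log2(matrix.values), scale_state="log")
        out = nm.adjust_for_confounders(logm, clinical[["status"]], "status",
                                        confounders=[])
        centered = logm.values - logm.values.mean(axis=0)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   centered.to_numpy(), atol=1e-9)

    def test_pure_confounder_signal_removed(self):
        rng = np.random.default_rng(8)
        idx = [f"s{i}" for i in range(64)]
        clin = pd.DataFrame({"status": [1] * 44 + [0] * 20,
                             "ga": rng.normal(37, 2, 64)}, index=idx)
        X = np.column_stack([2.0 * clin["ga"].to_numpy(),
                             rng.normal(size=64)])
        out = nm.adjust_for_confounders(toy_matrix(X, sample_ids=idx), clin,
                                        "status")
        assert out.values.iloc[:, 0].std() < 0.2 * X[:, 0].std()

    def test_status_effect_preserved(self):
        deltas = []
        for s in range(40):
            rng = np.random.default_rng(100 + s)
            idx = [f"s{i}" for i in range(64)]
            status = np.array([1] * 44 + [0] * 20)
            ga = rng.normal(37, 2, 64) - status * 2
            y = 1.0 * status + 0.3 * ga + rng.normal(size=64)
            clin = pd.DataFrame({"status": status, "ga": ga}, index=idx)
            out = nm.adjust_for_confounders(
                toy_matrix(y[:, None], sample_ids=idx), clin, "status")
            v = out.values.iloc[:, 0]
            deltas.append(v[status == 1].mean() - v[status == 0].mean())
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert np.mean(deltas) == pytest.approx(1.0, abs=2 * se + 0.05)
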