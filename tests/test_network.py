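"""Profile alignment, shrinkage GGM, edge selection, MCODE and transfer.

Statistical behavior is checked against data simulated from known sparse
precision matrices, so recall/FDR assertions compare against exact planted
truth rather than against a reference implementation.
"""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from ms2deep import (AlignParams, AssociationNetwork, Cluster, FeatureRecord,
                     MCODEParams, MS2TEntry, NetworkEdge, align_profiles,
                     estimate_pcor, fit_null_and_probabilities, mcode_cluster,
                     normalize_profiles, permutation_null_probabilities,
                     random_sparse_precision, select_edges, simulate_profiles,
                     transfer_annotations)


def feat(fid, mz, rt, mode="positive", area=1e6):
    return FeatureRecord(id=fid, ion_mode=mode, mz=mz, rt=rt,
                         areas={"s1": area}, classes={"s1": "sample"})


# ---------------------------------------------------------------------------
# Alignment and normalization


class TestAlignProfiles:
    def library(self):
        return [MS2TEntry.from_feature(feat("L1", 300.0, 2.0)),
                MS2TEntry.from_feature(feat("L2", 300.0, 3.0))]

    def test_match_within_windows(self):
        prof = align_profiles({"A": [feat("x", 300.0000, 2.05, area=5e5)]},
                              self.library())
        assert prof.loc["A", "L1"] == pytest.approx(5e5)
        assert prof.loc["A", "L2"] == 0.0

    def test_rt_gap_beyond_tolerance_unassigned(self):
        prof = align_profiles({"A": [feat("x", 300.0, 2.4, area=5e5)]},
                              self.library(), AlignParams(rt_tol=0.35))
        assert prof.loc["A"].sum() == 0.0

    def test_nearer_rt_wins_over_smaller_ppm(self):
        lib = [MS2TEntry.from_feature(feat("near", 300.0009, 2.00)),
               MS2TEntry.from_feature(feat("far", 300.0000, 2.30))]
        prof = align_profiles({"A": [feat("x", 300.0, 2.05, area=1e6)]},
                              lib, AlignParams(rt_tol=0.35, mz_tol_ppm=5.0))
        assert prof.loc["A", "near"] == pytest.approx(1e6)
        assert prof.loc["A", "far"] == 0.0

    def test_mode_mismatch_never_assigned(self):
        lib = [MS2TEntry.from_feature(feat("L1n", 300.0, 2.0, mode="negative"))]
        prof = align_profiles({"A": [feat("x", 300.0, 2.0)]}, lib)
        assert prof.loc["A"].sum() == 0.0


class TestNormalizeProfiles:
    def base_areas(self):
        idx = ["ref1", "i1", "i2", "ref2", "i3", "i4", "ref3"]
        rng = np.random.default_rng(41)
        return pd.DataFrame(rng.uniform(1e5, 1e6, size=(7, 4)), index=idx,
                            columns=[f"F{k}" for k in range(4)])

    def test_doubling_internal_standard_halves_profile(self):
        areas = self.base_areas()
        is1 = pd.Series(1.0, index=areas.index)
        out1 = normalize_profiles(areas, is1, reference_runs=["ref1", "ref2", "ref3"])
        out2 = normalize_profiles(areas, 2 * is1, reference_runs=["ref1", "ref2", "ref3"])
        # log2 of a halved matrix differs by ~1 everywhere (up to the eps term)
        diff = (out1 - out2).to_numpy()
        assert np.allclose(diff, 1.0, atol=0.01)

    def test_linear_drift_removed_from_reference_runs(self):
        idx = [f"r{i}" if i % 3 == 0 else f"s{i}" for i in range(13)]
        refs = [x for x in idx if x.startswith("r")]
        base = np.ones((13, 3)) * 1e5
        drift = np.linspace(1.0, 2.0, 13)[:, None]   # 2x drift over the run
        areas = pd.DataFrame(base * drift, index=idx, columns=list("abc"))
        is_ = pd.Series(1.0, index=idx)
        # undo the log to inspect the normalized reference areas directly
        norm = 2.0 ** normalize_profiles(areas.loc[idx], is_, reference_runs=[])
        rsd_raw = areas.loc[refs].std() / areas.loc[refs].mean()
        assert (rsd_raw > 0.2).all()
        corrected = normalize_profiles(areas, is_, reference_runs=refs)
        # after drift correction biological injections are flat per feature
        vals = 2.0 ** corrected
        rsd = vals.std() / vals.mean()
        assert (rsd < 0.05).all()

    def test_replicate_averaging(self):
        areas = pd.DataFrame({"F0": [2.0, 4.0, 8.0]}, index=["a1", "a2", "b1"])
        is_ = pd.Series(1.0, index=areas.index)
        out = normalize_profiles(areas, is_, reference_runs=[],
                                 replicates={"a1": "A", "a2": "A", "b1": "B"})
        assert list(out.index) == ["A", "B"]
        eps = 1.5   # half the smallest nonzero replicate-averaged value (3.0)
        assert out.loc["A", "F0"] == pytest.approx(np.log2(3.0 + eps))
        assert out.loc["B", "F0"] == pytest.approx(np.log2(8.0 + eps))

    def test_zero_internal_standard_rejected(self):
        areas = self.base_areas()
        is_ = pd.Series(1.0, index=areas.index)
        is_.iloc[2] = 0.0
        with pytest.raises(ValueError, match="internal standard"):
            normalize_profiles(areas, is_, reference_runs=["ref1"])


# ---------------------------------------------------------------------------
# Shrinkage partial correlations


class TestEstimatePcor:
    def test_two_features_closed_form(self):
        rng = np.random.default_rng(50)
        x = rng.normal(size=300)
        y = 0.6 * x + 0.8 * rng.normal(size=300)
        m = pd.DataFrame({"x": x, "y": y})
        res = estimate_pcor(m)
        r = np.corrcoef(x, y)[0, 1]
        # with p = 2 the partial correlation is the shrunk correlation itself
        assert res.pcor.loc["x", "y"] == pytest.approx((1 - res.lam) * r, abs=1e-10)
        assert 0.0 <= res.lam <= 1.0

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(51)
        m = pd.DataFrame(rng.normal(size=(60, 8)))
        P = estimate_pcor(m).pcor.to_numpy()
        assert np.allclose(P, P.T)
        assert np.allclose(np.diag(P), 1.0)

    def test_independent_features_near_zero(self):
        rng = np.random.default_rng(52)
        m = pd.DataFrame(rng.normal(size=(500, 10)))
        P = estimate_pcor(m).pcor.to_numpy()
        off = P[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 0.15

    def test_planted_signs_recovered(self):
        rng = np.random.default_rng(53)
        omega, true_pcor = random_sparse_precision(30, 20, rng)
        X, _ = simulate_profiles(omega, n=200, seed=54)
        P = estimate_pcor(X).pcor.to_numpy()
        ii, jj = np.where(np.triu(np.abs(true_pcor), k=1) >= 0.3)
        assert len(ii) == 20
        for i, j in zip(ii, jj):
            assert np.sign(P[i, j]) == np.sign(true_pcor[i, j])

    def test_constant_column_rejected(self):
        m = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "b": [5.0] * 4})
        with pytest.raises(ValueError, match="constant"):
            estimate_pcor(m)

    def test_too_few_samples_rejected(self):
        m = pd.DataFrame(np.random.default_rng(0).normal(size=(2, 4)))
        with pytest.raises(ValueError, match="samples"):
            estimate_pcor(m)


# ---------------------------------------------------------------------------
# Null fit and edge probabilities


def planted_run(seed, p=30, n_edges=20, n=200):
    rng = np.random.default_rng(seed)
    omega, true_pcor = random_sparse_precision(p, n_edges, rng)
    X, _ = simulate_profiles(omega, n=n, seed=seed + 1000)
    res = estimate_pcor(X)
    _, edges = fit_null_and_probabilities(res)
    truth = {tuple(sorted((f"F{i:03d}", f"F{j:03d}")))
             for i, j in zip(*np.where(np.triu(np.abs(true_pcor), k=1) >= 0.3))}
    return edges, truth


class TestEdgeProbabilities:
    def test_probability_monotone_in_abs_pcor(self):
        edges, _ = planted_run(seed=60)
        ordered = sorted(edges, key=lambda e: abs(e.pcor))
        probs = [e.probability for e in ordered]
        assert all(b >= a - 1e-12 for a, b in zip(probs, probs[1:]))
        assert all(0.0 <= p <= 1.0 for p in probs)

    def test_pure_null_rarely_confident(self):
        spurious = total = 0
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            X = pd.DataFrame(rng.normal(size=(200, 30)),
                             columns=[f"F{i:03d}" for i in range(30)])
            _, edges = fit_null_and_probabilities(estimate_pcor(X))
            spurious += sum(e.probability > 0.99 for e in edges)
            total += len(edges)
        assert spurious / total <= 0.01

    def test_planted_edges_recovered_with_low_fdr(self):
        kept_true = kept_false = missed = 0
        for seed in range(20):
            edges, truth = planted_run(seed=800 + seed)
            kept = {tuple(sorted((e.a, e.b))) for e in edges
                    if e.probability > 0.99}
            kept_true += len(kept & truth)
            kept_false += len(kept - truth)
            missed += len(truth - kept)
        fdr = kept_false / max(kept_true + kept_false, 1)
        recall = kept_true / (kept_true + missed)
        assert fdr <= 0.10
        assert recall >= 0.80

    def test_eta0_near_one_under_null(self):
        rng = np.random.default_rng(61)
        X = pd.DataFrame(rng.normal(size=(200, 30)))
        null, _ = fit_null_and_probabilities(estimate_pcor(X))
        # truncated ML is somewhat biased; under a pure null eta0 should still
        # attribute the bulk of the mixture to the null component
        assert 0.7 <= null.eta0 <= 1.0
        assert null.kappa > 3.0

    def test_null_density_integrates_to_one(self):
        from ms2deep import GGMNullModel
        null = GGMNullModel(kappa=50.0, eta0=1.0)
        grid = np.linspace(-0.999, 0.999, 20001)
        assert np.trapezoid(null.density(grid), grid) == pytest.approx(1.0, abs=1e-3)

    def test_full_shrinkage_yields_zero_probabilities(self):
        # 3 samples of 30 features: the analytic lambda saturates at 1
        rng = np.random.default_rng(62)
        X = pd.DataFrame(rng.normal(size=(3, 30)))
        res = estimate_pcor(X)
        if res.lam == 1.0:
            null, edges = fit_null_and_probabilities(res)
            assert all(e.probability == 0.0 for e in edges)
            assert null.eta0 == 1.0

    def test_permutation_null_agrees_on_planted_edges(self):
        rng = np.random.default_rng(63)
        omega, true_pcor = random_sparse_precision(15, 8, rng)
        X, _ = simulate_profiles(omega, n=300, seed=64)
        res = estimate_pcor(X)
        edges = permutation_null_probabilities(X, res, rounds=20, seed=65)
        truth = {tuple(sorted((f"F{i:03d}", f"F{j:03d}")))
                 for i, j in zip(*np.where(np.triu(np.abs(true_pcor), k=1) >= 0.3))}
        kept = {tuple(sorted((e.a, e.b))) for e in edges if e.probability > 0.99}
        assert len(kept & truth) / len(truth) >= 0.8


class TestSelectEdges:
    def test_threshold_is_strict(self):
        edges = [NetworkEdge("a", "b", 0.5, 0.99),
                 NetworkEdge("b", "c", 0.5, 0.991)]
        net = select_edges(edges, threshold=0.99)
        assert set(net.graph.edges) == {("b", "c")}

    def test_isolated_features_reported(self):
        edges = [NetworkEdge("a", "b", 0.5, 1.0)]
        net = select_edges(edges, all_features=["a", "b", "c", "d"])
        assert net.isolated == ("c", "d")


# ---------------------------------------------------------------------------
# MCODE and annotation transfer


class TestMCODE:
    def test_clique_with_pendant_path(self):
        G = nx.complete_graph(5)
        nx.add_path(G, [4, 10, 11, 12])
        clusters = mcode_cluster(G)
        assert set(clusters[0].members) == set(range(5))
        assert clusters[0].density == pytest.approx(1.0)
        assert clusters[0].score == pytest.approx(5.0)

    def test_two_cliques_ranked_by_score(self):
        G = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(4))
        clusters = mcode_cluster(G)
        assert [len(c.members) for c in clusters] == [6, 4]
        assert clusters[0].score > clusters[1].score

    def test_haircut_removes_degree_one_member(self):
        G = nx.complete_graph(4)
        G.add_edge(3, 99)   # pendant vertex off the clique
        clusters = mcode_cluster(G)
        assert 99 not in clusters[0].members

    def test_no_dense_region_no_cluster(self):
        assert mcode_cluster(nx.path_graph(6)) == []
        assert mcode_cluster(nx.Graph()) == []

    def test_node_relabelling_preserves_partition(self):
        G = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(4))
        nx.add_path(G, [0, 20, 21, 5])
        mapping = {v: f"N{(v * 7) % 97:02d}" for v in G.nodes}
        H = nx.relabel_nodes(G, mapping)
        part_g = [frozenset(mapping[v] for v in c.members) for c in mcode_cluster(G)]
        part_h = [frozenset(c.members) for c in mcode_cluster(H)]
        assert part_g == part_h


class TestTransferAnnotations:
    def toy(self):
        G = nx.Graph([("u", "a"), ("u", "b"), ("u", "c"), ("a", "b"),
                      ("b", "c"), ("v", "a"), ("w", "x")])
        cluster = ["u", "v", "a", "b", "c"]
        return G, cluster

    def test_majority_class_assigned(self):
        G, cluster = self.toy()
        classes = {"a": "flavonoid", "b": "flavonoid", "c": "lipid"}
        out = transfer_annotations(G, cluster, classes)
        assert out["u"] == ("flavonoid",)

    def test_tie_reports_all_classes(self):
        G, cluster = self.toy()
        classes = {"a": "flavonoid", "c": "lipid"}
        out = transfer_annotations(G, cluster, classes)
        assert out["u"] == ("flavonoid", "lipid")

    def test_no_annotated_neighbour_empty(self):
        G, cluster = self.toy()
        out = transfer_annotations(G, cluster + ["w"], {"b": "flavonoid"})
        assert out["w"] == ()

    def test_neighbours_outside_cluster_ignored(self):
        G, cluster = self.toy()
        classes = {"a": "flavonoid"}
        out = transfer_annotations(G, ["v"], classes)   # a not in cluster
        assert out["v"] == ()


# ---------------------------------------------------------------------------
# End-to-end: planted modules through pcor -> probabilities -> MCODE


def block_clique_precision(sizes, rho=0.32, p_total=None):
    """Precision with one fully connected module per size (pcor = rho);
    remaining features up to ``p_total`` are independent null background.
    The background matters: the empirical-Bayes null is fitted on the central
    bulk of partial correlations, so most pairs must be null."""
    p = p_total if p_total is not None else sum(sizes)
    omega = np.eye(p)
    start = 0
    blocks = []
    for s in sizes:
        idx = list(range(start, start + s))
        for i in idx:
            for j in idx:
                if i != j:
                    omega[i, j] = -rho
        blocks.append(idx)
        start += s
    return omega, blocks


def test_planted_modules_recovered_end_to_end():
    omega, blocks = block_clique_precision([4, 4], rho=0.32, p_total=30)
    X, _ = simulate_profiles(omega, n=400, seed=71)
    _, edges = fit_null_and_probabilities(estimate_pcor(X))
    net = select_edges(edges, threshold=0.99, all_features=list(X.columns))
    clusters = mcode_cluster(net)
    planted = [frozenset(f"F{i:03d}" for i in b) for b in blocks]
    assert len(clusters) >= 2
    for module in planted:
        best = max(len(module & set(c.members)) /
                   len(module | set(c.members)) for c in clusters)
        assert best >= 0.8
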