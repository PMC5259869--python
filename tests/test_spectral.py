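import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from comodule.netbuild import Adjacency, CrossAdjacency
from comodule.spectral import (
    Embedding,
    IntegratedNetwork,
    Module,
    ModuleAssignment,
    build_integrated_matrix,
    bruteforce_max_normalized_objective,
    cluster_embedding,
    comodule_scores,
    detect_modules,
    discrete_objective,
    filter_candidate_modules,
    merge_module_runs,
    spectral_embedding,
)

from conftest import network_from_expression, random_integrated


def tiny_net(lam=1.0):
    """Two genes joined by an edge, one miRNA connected to both."""
    a_g = Adjacency(["g1", "g2"], np.array([[0, 1], [1, 0]]))
    a_m = Adjacency(["m1"], np.zeros((1, 1), dtype=int))
    c = CrossAdjacency(["g1", "g2"], ["m1"], np.array([[1], [1]]))
    return IntegratedNetwork(a_g=a_g, a_m=a_m, c=c, lam=lam)


class TestBuildIntegratedMatrix:
    def test_hand_assembled_matrix(self):
        L = build_integrated_matrix(tiny_net(lam=1.0))
        np.testing.assert_array_equal(
            L, [[-1, 2, 1], [2, -1, 1], [1, 1, 0]]
        )

    def test_lambda_zero_block_diagonal_spectrum(self):
        net = tiny_net(lam=0.0)
        L = build_integrated_matrix(net, check_connected=False)
        lg = 2 * net.a_g.matrix.astype(float) - np.diag(net.a_g.degrees)
        spectrum = np.sort(np.linalg.eigvalsh(L))
        blocks = np.sort(np.concatenate([np.linalg.eigvalsh(lg), [0.0]]))
        np.testing.assert_allclose(spectrum, blocks, atol=1e-12)

    def test_disconnected_network_refused(self):
        a_g = Adjacency(["g1", "g2"], np.array([[0, 1], [1, 0]]))
        a_m = Adjacency(["m1"], np.zeros((1, 1), dtype=int))
        c = CrossAdjacency(["g1", "g2"], ["m1"], np.zeros((2, 1), dtype=int))
        net = IntegratedNetwork(a_g=a_g, a_m=a_m, c=c)
        with pytest.raises(ValueError, match="component"):
            build_integrated_matrix(net)
        assert build_integrated_matrix(net, check_connected=False).shape == (3, 3)


class TestSpectralEmbedding:
    def triangle_L(self):
        a = (np.ones((3, 3)) - np.eye(3))
        return 2 * a - np.diag([2.0, 2.0, 2.0])

    def test_complete_triangle_top_eigenpair(self):
        emb = spectral_embedding(self.triangle_L(), 1)
        assert emb.eigenvalues[0] == pytest.approx(2.0, abs=1e-12)
        np.testing.assert_allclose(np.abs(emb.T.ravel()), 1 / np.sqrt(3), rtol=1e-12)
        assert emb.T[0, 0] > 0  # sign canonicalized

    def test_full_basis_trace(self):
        L = build_integrated_matrix(tiny_net())
        emb = spectral_embedding(L, 3)
        assert np.trace(emb.T.T @ L @ emb.T) == pytest.approx(np.trace(L), abs=1e-10)

    def test_trace_dominates_random_orthonormal_frames(self):
        rng = np.random.default_rng(0)
        net, k = random_integrated(rng, max_side=5)
        L = build_integrated_matrix(net, check_connected=False)
        emb = spectral_embedding(L, k)
        opt = np.trace(emb.T.T @ L @ emb.T)
        n = L.shape[0]
        for _ in range(100):
            q, _ = np.linalg.qr(rng.normal(size=(n, k)))
            assert np.trace(q.T @ L @ q) <= opt + 1e-9

    def test_orthonormal_columns(self):
        rng = np.random.default_rng(1)
        net, k = random_integrated(rng)
        emb = spectral_embedding(build_integrated_matrix(net, check_connected=False), k)
        np.testing.assert_allclose(emb.T.T @ emb.T, np.eye(k), atol=1e-10)


class TestClusterEmbedding:
    def test_duplicate_row_groups_recovered(self):
        t = np.array([[1.0, 0.0]] * 4 + [[0.0, 1.0]] * 3)
        emb = Embedding(T=t, eigenvalues=np.array([1.0, 1.0]))
        labels = cluster_embedding(emb, 2, seed=0)
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[-1]

    def test_single_cluster(self):
        emb = Embedding(T=np.random.default_rng(0).normal(size=(5, 2)),
                        eigenvalues=np.ones(2))
        assert set(cluster_embedding(emb, 1, seed=0)) == {0}

    def test_planted_three_module_recovery(self, small_planted):
        ds = small_planted
        net = network_from_expression(ds.expr_g, ds.expr_m)
        assign, _ = detect_modules(net, 3, seed=0)
        labels = np.concatenate([assign.gene_labels, assign.mirna_labels])
        truth = np.concatenate([ds.true_gene_labels, ds.true_mirna_labels])
        assert adjusted_rand_score(truth, labels) == pytest.approx(1.0)


class TestDiscreteObjective:
    def test_hand_computed_value(self):
        net = tiny_net()
        assign = ModuleAssignment(np.zeros(2, int), np.zeros(1, int), 1)
        assert discrete_objective(assign, net) == pytest.approx(1 + np.sqrt(2), rel=1e-12)

    def test_no_edges_singletons_zero(self):
        a_g = Adjacency(["g1", "g2"], np.zeros((2, 2), int))
        a_m = Adjacency(["m1"], np.zeros((1, 1), int))
        c = CrossAdjacency(["g1", "g2"], ["m1"], np.zeros((2, 1), int))
        net = IntegratedNetwork(a_g=a_g, a_m=a_m, c=c, lam=0.0)
        assign = ModuleAssignment([0, 1], [2], 3)
        assert discrete_objective(assign, net) == 0.0

    def test_complete_gene_triangle(self):
        a_g = Adjacency(["a", "b", "c"], (np.ones((3, 3)) - np.eye(3)).astype(int))
        a_m = Adjacency(["m"], np.zeros((1, 1), int))
        c = CrossAdjacency(["a", "b", "c"], ["m"], np.zeros((3, 1), int))
        net = IntegratedNetwork(a_g=a_g, a_m=a_m, c=c, lam=0.0)
        assign = ModuleAssignment([0, 0, 0], [1], 2)
        assert discrete_objective(assign, net) == pytest.approx(2.0)


class TestComoduleScores:
    def test_identical_and_orthogonal_rows(self):
        t = np.array([[1.0, 0.0], [2.0, 0.0], [0.0, 3.0]])
        s = comodule_scores(t)
        assert s[0, 1] == pytest.approx(1.0)
        assert s[0, 2] == pytest.approx(0.0)
        np.testing.assert_allclose(np.diag(s), 1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(5)
        t = rng.normal(size=(10, 3))
        tn = t / np.linalg.norm(t, axis=1, keepdims=True)
        np.testing.assert_allclose(comodule_scores(t), tn @ tn.T, atol=1e-12)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(6)
        t = rng.normal(size=(12, 4))
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        np.testing.assert_allclose(comodule_scores(t), comodule_scores(t @ q), atol=1e-10)

    def test_zero_row_scores_zero(self):
        t = np.array([[1.0, 0.0], [0.0, 0.0]])
        s = comodule_scores(t)
        assert s[1, 0] == 0.0 and s[1, 1] == 0.0


class TestFilterCandidateModules:
    def make_net(self):
        a_g = Adjacency(["g1", "g2", "g3"], np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        a_m = Adjacency(["m1", "m2", "m3"], np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]]))
        c = CrossAdjacency(
            ["g1", "g2", "g3"], ["m1", "m2", "m3"],
            np.array([[1, 0, 0], [0, 0, 0], [0, 0, 0]]),
        )
        return IntegratedNetwork(a_g=a_g, a_m=a_m, c=c)

    def test_criteria(self):
        net = self.make_net()
        # cluster 0: g1,g2,m1,m2 has all three edge types -> valid
        # cluster 1: g3 only -> invalid; cluster 2: m3 only -> invalid
        assign = ModuleAssignment([0, 0, 1], [0, 0, 2], 3)
        mods = filter_candidate_modules(assign, net)
        assert [m.valid for m in mods] == [True, False, False]
        assert mods[0].edge_counts == {"gene_gene": 1, "mirna_mirna": 1, "gene_mirna": 1}

    def test_missing_cross_edge_rejected(self):
        net = self.make_net()
        # g1,g2 with m3: gene-gene edge but no miRNA-miRNA or cross edge
        assign = ModuleAssignment([0, 0, 1], [1, 1, 0], 2)
        mods = filter_candidate_modules(assign, net)
        assert not mods[0].valid


class TestMergeModuleRuns:
    @staticmethod
    def module(genes, mirnas=("mX",)):
        return Module(genes=set(genes), mirnas=set(mirnas), valid=True)

    def test_identical_modules_collapse(self):
        a = self.module("abc")
        merged = merge_module_runs([[a], [self.module("abc")]])
        assert len(merged) == 1

    def test_ninety_percent_overlap_not_merged(self):
        ten = [f"n{i}" for i in range(9)]  # 9 genes + 1 shared miRNA = 10 nodes
        a = self.module(ten, ["mX"])
        b = self.module(ten[:8] + ["other"], ["mX"])  # overlap 9/10 exactly
        assert len(a.nodes & b.nodes) / min(len(a.nodes), len(b.nodes)) == 0.9
        merged = merge_module_runs([[a], [b]], overlap_frac=0.9)
        assert len(merged) == 2

    def test_chain_merges_to_fixed_point(self):
        base = [f"n{i}" for i in range(30)]
        a = self.module(base[:20])
        b = self.module(base[1:21])   # overlaps a by 19/21+... > 0.9
        c = self.module(base[2:22])
        merged = merge_module_runs([[a, c], [b]], overlap_frac=0.9)
        assert len(merged) == 1
        assert merged[0].genes == set(base[:22])

    def test_idempotent(self):
        rng = np.random.default_rng(7)
        mods = [
            self.module(rng.choice(50, size=rng.integers(5, 15), replace=False).astype(str))
            for _ in range(8)
        ]
        once = merge_module_runs([mods])
        twice = merge_module_runs([once])
        assert [(sorted(m.genes), sorted(m.mirnas)) for m in once] == [
            (sorted(m.genes), sorted(m.mirnas)) for m in twice
        ]

    def test_overlap_frac_validation(self):
        with pytest.raises(ValueError):
            merge_module_runs([], overlap_frac=0.0)


def test_permutation_equivariance_of_embedding_scores():
    rng = np.random.default_rng(8)
    net, k = random_integrated(rng, max_side=5)
    L = build_integrated_matrix(net, check_connected=False)
    s = comodule_scores(spectral_embedding(L, k))
    perm = rng.permutation(L.shape[0])
    s_perm = comodule_scores(spectral_embedding(L[np.ix_(perm, perm)], k))
    np.testing.assert_allclose(s_perm, s[np.ix_(perm, perm)], atol=1e-8)


def test_relaxation_bound_on_small_random_networks():
    rng = np.random.default_rng(9)
    for _ in range(20):
        net, k = random_integrated(rng, max_side=4)
        L = build_integrated_matrix(net, check_connected=False)
        relaxed = float(spectral_embedding(L, k).eigenvalues.sum())
        discrete = bruteforce_max_normalized_objective(net, k)
        assert discrete <= relaxed + 1e-9
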