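import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from comodule.netbuild import (
    Adjacency,
    CrossAdjacency,
    PROV_BOTH,
    PROV_KNOWN,
    combine_cross_network,
    correlation_matrix,
    scale_free_fit,
    scale_free_fit_from_frequencies,
    select_scale_free_threshold,
    threshold_adjacency,
    threshold_cross_adjacency,
)


class TestCorrelationMatrix:
    def test_self_correlation_is_one(self):
        x = np.array([[1.0, 2.0, 5.0, 3.0]])
        np.testing.assert_allclose(correlation_matrix(x), [[1.0]])

    def test_anticorrelation(self):
        x = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(correlation_matrix(x, -x), [[-1.0]], atol=1e-14)

    def test_hand_computed_value(self):
        x = np.array([[1.0, 2.0, 3.0]])
        y = np.array([[1.0, 2.0, 4.0]])
        np.testing.assert_allclose(
            correlation_matrix(x, y), [[9.0 / np.sqrt(84.0)]], rtol=1e-12
        )

    def test_constant_row_zeroed_and_flagged(self):
        x = np.array([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        corr, const = correlation_matrix(x, return_constant_mask=True)
        assert const.tolist() == [True, False]
        np.testing.assert_allclose(corr[0], [0.0, 0.0])
        assert corr[1, 1] == 1.0

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="3 samples"):
            correlation_matrix(np.ones((2, 2)))


class TestThresholdAdjacency:
    CORR = np.array([[1.0, 0.7, -0.65], [0.7, 1.0, 0.2], [-0.65, 0.2, 1.0]])

    def test_strict_rule_application(self):
        adj = threshold_adjacency(self.CORR, 0.6, ["a", "b", "c"])
        expected = np.array([[0, 1, 1], [1, 0, 0], [1, 0, 0]])
        np.testing.assert_array_equal(adj.matrix, expected)

    def test_high_tau_empty(self):
        assert threshold_adjacency(self.CORR, 0.99, ["a", "b", "c"]).n_edges == 0

    def test_boundary_is_strict(self):
        corr = np.array([[1.0, 0.6], [0.6, 1.0]])
        assert threshold_adjacency(corr, 0.6, ["a", "b"]).n_edges == 0

    def test_tau_validation(self):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                threshold_adjacency(self.CORR, bad, ["a", "b", "c"])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_antitone_in_tau_with_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(8, 12))
        corr = correlation_matrix(x)
        taus = sorted(rng.uniform(0, 0.99, size=3))
        ids = [f"f{i}" for i in range(8)]
        prev = None
        for tau in taus:
            adj = threshold_adjacency(corr, tau, ids)
            assert np.array_equal(adj.matrix, adj.matrix.T)
            assert np.all(np.diag(adj.matrix) == 0)
            if prev is not None:
                assert np.all(adj.matrix <= prev)  # edges only disappear
            prev = adj.matrix


class TestScaleFreeFit:
    @staticmethod
    def exact_power_law_graph():
        """21 nodes with degree frequencies f(1)=16, f(2)=4, f(4)=1."""
        n = 21
        a = np.zeros((n, n), dtype=int)
        for leaf in range(1, 5):            # hub 0 with 4 leaves
            a[0, leaf] = a[leaf, 0] = 1
        cycle = [5, 6, 7, 8]                # 4 nodes of degree 2
        for i, j in zip(cycle, cycle[1:] + cycle[:1]):
            a[i, j] = a[j, i] = 1
        for i in range(9, 21, 2):           # 6 disjoint edges -> 12 leaves
            a[i, i + 1] = a[i + 1, i] = 1
        return Adjacency([f"n{i}" for i in range(n)], a)

    def test_exact_power_law(self):
        fit = scale_free_fit(self.exact_power_law_graph())
        assert fit.slope == pytest.approx(-2.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.n_points == 3

    def test_constant_frequencies_slope_zero(self):
        fit = scale_free_fit_from_frequencies([1, 2, 4], [7, 7, 7])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)

    def test_too_few_degrees(self):
        with pytest.raises(ValueError, match="distinct"):
            scale_free_fit_from_frequencies([1, 2], [5, 3])

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = np.unique(rng.integers(1, 50, size=10))
            if len(d) < 3:
                continue
            f = rng.integers(1, 100, size=len(d)).astype(float)
            fit = scale_free_fit_from_frequencies(d, f)
            # closed-form OLS through the normal equations
            x, y = np.log10(d), np.log10(f)
            xm, ym = x.mean(), y.mean()
            slope = ((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm))
            resid = y - (ym + slope * (x - xm))
            r2 = 1.0 - (resid @ resid) / ((y - ym) @ (y - ym))
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.r_squared == pytest.approx(r2, rel=1e-10, abs=1e-12)


class TestSelectScaleFreeThreshold:
    def test_smallest_qualifying_tau_wins(self):
        rng = np.random.default_rng(2)
        # three latent groups -> thresholding gives hub-ish structure
        x = np.vstack([rng.normal(size=(1, 40)) * 0.9 + rng.normal(size=(10, 40)) * 0.45
                       for _ in range(4)])
        corr = correlation_matrix(x)
        grid = [0.3, 0.5, 0.7]
        fits = {}
        for tau in grid:
            try:
                fits[tau] = scale_free_fit(
                    threshold_adjacency(corr, tau, [f"f{i}" for i in range(40)])
                ).r_squared
            except ValueError:
                pass
        min_r2 = 0.0  # everything qualifies -> smallest computable tau
        chosen = select_scale_free_threshold(corr, grid, min_r2=min_r2)
        assert chosen.threshold == min(fits)
        assert not chosen.fallback

    def test_fallback_flags_argmax(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 50))
        corr = correlation_matrix(x)
        chosen = select_scale_free_threshold(corr, [0.1, 0.2, 0.3], min_r2=0.999)
        assert chosen.fallback

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            select_scale_free_threshold(np.eye(3), [1.2])


class TestCombineCrossNetwork:
    def setup_method(self):
        self.coexpr = CrossAdjacency(
            ["g1", "g2"], ["m1", "m2"], np.array([[1, 0], [0, 0]])
        )

    def test_empty_known_is_identity(self):
        out = combine_cross_network(self.coexpr, set())
        np.testing.assert_array_equal(out.matrix, self.coexpr.matrix)

    def test_known_edge_already_present_marked_both(self):
        out = combine_cross_network(self.coexpr, {("g1", "m1")})
        np.testing.assert_array_equal(out.matrix, self.coexpr.matrix)
        assert out.provenance[0, 0] == PROV_BOTH

    def test_new_known_edge_added(self):
        out = combine_cross_network(self.coexpr, {("g2", "m2")})
        assert out.matrix[1, 1] == 1
        assert out.provenance[1, 1] == PROV_KNOWN

    def test_unresolvable_pairs_dropped(self):
        out = combine_cross_network(self.coexpr, {("gX", "m1"), ("g1", "mX")})
        np.testing.assert_array_equal(out.matrix, self.coexpr.matrix)
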