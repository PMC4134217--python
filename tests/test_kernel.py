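"""R-convolution graph kernel, bandwidth heuristic and Gram matrices."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gsvc.graphs import PatternGraph
from gsvc.kernel import (
    KernelParams,
    estimate_bandwidths,
    gram,
    k_activation,
    k_geometric,
    k_structural,
    kernel,
)
from oracles import brute_force_kernel, random_pattern_graph


def single_edge_graph(geom, acts):
    return PatternGraph(np.array([[0, 1], [1, 0]]), np.asarray(geom, float),
                        np.asarray(acts, float))


class TestBaseKernels:
    @pytest.mark.parametrize("a,b,expected", [(1, 1, 1), (1, 0, 0), (0, 1, 0), (0, 0, 0)])
    def test_structural_is_edge_indicator(self, a, b, expected):
        assert k_structural(a, b) == expected

    def test_geometric_identity_and_limit(self):
        e = (np.array([0.0, 0.0]), np.array([1.0, 1.0]))
        assert k_geometric(e, e, sigma_g=0.5) == 1.0
        far = (np.array([5.0, 5.0]), np.array([9.0, 9.0]))
        assert k_geometric(e, far, sigma_g=1e12) == pytest.approx(1.0)

    def test_geometric_closed_form(self):
        """Displacements (1, 2) at sigma 1 give exp(-(1 + 4)/2) = 0.0821."""
        e1 = (np.array([0.0, 0.0]), np.array([0.0, 0.0]))
        e2 = (np.array([1.0, 0.0]), np.array([2.0, 0.0]))
        assert k_geometric(e1, e2, 1.0) == pytest.approx(np.exp(-2.5), rel=1e-12)
        assert k_geometric(e1, e2, 1.0) == pytest.approx(0.0821, abs=5e-5)

    def test_activation_closed_form_and_monotonicity(self):
        assert k_activation((0.0, 0.0), (1.0, 0.0), 1.0) == pytest.approx(np.exp(-0.5))
        vals = [k_activation((0.0, 0.0), (d, 0.0), 1.0) for d in (0.0, 0.5, 1.0, 2.0)]
        assert all(x > y for x, y in zip(vals, vals[1:]))

    def test_invalid_bandwidths_rejected(self):
        with pytest.raises(ValueError):
            KernelParams(sigma_g=0.0)
        with pytest.raises(ValueError):
            KernelParams(sigma_a=-1.0)
        with pytest.raises(ValueError):
            KernelParams(variant="xyz")


class TestKernel:
    @pytest.mark.parametrize("variant", ["sga", "sg", "sa", "ga"])
    def test_matches_bruteforce_on_small_graphs(self, variant):
        rng = np.random.default_rng(0)
        params = KernelParams(sigma_g=1.3, sigma_a=0.7, variant=variant)
        for _ in range(25):
            G = random_pattern_graph(rng, int(rng.integers(2, 6)))
            H = random_pattern_graph(rng, int(rng.integers(2, 6)))
            expected = brute_force_kernel(G, H, params)
            assert kernel(G, H, params) == pytest.approx(expected, rel=1e-12, abs=1e-300)

    def test_large_bandwidth_limit_counts_ordered_edge_pairs(self):
        """As both bandwidths diverge every Gaussian factor tends to 1, so the
        kernel counts ordered edge pairs: (2 m_G)(2 m_H)."""
        rng = np.random.default_rng(1)
        params = KernelParams(sigma_g=1e9, sigma_a=1e9, variant="sga")
        for _ in range(10):
            G = random_pattern_graph(rng, int(rng.integers(2, 8)))
            H = random_pattern_graph(rng, int(rng.integers(2, 8)))
            assert kernel(G, H, params) == pytest.approx(4 * G.n_edges * H.n_edges,
                                                         rel=1e-9)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        G = random_pattern_graph(rng, 4)
        H = random_pattern_graph(rng, 6)
        for variant in ("sga", "sg", "sa", "ga"):
            params = KernelParams(sigma_g=0.9, sigma_a=1.1, variant=variant)
            assert kernel(G, H, params) == pytest.approx(kernel(H, G, params), rel=1e-12)

    def test_identical_single_edge_graphs_enumeration(self):
        """Two copies of one single-edge graph: the 4 ordered pair combinations
        contribute 1 + 1 + x + x with x the cross-orientation factor."""
        g = single_edge_graph([[0.0, 0.0], [1.0, 0.0]], [0.0, 1.0])
        params = KernelParams(sigma_g=1.0, sigma_a=1.0)
        cross = np.exp(-1.0 / 2) ** 2 * np.exp(-1.0 / 2) ** 2  # both nodes swapped
        assert kernel(g, g, params) == pytest.approx(2 + 2 * cross, rel=1e-12)

    def test_sg_equals_sga_at_infinite_activation_bandwidth(self):
        rng = np.random.default_rng(3)
        G = random_pattern_graph(rng, 5)
        H = random_pattern_graph(rng, 4)
        sg = kernel(G, H, KernelParams(sigma_g=1.0, sigma_a=1.0, variant="sg"))
        sga = kernel(G, H, KernelParams(sigma_g=1.0, sigma_a=1e9, variant="sga"))
        assert sg == pytest.approx(sga, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000), st.integers(2, 6), st.integers(2, 6))
    def test_node_permutation_invariance(self, seed, qg, qh):
        rng = np.random.default_rng(seed)
        G = random_pattern_graph(rng, qg)
        H = random_pattern_graph(rng, qh)
        perm = rng.permutation(qg)
        for variant in ("sga", "ga"):
            params = KernelParams(sigma_g=1.2, sigma_a=0.8, variant=variant)
            assert kernel(G.permuted(perm), H, params) == pytest.approx(
                kernel(G, H, params), rel=1e-10)

    def test_joint_translation_invariance(self):
        rng = np.random.default_rng(4)
        G = random_pattern_graph(rng, 5)
        H = random_pattern_graph(rng, 3)
        shift = np.array([13.0, -4.5])
        params = KernelParams(sigma_g=0.7, sigma_a=0.9)
        Gt = PatternGraph(G.adjacency, G.geom + shift, G.activation)
        Ht = PatternGraph(H.adjacency, H.geom + shift, H.activation)
        assert kernel(Gt, Ht, params) == pytest.approx(kernel(G, H, params), rel=1e-12)

    def test_upper_bound_four_m_m(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            G = random_pattern_graph(rng, 5)
            H = random_pattern_graph(rng, 5)
            v = kernel(G, H, KernelParams(sigma_g=1.0, sigma_a=1.0))
            assert 0.0 <= v <= 4 * G.n_edges * H.n_edges + 1e-12

    def test_normalized_kernel_is_cosine(self):
        rng = np.random.default_rng(6)
        G = random_pattern_graph(rng, 4)
        H = random_pattern_graph(rng, 5)
        params = KernelParams(sigma_g=1.0, sigma_a=1.0, normalize=True)
        raw = KernelParams(sigma_g=1.0, sigma_a=1.0)
        expected = kernel(G, H, raw) / np.sqrt(kernel(G, G, raw) * kernel(H, H, raw))
        assert kernel(G, H, params) == pytest.approx(expected, rel=1e-12)
        assert kernel(G, G, params) == pytest.approx(1.0, rel=1e-12)

    def test_different_node_counts_supported(self):
        rng = np.random.default_rng(7)
        G = random_pattern_graph(rng, 3)
        H = random_pattern_graph(rng, 9)
        assert kernel(G, H, KernelParams()) >= 0.0


class TestEstimateBandwidths:
    def test_single_pair(self):
        g = single_edge_graph([[0.0, 0.0], [1.0, 0.0]], [0.0, 1.0])
        sigma_g, sigma_a = estimate_bandwidths([g])
        assert sigma_g == 1.0 and sigma_a == 1.0

    def test_three_node_median(self):
        """Activations (0, 1, 3): pairwise distances {1, 3, 2}, median 2."""
        g = PatternGraph(np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]]),
                         np.array([[0.0, 0], [1, 0], [3, 0]]), np.array([0.0, 1.0, 3.0]))
        sigma_g, sigma_a = estimate_bandwidths([g])
        assert sigma_a == 2.0 and sigma_g == 2.0

    def test_degenerate_attributes_floored_with_warning(self):
        g = PatternGraph(np.array([[0, 1], [1, 0]]), np.zeros((2, 2)) + 5.0,
                         np.zeros(2) + 1.0)
        with pytest.warns(UserWarning, match="floored"):
            sigma_g, sigma_a = estimate_bandwidths([g])
        assert sigma_g > 0 and sigma_a > 0

    def test_subsampling_is_seeded_and_close_to_exact(self):
        rng = np.random.default_rng(8)
        graphs = [random_pattern_graph(rng, 10) for _ in range(20)]
        exact = estimate_bandwidths(graphs, max_pairs=10 ** 9)
        sub1 = estimate_bandwidths(graphs, max_pairs=5000, seed=1)
        sub2 = estimate_bandwidths(graphs, max_pairs=5000, seed=1)
        assert sub1 == sub2
        assert sub1[0] == pytest.approx(exact[0], rel=0.15)
        assert sub1[1] == pytest.approx(exact[1], rel=0.15)


class TestGram:
    def test_self_gram_positive(self):
        rng = np.random.default_rng(9)
        G = random_pattern_graph(rng, 4)
        gm = gram([G], None, KernelParams())
        assert gm.values.shape == (1, 1) and gm.values[0, 0] > 0

    def test_square_gram_is_symmetric_psd(self):
        rng = np.random.default_rng(10)
        graphs = [random_pattern_graph(rng, int(rng.integers(3, 7))) for _ in range(15)]
        gm = gram(graphs, None, KernelParams(sigma_g=1.0, sigma_a=1.0))
        assert np.allclose(gm.values, gm.values.T)
        eigs = np.linalg.eigvalsh(gm.values)
        assert eigs.min() >= -1e-8 * np.abs(eigs).max()

    def test_rectangular_gram_transposes(self):
        rng = np.random.default_rng(11)
        A = [random_pattern_graph(rng, 4) for _ in range(3)]
        B = [random_pattern_graph(rng, 5) for _ in range(4)]
        params = KernelParams()
        ab = gram(A, B, params).values
        ba = gram(B, A, params).values
        assert np.allclose(ab, ba.T)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gram([], None, KernelParams())
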