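import numpy as np
import pytest

from mirtargraph.graph import first_order_coefficients, chebyshev_oracle, normalize, selfloop_laplacian
from mirtargraph.model import (
    GCNConfig,
    LinkModel,
    NodeRepresentations,
    celu,
    edge_features,
    gcn_forward,
    init_params,
    mlp_predict,
)
from mirtargraph.training import bce_loss, l2_penalty


def _setup(rng, n_mirna=4, n_target=6, d_in=5, dims=((6, 5, 4), (4, 3)), seed=7):
    n = n_mirna + n_target
    A = rng.random((n, n))
    A = np.triu(A, 1) * (rng.random((n, n)) < 0.5)
    A = A + A.T
    P = normalize(A).P
    M = rng.standard_normal((n, d_in))
    cfg = GCNConfig(gcn_dims=dims[0], mlp_hidden=dims[1], seed=seed)
    return A, P, M, cfg


class TestGCNForward:
    def test_zero_features_give_zero_output(self, rng):
        _, P, M, cfg = _setup(rng)
        params = init_params(M.shape[1], cfg)
        reps = gcn_forward(P, np.zeros_like(M), params, n_mirna=4)
        assert np.allclose(reps.H_mirna, 0.0)
        assert np.allclose(reps.H_target, 0.0)

    def test_single_node_hand_chain(self, rng):
        P = np.array([[1.0]])  # isolated node with self-loop
        M = rng.standard_normal((1, 3))
        cfg = GCNConfig(gcn_dims=(2, 2, 2), mlp_hidden=(2,), seed=1)
        params = init_params(3, cfg)
        reps = gcn_forward(P, M, params, n_mirna=1)
        h = M
        for th in params.theta:
            h = celu(h @ th)
        assert np.allclose(reps.H_mirna, h)

    def test_compositionality_one_layer_at_a_time(self, rng):
        _, P, M, cfg = _setup(rng)
        params = init_params(M.shape[1], cfg)
        reps = gcn_forward(P, M, params, n_mirna=4)
        H = M
        for th in params.theta:
            H = celu(P @ H @ th)
        assert np.allclose(np.vstack([reps.H_mirna, reps.H_target]), H)

    def test_first_order_chebyshev_equivalence(self, rng):
        """One propagation layer (pre-activation) equals the spectral K=1
        filter with matched coefficients, to 1e-8, on random graphs."""
        for _ in range(20):
            n = int(rng.integers(5, 51))
            A = rng.random((n, n)) * (rng.random((n, n)) < 0.3)
            A = np.triu(A, 1)
            A = A + A.T
            P = normalize(A).P
            M = rng.standard_normal((n, 6))
            W = rng.standard_normal((6, 3))
            lam_max = float(np.linalg.eigvalsh(selfloop_laplacian(A)).max())
            theta = first_order_coefficients(lam_max)
            spectral = chebyshev_oracle(A, M, K=1, theta=theta) @ W
            assert np.abs(P @ M @ W - spectral).max() < 1e-8


class TestEdgeFeatures:
    @pytest.fixture
    def reps(self, rng):
        return NodeRepresentations(
            H_mirna=rng.standard_normal((3, 4)), H_target=rng.standard_normal((5, 4))
        )

    def test_width_is_2d(self, reps):
        E = edge_features(reps, [(0, 0), (2, 4)])
        assert E.shape == (2, 8)
        assert np.allclose(E[1, :4], reps.H_mirna[2])
        assert np.allclose(E[1, 4:], reps.H_target[4])

    def test_empty_pair_list(self, reps):
        assert edge_features(reps, []).shape == (0, 8)

    def test_swapping_pairs_swaps_rows(self, reps):
        a = edge_features(reps, [(0, 1), (2, 3)])
        b = edge_features(reps, [(2, 3), (0, 1)])
        assert np.allclose(a, b[::-1])

    def test_out_of_range(self, reps):
        with pytest.raises(IndexError):
            edge_features(reps, [(0, 9)])


class TestMLP:
    def test_zero_parameters_give_half(self, rng):
        cfg = GCNConfig(gcn_dims=(4, 4, 4), mlp_hidden=(3, 2), seed=0)
        params = init_params(5, cfg)
        for i in range(len(params.W)):
            params.W[i] = np.zeros_like(params.W[i])
        E = rng.standard_normal((7, 8))
        assert np.allclose(mlp_predict(E, params), 0.5)

    def test_large_positive_bias_saturates(self, rng):
        cfg = GCNConfig(gcn_dims=(4, 4, 4), mlp_hidden=(3, 2), seed=0)
        params = init_params(5, cfg)
        params.b[-1] = np.array([50.0])
        E = rng.standard_normal((4, 8))
        assert np.all(mlp_predict(E, params) > 0.999999)

    def test_probabilities_strictly_in_unit_interval(self, rng):
        cfg = GCNConfig(gcn_dims=(4, 4, 4), mlp_hidden=(3, 2), seed=3)
        params = init_params(5, cfg)
        E = 10 * rng.standard_normal((50, 8))
        p = mlp_predict(E, params)
        assert np.all(p > 0.0) and np.all(p < 1.0)

    def test_deterministic(self, rng):
        cfg = GCNConfig(gcn_dims=(4, 4, 4), mlp_hidden=(3, 2), seed=0)
        params = init_params(5, cfg)
        E = rng.standard_normal((6, 8))
        assert np.array_equal(mlp_predict(E, params), mlp_predict(E, params))

    def test_width_mismatch(self, rng):
        cfg = GCNConfig(gcn_dims=(4, 4, 4), mlp_hidden=(3, 2), seed=0)
        params = init_params(5, cfg)
        with pytest.raises(ValueError, match="width"):
            mlp_predict(rng.standard_normal((2, 5)), params)


def test_node_permutation_equivariance(rng):
    """Relabelling nodes permutes representations and leaves pair scores
    unchanged."""
    A, P, M, cfg = _setup(rng)
    model = LinkModel(P, M, n_mirna=4, config=cfg)
    pairs = [(0, 1), (3, 5), (2, 2)]
    p0 = model.forward(pairs)[0]
    # permute miRNAs and targets separately, keeping the role split
    pm = rng.permutation(4)
    pt = rng.permutation(6)
    perm = np.concatenate([pm, 4 + pt])
    P2 = P[np.ix_(perm, perm)]
    M2 = M[perm]
    model2 = LinkModel(P2, M2, n_mirna=4, params=model.params)
    inv_m = np.argsort(pm)
    inv_t = np.argsort(pt)
    pairs2 = [(inv_m[i], inv_t[j]) for i, j in pairs]
    p2 = model2.forward(pairs2)[0]
    assert np.allclose(p0, p2, atol=1e-10)


def test_backward_matches_numerical_gradient(rng):
    A, P, M, cfg = _setup(rng, dims=((4, 3, 3), (3, 2)))
    model = LinkModel(P, M, n_mirna=4, config=cfg)
    pairs = [(0, 0), (1, 3), (3, 5)]
    y = np.array([1.0, 0.0, 1.0])
    lam = 0.2

    def loss():
        prob, _ = model.forward(pairs)
        return bce_loss(y, prob) + l2_penalty(model.params.weight_matrices(), lam, len(pairs))

    prob, caches = model.forward(pairs)
    grads = model.backward(pairs, y, caches, l2_lambda=lam)
    eps = 1e-6
    for p, g in zip(model.params.flat(), grads):
        flat = p.reshape(-1)
        for ix in rng.choice(flat.size, size=min(4, flat.size), replace=False):
            orig = flat[ix]
            flat[ix] = orig + eps
            lp = loss()
            flat[ix] = orig - eps
            lm = loss()
            flat[ix] = orig
            assert (lp - lm) / (2 * eps) == pytest.approx(g.reshape(-1)[ix], abs=1e-7)
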