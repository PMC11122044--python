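"""First-order spectral GCN encoder and MLP link decoder.

Each of the three graph-convolution layers computes

    H^(l) = CELU(P @ H^(l-1) @ theta^(l)),      H^(0) = M_kmer,

where P is the self-looped, symmetrically normalised adjacency — the K=1
Chebyshev truncation of a spectral filter on the heterogeneous graph. After
three layers the node representations split by role into H_miRNA (first
N_miRNA rows) and H_target. A candidate pair (i, j) is represented by the
concatenation [H_miRNA_i || H_target_j] (width 2d) and scored by a
three-layer MLP with CELU hidden activations and a final sigmoid, giving an
association probability in (0, 1).

Everything is NumPy: forward passes cache activations, ``backward`` returns
gradients of the BCE(+L2) objective for all weights, and training drives them
through Adam. Initialisation is seeded Glorot-uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GCNConfig",
    "ModelParams",
    "NodeRepresentations",
    "celu",
    "celu_grad",
    "init_params",
    "gcn_forward",
    "edge_features",
    "mlp_predict",
    "forward_scores",
    "LinkModel",
]


def celu(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Continuously differentiable ELU: x for x>=0, alpha(exp(x/alpha)-1) below."""
    return np.where(x >= 0, x, alpha * np.expm1(np.minimum(x, 0.0) / alpha))


def celu_grad(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    return np.where(x >= 0, 1.0, np.exp(np.minimum(x, 0.0) / alpha))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass(frozen=True)
class GCNConfig:
    """Encoder/decoder architecture. Three graph-convolution layers
    (256, 128, 64 wide by default) and a 2d -> 64 -> 16 -> 1 MLP."""

    gcn_dims: tuple[int, ...] = (256, 128, 64)
    mlp_hidden: tuple[int, ...] = (64, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d < 1 for d in self.gcn_dims + self.mlp_hidden):
            raise ValueError("layer widths must be >= 1")


@dataclass
class ModelParams:
    """GCN layer weights ``theta`` (no biases) and MLP weights/biases ``W``/``b``."""

    theta: list[np.ndarray]
    W: list[np.ndarray]
    b: list[np.ndarray]

    def flat(self) -> list[np.ndarray]:
        return [*self.theta, *self.W, *self.b]

    def weight_matrices(self) -> list[np.ndarray]:
        """All weight matrices (biases excluded) — the L2-penalised set."""
        return [*self.theta, *self.W]


@dataclass
class NodeRepresentations:
    H_mirna: np.ndarray
    H_target: np.ndarray

    @property
    def d(self) -> int:
        return self.H_mirna.shape[1]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def init_params(in_dim: int, config: GCNConfig) -> ModelParams:
    """Seeded Glorot-uniform initialisation of all layers."""
    rng = np.random.default_rng(config.seed)
    theta = []
    prev = in_dim
    for d in config.gcn_dims:
        theta.append(_glorot(rng, prev, d))
        prev = d
    W, b = [], []
    prev = 2 * config.gcn_dims[-1]
    for d in (*config.mlp_hidden, 1):
        W.append(_glorot(rng, prev, d))
        b.append(np.zeros(d))
        prev = d
    return ModelParams(theta=theta, W=W, b=b)


def gcn_forward(
    P: np.ndarray,
    M: np.ndarray,
    params: ModelParams,
    n_mirna: int,
    return_cache: bool = False,
):
    """Run the stacked propagation CELU(P H theta) and split rows by role."""
    H = np.asarray(M, dtype=np.float64)
    cache = {"H": [H], "Z": []}
    for th in params.theta:
        Z = P @ H @ th
        if not np.all(np.isfinite(Z)):
            raise FloatingPointError(
                f"non-finite activation in GCN layer {len(cache['Z'])}"
            )
        H = celu(Z)
        cache["Z"].append(Z)
        cache["H"].append(H)
    reps = NodeRepresentations(H_mirna=H[:n_mirna], H_target=H[n_mirna:])
    return (reps, cache) if return_cache else reps


def edge_features(
    H: NodeRepresentations, pairs: list[tuple[int, int]]
) -> np.ndarray:
    """Row per pair: [H_miRNA_i || H_target_j], width 2d; order preserved."""
    d = H.d
    if not pairs:
        return np.empty((0, 2 * d))
    idx = np.asarray(pairs, dtype=np.int64)
    if idx.min() < 0 or idx[:, 0].max() >= H.H_mirna.shape[0] or idx[:, 1].max() >= H.H_target.shape[0]:
        raise IndexError("pair index out of range")
    return np.concatenate([H.H_mirna[idx[:, 0]], H.H_target[idx[:, 1]]], axis=1)


def mlp_predict(
    E: np.ndarray, params: ModelParams, return_cache: bool = False
):
    """Three affine layers, CELU hidden, sigmoid output; one probability per row."""
    if E.shape[1] != params.W[0].shape[0]:
        raise ValueError(
            f"edge feature width {E.shape[1]} != MLP input width {params.W[0].shape[0]}"
        )
    A = E
    cache = {"A": [E], "Z": []}
    n_layers = len(params.W)
    for li, (W, b) in enumerate(zip(params.W, params.b)):
        Z = A @ W + b
        cache["Z"].append(Z)
        A = Z if li == n_layers - 1 else celu(Z)
        cache["A"].append(A)
    logits = A[:, 0]
    prob = _sigmoid(logits)
    cache["logits"] = logits
    return (prob, cache) if return_cache else prob


def forward_scores(
    P: np.ndarray,
    M: np.ndarray,
    params: ModelParams,
    n_mirna: int,
    pairs: list[tuple[int, int]],
) -> np.ndarray:
    """Full forward pass: GCN encode, concatenate, MLP score."""
    reps = gcn_forward(P, M, params, n_mirna)
    return mlp_predict(edge_features(reps, pairs), params)


class LinkModel:
    """Bundles P, node features and parameters; supports forward + backward.

    ``backward`` computes gradients of
        BCE(y, sigmoid(logits)) + lambda/(2N) * sum(weights^2)
    with respect to every parameter by hand-rolled reverse-mode
    differentiation through the MLP, the concatenation scatter and the three
    propagation layers (P is symmetric, so P^T = P in the feature backprop).
    """

    def __init__(
        self,
        P: np.ndarray,
        M: np.ndarray,
        n_mirna: int,
        config: GCNConfig | None = None,
        params: ModelParams | None = None,
    ) -> None:
        self.P = np.asarray(P, dtype=np.float64)
        self.M = np.asarray(M, dtype=np.float64)
        self.n_mirna = n_mirna
        self.config = config or GCNConfig()
        self.params = params or init_params(self.M.shape[1], self.config)

    def forward(self, pairs: list[tuple[int, int]]):
        reps, gcache = gcn_forward(
            self.P, self.M, self.params, self.n_mirna, return_cache=True
        )
        E = edge_features(reps, pairs)
        prob, mcache = mlp_predict(E, self.params, return_cache=True)
        return prob, (reps, gcache, E, mcache)

    def backward(
        self,
        pairs: list[tuple[int, int]],
        y: np.ndarray,
        caches,
        l2_lambda: float = 0.0,
    ) -> list[np.ndarray]:
        """Gradients in the order of ``params.flat()``."""
        reps, gcache, E, mcache = caches
        p = self.params
        n_pairs = max(len(pairs), 1)
        prob = _sigmoid(mcache["logits"])
        # d BCE / d logits with mean over pairs
        gZ = ((prob - y) / n_pairs)[:, None]
        gW = [None] * len(p.W)
        gb = [None] * len(p.b)
        n_mlp = len(p.W)
        for li in range(n_mlp - 1, -1, -1):
            A_prev = mcache["A"][li]
            gW[li] = A_prev.T @ gZ
            gb[li] = gZ.sum(axis=0)
            if li > 0:
                gA = gZ @ p.W[li].T
                gZ = gA * celu_grad(mcache["Z"][li - 1])
        gE = gZ @ p.W[0].T if n_mlp > 0 else gZ

        # scatter edge-feature gradient back to node rows
        d = reps.d
        n_nodes = self.P.shape[0]
        gH = np.zeros((n_nodes, d))
        if pairs:
            idx = np.asarray(pairs, dtype=np.int64)
            np.add.at(gH, idx[:, 0], gE[:, :d])
            np.add.at(gH, self.n_mirna + idx[:, 1], gE[:, d:])

        gtheta = [None] * len(p.theta)
        for li in range(len(p.theta) - 1, -1, -1):
            gZl = gH * celu_grad(gcache["Z"][li])
            PH = self.P @ gcache["H"][li]
            gtheta[li] = PH.T @ gZl
            if li > 0:
                gH = self.P @ (gZl @ p.theta[li].T)

        if l2_lambda > 0:
            scale = l2_lambda / n_pairs
            for g, w in zip(gtheta, p.theta):
                g += scale * w
            for g, w in zip(gW, p.W):
                g += scale * w
        return [*gtheta, *gW, *gb]
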