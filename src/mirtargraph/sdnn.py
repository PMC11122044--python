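"""Self-supervised embedding of k-mer frequency vectors.

A four-layer fully connected autoencoder (encoder 4^k -> hidden -> d_emb,
decoder mirror) is trained to reconstruct each sequence's frequency vector
under mean squared error. Hidden layers use the hyperbolic tangent, which
centres activations around zero; the final decoder layer is linear. Because
the objective is reconstruction only, training uses no association labels and
the encoder can be fit once on all miRNA and transcript rows together before
any cross-validation split without leaking labels.

The bottleneck activations form the embedding matrix
M_kmer in R^{(N_miRNA + N_target) x N_embedding} used as node attributes by
the graph model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from ._optim import Adam
from .kmer import FrequencyMatrix

__all__ = ["SDNNConfig", "SDNNEncoder", "EmbeddingMatrix", "train_sdnn", "embed"]


@dataclass(frozen=True)
class SDNNConfig:
    """Autoencoder architecture and training settings.

    embedding_dim defaults to 128: smaller bottlenecks start to cost ranking
    performance while larger ones mostly cost memory. hidden_dim is the width
    of the single intermediate layer on each side of the bottleneck.

    input_norm="l2" rescales each frequency row to unit Euclidean norm before
    encoding. Relative k-mer frequencies of long transcripts are individually
    tiny (order 1/window-count), which leaves the squared reconstruction
    error dominated by the shared bias and the per-sequence structure
    unlearned; unit rows put every sequence's reconstruction on the same
    scale without changing the direction of its profile.
    """

    embedding_dim: int = 128
    hidden_dim: int = 512
    epochs: int = 100
    learning_rate: float = 1e-3
    input_norm: str = "l2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.embedding_dim < 1 or self.hidden_dim < 1:
            raise ValueError("layer widths must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.input_norm not in ("l2", "none"):
            raise ValueError("input_norm must be 'l2' or 'none'")


@dataclass
class EmbeddingMatrix:
    """(N_miRNA + N_target) x N_embedding node-attribute matrix."""

    values: np.ndarray
    row_ids: list[str]
    n_mirna: int

    def __post_init__(self) -> None:
        if self.values.shape[0] != len(self.row_ids):
            raise ValueError("row_ids length does not match matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite embedding values")

    @property
    def n_target(self) -> int:
        return len(self.row_ids) - self.n_mirna


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(np.float32)


@dataclass
class SDNNEncoder:
    """Trained encoder weights; ``transform`` maps frequency rows to embeddings."""

    weights: list[np.ndarray]  # W1, b1, W2, b2 (encoder only)
    input_dim: int
    config: SDNNConfig

    def transform(self, X: np.ndarray) -> np.ndarray:
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"encoder expects {self.input_dim} columns, got {X.shape[1]}"
            )
        W1, b1, W2, b2 = self.weights
        h = np.tanh(X.astype(np.float32) @ W1 + b1)
        return np.tanh(h @ W2 + b2)


def _dense32(freqs: FrequencyMatrix | np.ndarray, input_norm: str = "none") -> np.ndarray:
    X = freqs.values if isinstance(freqs, FrequencyMatrix) else freqs
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=np.float32)
    if input_norm == "l2":
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        X = X / np.maximum(norms, 1e-12)
    return X


def train_sdnn(
    freqs: FrequencyMatrix, config: SDNNConfig | None = None
) -> tuple[SDNNEncoder, list[float]]:
    """Fit the autoencoder by full-batch Adam on MSE reconstruction loss.

    Returns the trained encoder and the per-epoch loss trace (one value per
    epoch, evaluated at the start of the epoch). Divergence (non-finite loss)
    raises with a hint to lower the learning rate.
    """
    config = config or SDNNConfig()
    X = _dense32(freqs, config.input_norm)
    if X.shape[0] == 0:
        raise ValueError("empty frequency matrix")
    rng = np.random.default_rng(config.seed)
    d_in, d_h, d_e = X.shape[1], config.hidden_dim, config.embedding_dim
    W1 = _glorot(rng, d_in, d_h)
    b1 = np.zeros(d_h, dtype=np.float32)
    W2 = _glorot(rng, d_h, d_e)
    b2 = np.zeros(d_e, dtype=np.float32)
    W3 = _glorot(rng, d_e, d_h)
    b3 = np.zeros(d_h, dtype=np.float32)
    W4 = _glorot(rng, d_h, d_in)
    b4 = np.zeros(d_in, dtype=np.float32)
    params = [W1, b1, W2, b2, W3, b3, W4, b4]
    opt = Adam(params, lr=config.learning_rate)
    trace: list[float] = []
    for _ in range(config.epochs):
        h1 = np.tanh(X @ W1 + b1)
        h2 = np.tanh(h1 @ W2 + b2)
        h3 = np.tanh(h2 @ W3 + b3)
        out = h3 @ W4 + b4
        diff = out - X
        loss = float(np.mean(diff.astype(np.float64) ** 2))
        if not np.isfinite(loss):
            raise FloatingPointError(
                "SDNN reconstruction loss diverged; try a smaller learning_rate"
            )
        trace.append(loss)
        # backprop: d(mean sq err)/d out
        g_out = (2.0 / diff.size) * diff
        gW4 = h3.T @ g_out
        gb4 = g_out.sum(axis=0)
        g_h3 = (g_out @ W4.T) * (1.0 - h3**2)
        gW3 = h2.T @ g_h3
        gb3 = g_h3.sum(axis=0)
        g_h2 = (g_h3 @ W3.T) * (1.0 - h2**2)
        gW2 = h1.T @ g_h2
        gb2 = g_h2.sum(axis=0)
        g_h1 = (g_h2 @ W2.T) * (1.0 - h1**2)
        gW1 = X.T @ g_h1
        gb1 = g_h1.sum(axis=0)
        opt.step([gW1, gb1, gW2, gb2, gW3, gb3, gW4, gb4])
    encoder = SDNNEncoder(weights=[W1, b1, W2, b2], input_dim=d_in, config=config)
    return encoder, trace


def embed(encoder: SDNNEncoder, freqs: FrequencyMatrix) -> EmbeddingMatrix:
    """Map every frequency row through the trained encoder.

    Deterministic given fixed weights; output shape
    (N_miRNA + N_target) x N_embedding in float64.
    """
    X = _dense32(freqs, encoder.config.input_norm)
    Z = encoder.transform(X).astype(np.float64)
    return EmbeddingMatrix(values=Z, row_ids=list(freqs.row_ids), n_mirna=freqs.n_mirna)
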