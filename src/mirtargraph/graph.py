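"""Heterogeneous miRNA-target graph construction and spectral operators.

The graph has two node roles. Within-role edges come from pairwise sequence
similarity (cosine or Jaccard over k-mer profiles, thresholded at 0.5 by
default); between-role edges are the known associations. The adjacency is the
symmetric block matrix

    A_H = [[S_miRNA, A       ],
           [A^T,     S_target]]

over miRNA nodes followed by target nodes. For graph convolution, self-loops
are added and the matrix is symmetrically degree-normalised (the
"renormalization trick"):

    P = D_hat^{-1/2} (I + A_H) D_hat^{-1/2},

with D_hat the degree matrix of I + A_H, so isolated nodes keep P_ii = 1 and
all eigenvalues of P lie in [-1, 1].

A dense eigendecomposition oracle for Chebyshev spectral filters of arbitrary
order K is included for small graphs; with exact lambda_max and matched
first-order coefficients it reproduces P exactly, which is how the runtime
one-layer propagation is validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.metrics.pairwise import cosine_similarity

from .io_formats import AssociationList
from .sdnn import EmbeddingMatrix

__all__ = [
    "SimilarityNetwork",
    "HeterogeneousGraph",
    "NormalizedAdjacency",
    "similarity_network",
    "assemble_graph",
    "normalize",
    "chebyshev_oracle",
    "first_order_coefficients",
    "selfloop_laplacian",
]


@dataclass
class SimilarityNetwork:
    """Thresholded within-role similarity matrix.

    Symmetric, diagonal forced to 1, entries in [0, 1]; every surviving
    off-diagonal entry is >= the threshold (sub-threshold entries are zeroed,
    survivors keep their real value — the graph stays weighted).
    """

    values: np.ndarray
    metric: str
    threshold: float

    @property
    def n(self) -> int:
        return self.values.shape[0]


def similarity_network(
    rows: np.ndarray | sp.spmatrix,
    metric: str = "cosine",
    threshold: float = 0.5,
    binarize: bool = False,
) -> SimilarityNetwork:
    """Pairwise similarity network over the feature rows of one node role.

    cosine: dot(u, v) / (|u||v|), with all-zero rows similar to nothing.
    jaccard: |supp(u) & supp(v)| / |supp(u) | supp(v)| over the sets of
    k-mers with nonzero frequency. Entries below ``threshold`` are set to 0;
    the diagonal is forced to 1. ``binarize=True`` maps survivors to 1.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if metric == "cosine":
        S = cosine_similarity(rows)
        # floating-point slop can push |S| marginally past 1
        np.clip(S, 0.0, 1.0, out=S)
    elif metric == "jaccard":
        B = (rows != 0) if sp.issparse(rows) else sp.csr_matrix(np.asarray(rows) != 0)
        B = B.astype(np.float64)
        inter = np.asarray((B @ B.T).todense())
        sizes = np.asarray(B.sum(axis=1)).ravel()
        union = sizes[:, None] + sizes[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            S = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    else:
        raise ValueError(f"unknown similarity metric {metric!r}")
    S = np.asarray(S, dtype=np.float64)
    S = 0.5 * (S + S.T)
    # ">= threshold" with a tolerance so exact boundary values (e.g. a hand
    # cosine of 1/2) survive floating-point round-off
    S[S < threshold - 1e-12] = 0.0
    if binarize:
        S = (S > 0).astype(np.float64)
    np.fill_diagonal(S, 1.0)
    return SimilarityNetwork(values=S, metric=metric, threshold=threshold)


@dataclass
class HeterogeneousGraph:
    """Block adjacency over miRNA-then-target nodes plus node attributes."""

    A_H: np.ndarray
    association_block: np.ndarray
    node_features: EmbeddingMatrix
    mirna_ids: list[str]
    target_ids: list[str]

    @property
    def n_mirna(self) -> int:
        return len(self.mirna_ids)

    @property
    def n_target(self) -> int:
        return len(self.target_ids)

    @property
    def n_nodes(self) -> int:
        return self.A_H.shape[0]

    def blocks(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(S_miRNA, A, S_target) recovered from A_H."""
        nm = self.n_mirna
        return self.A_H[:nm, :nm], self.A_H[:nm, nm:], self.A_H[nm:, nm:]

    def edge_list(self):
        """Upper-triangle nonzero entries as (node_i, node_j, weight) tuples."""
        ids = self.mirna_ids + self.target_ids
        iu, ju = np.nonzero(np.triu(self.A_H, k=1))
        return [(ids[i], ids[j], float(self.A_H[i, j])) for i, j in zip(iu, ju)]


def assemble_graph(
    S_mirna: SimilarityNetwork,
    S_target: SimilarityNetwork,
    associations: AssociationList,
    features: EmbeddingMatrix,
) -> HeterogeneousGraph:
    """Assemble the symmetric block adjacency from its three components.

    ``associations`` should already be restricted to training-fold positives
    when the graph is used inside cross-validation, so held-out edges never
    appear in the adjacency.
    """
    nm, nt = S_mirna.n, S_target.n
    if features.values.shape[0] != nm + nt:
        raise ValueError(
            f"feature rows ({features.values.shape[0]}) != n_mirna + n_target ({nm + nt})"
        )
    if features.n_mirna != nm:
        raise ValueError("feature matrix role split does not match similarity blocks")
    mirna_ids = features.row_ids[:nm]
    target_ids = features.row_ids[nm:]
    m_index = {mid: i for i, mid in enumerate(mirna_ids)}
    t_index = {tid: j for j, tid in enumerate(target_ids)}
    A = np.zeros((nm, nt))
    for m, t in associations:
        if m not in m_index or t not in t_index:
            raise ValueError(f"association ({m}, {t}) references unknown node")
        A[m_index[m], t_index[t]] = 1.0
    A_H = np.block([[S_mirna.values, A], [A.T, S_target.values]])
    return HeterogeneousGraph(
        A_H=A_H,
        association_block=A,
        node_features=features,
        mirna_ids=list(mirna_ids),
        target_ids=list(target_ids),
    )


@dataclass
class NormalizedAdjacency:
    """P = D_hat^{-1/2} (I + A_H) D_hat^{-1/2} and its ingredients."""

    P: np.ndarray
    degree: np.ndarray  # diagonal of D_hat, degrees of I + A_H


def normalize(graph: HeterogeneousGraph | np.ndarray) -> NormalizedAdjacency:
    """Self-loop and symmetrically degree-normalise the adjacency.

    Degrees are taken from (I + A_H) rather than A_H so isolated nodes get
    degree 1 instead of 0 and P_ii = 1 for them; all eigenvalues of P lie in
    [-1, 1].
    """
    A = graph.A_H if isinstance(graph, HeterogeneousGraph) else np.asarray(graph)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if np.any(A < 0):
        raise ValueError("adjacency entries must be non-negative")
    A_hat = A + np.eye(A.shape[0])
    deg = A_hat.sum(axis=1)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    P = A_hat * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]
    P = 0.5 * (P + P.T)  # exact symmetry against rounding
    return NormalizedAdjacency(P=P, degree=deg)


def selfloop_laplacian(A: np.ndarray) -> np.ndarray:
    """Symmetric normalised Laplacian of the self-looped graph: L = I - P."""
    return np.eye(A.shape[0]) - normalize(A).P


def first_order_coefficients(lam_max: float) -> np.ndarray:
    """Chebyshev coefficients (theta_0, theta_1) whose K=1 filter equals P.

    With L = I - P, eigenvalue rescaling lam_tilde = 2 lam / lam_max - 1 and
    the filter theta_0 T_0 + theta_1 T_1, solving for the filter I - L gives
    theta_0 = 1 - lam_max / 2 and theta_1 = -lam_max / 2.
    """
    return np.array([1.0 - lam_max / 2.0, -lam_max / 2.0])


def chebyshev_oracle(
    A: np.ndarray,
    features: np.ndarray,
    K: int,
    theta: np.ndarray,
    lam_max: float | None = None,
) -> np.ndarray:
    """Spectral Chebyshev filter of order K via dense eigendecomposition.

    Intended as a small-graph test oracle (node count <= a few hundred).
    Builds L = I - P from the self-looped, degree-normalised graph,
    eigendecomposes L = U diag(lam) U^T, rescales the spectrum to [-1, 1]
    with lam_max (exact spectral maximum when not given), evaluates
    sum_k theta_k T_k(lam_tilde) on the eigenvalues by the recurrence
    T_k = 2 x T_{k-1} - T_{k-2}, and maps the filtered spectrum back:
    U diag(filter) U^T @ features.
    """
    A = np.asarray(A, dtype=np.float64)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("oracle requires a symmetric adjacency")
    theta = np.asarray(theta, dtype=np.float64)
    if theta.shape != (K + 1,):
        raise ValueError(f"need K+1 = {K + 1} coefficients, got {theta.shape}")
    L = selfloop_laplacian(A)
    lam, U = np.linalg.eigh(L)
    if lam_max is None:
        lam_max = float(lam.max())
    if lam_max <= 0:
        raise ValueError("lam_max must be positive")
    lam_tilde = 2.0 * lam / lam_max - 1.0
    T_prev = np.ones_like(lam_tilde)  # T_0
    filt = theta[0] * T_prev
    if K >= 1:
        T_cur = lam_tilde.copy()  # T_1
        filt = filt + theta[1] * T_cur
        for k in range(2, K + 1):
            T_next = 2.0 * lam_tilde * T_cur - T_prev
            filt = filt + theta[k] * T_next
            T_prev, T_cur = T_cur, T_next
    return (U * filt) @ U.T @ np.asarray(features, dtype=np.float64)
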