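"""Multiple-maps t-SNE state and its regularized objective.

The low-dimensional model places every point in M two-dimensional maps. Point
i carries an importance weight pi_i^(m) per map — a negative-exponent softmax
of unconstrained weights omega_i^(m), so weights are positive and sum to 1
across maps. The model similarity between points i and j is the weight-mixed
Student-t kernel

    q_ij = sum_m pi_i^(m) pi_j^(m) (1 + ||y_i^(m) - y_j^(m)||^2)^-1 / Z,

with Z normalizing over all ordered pairs and maps. A pair can have q_ij = 0
even when both points are close to a shared third point in different maps —
the intransitive-similarity geometry a single metric map cannot express.

The objective blends the Kullback-Leibler divergence KL(P||Q) with a graph-
Laplacian quadratic penalty on the weights,

    C = (1 - lambda) KL(P||Q) + lambda * sum_m pi_(.,m)^T L pi_(.,m),

where L = diag(P 1) - P is the Laplacian of the affinity graph, pushing
strongly-similar points to occupy the same maps. Gradients with respect to
positions and unconstrained weights are analytic; their correctness is pinned
by finite-difference tests rather than trusted typography.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .affinity import JointProbabilities

__all__ = [
    "MultiMapEmbedding",
    "ImportanceWeights",
    "PairwiseQ",
    "LaplacianMatrix",
    "CostBreakdown",
    "importance_weights",
    "compute_q",
    "graph_laplacian",
    "regularized_cost",
    "grad_positions",
    "grad_weights",
]

# q floor used only inside logs / denominators, never stored
_Q_FLOOR = 1e-12


@dataclass(frozen=True)
class MultiMapEmbedding:
    """Positions ``Y`` (n x M x 2) and unconstrained weights ``Omega`` (n x M)."""

    ids: tuple[str, ...]
    Y: np.ndarray
    Omega: np.ndarray

    def __post_init__(self):
        Y = np.asarray(self.Y, dtype=float)
        Omega = np.asarray(self.Omega, dtype=float)
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "Omega", Omega)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if Y.ndim != 3 or Y.shape[2] != 2:
            raise ValueError("Y must have shape (n, n_maps, 2)")
        n, M, _ = Y.shape
        if Omega.shape != (n, M):
            raise ValueError("Omega must have shape (n, n_maps)")
        if M < 1:
            raise ValueError("need at least one map")
        if not (np.all(np.isfinite(Y)) and np.all(np.isfinite(Omega))):
            raise ValueError("embedding state must be finite")
        if len(self.ids) != n:
            raise ValueError("ids length must match n")

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def n_maps(self) -> int:
        return self.Y.shape[1]

    @property
    def pi(self) -> np.ndarray:
        return importance_weights(self.Omega).Pi


@dataclass(frozen=True)
class ImportanceWeights:
    """Per-point map weights: nonnegative rows summing to 1."""

    Pi: np.ndarray


@dataclass(frozen=True)
class PairwiseQ:
    """Model similarities Q, normalizer Z, squared-distance tensor ``Dm``."""

    Q: np.ndarray
    Z: float
    Dm: np.ndarray


@dataclass(frozen=True)
class LaplacianMatrix:
    """Graph Laplacian of P: symmetric, zero row sums, positive semidefinite."""

    L: np.ndarray


@dataclass(frozen=True)
class CostBreakdown:
    """Objective value split into its KL and Laplacian-penalty terms."""

    total: float
    kl_term: float
    penalty_term: float
    lam: float


def importance_weights(Omega: np.ndarray) -> ImportanceWeights:
    """Negative-exponent softmax per row: pi_i^(m) = e^{-w_i^(m)} / sum_m' e^{-w_i^(m')}.

    Stabilized by subtracting each row's minimum omega (the largest exponent)
    before exponentiation.
    """
    Omega = np.asarray(Omega, dtype=float)
    if Omega.ndim == 1:
        Omega = Omega[None, :]
    shifted = -(Omega - Omega.min(axis=1, keepdims=True))
    E = np.exp(shifted)
    return ImportanceWeights(Pi=E / E.sum(axis=1, keepdims=True))


def _map_distances(Y: np.ndarray) -> np.ndarray:
    """Squared Euclidean distances per map: (n, n, M) tensor."""
    n, M, _ = Y.shape
    Dm = np.empty((n, n, M))
    for m in range(M):
        diff = Y[:, m, None, :] - Y[None, :, m, :]
        Dm[:, :, m] = np.einsum("ijk,ijk->ij", diff, diff)
    return Dm


def compute_q(embedding: MultiMapEmbedding) -> PairwiseQ:
    """Weight-mixed Student-t similarities and their joint normalizer Z."""
    Pi = embedding.pi
    Dm = _map_distances(embedding.Y)
    T = 1.0 / (1.0 + Dm)  # (n, n, M) Student-t kernels
    W = np.einsum("im,jm->ijm", Pi, Pi)
    N = np.einsum("ijm,ijm->ij", W, T)
    np.fill_diagonal(N, 0.0)
    Z = float(N.sum())
    return PairwiseQ(Q=N / Z, Z=Z, Dm=Dm)


def graph_laplacian(P: JointProbabilities | np.ndarray) -> LaplacianMatrix:
    """L = diag(row sums of P) - P."""
    Pm = P.P if isinstance(P, JointProbabilities) else np.asarray(P, dtype=float)
    return LaplacianMatrix(L=np.diag(Pm.sum(axis=1)) - Pm)


def _penalty(Pi: np.ndarray, L: np.ndarray) -> float:
    # quadratic form summed over map columns: permutation-invariant over maps
    return float(np.einsum("im,ij,jm->", Pi, L, Pi))


def regularized_cost(
    P: JointProbabilities | np.ndarray,
    embedding: MultiMapEmbedding,
    lam: float = 0.0,
    q: PairwiseQ | None = None,
) -> CostBreakdown:
    """(1-lambda) KL(P||Q) + lambda sum_m pi_m^T L pi_m, with 0 log 0 = 0."""
    if not 0.0 <= lam < 1.0:
        raise ValueError("lambda must lie in [0, 1)")
    Pm = P.P if isinstance(P, JointProbabilities) else np.asarray(P, dtype=float)
    q = q or compute_q(embedding)
    mask = Pm > 0
    kl = float(
        np.sum(Pm[mask] * (np.log(Pm[mask]) - np.log(np.maximum(q.Q[mask], _Q_FLOOR))))
    )
    pen = _penalty(embedding.pi, graph_laplacian(Pm).L)
    return CostBreakdown(
        total=(1.0 - lam) * kl + lam * pen, kl_term=kl, penalty_term=pen, lam=lam
    )


def grad_positions(
    P: JointProbabilities | np.ndarray,
    embedding: MultiMapEmbedding,
    lam: float = 0.0,
    q: PairwiseQ | None = None,
) -> np.ndarray:
    """Analytic gradient of the objective w.r.t. every map position y_i^(m).

    dC/dy_i^(m) = 4 (1-lambda) sum_j [(p_ij - q_ij)/(q_ij Z)] pi_i^(m) pi_j^(m)
                  (1 + d_ij^(m))^-2 (y_i^(m) - y_j^(m)).
    """
    Pm = P.P if isinstance(P, JointProbabilities) else np.asarray(P, dtype=float)
    q = q or compute_q(embedding)
    Pi = embedding.pi
    Y = embedding.Y
    n, M, _ = Y.shape
    R = (Pm - q.Q) / (np.maximum(q.Q, _Q_FLOOR) * q.Z)  # (p-q)/(qZ)
    np.fill_diagonal(R, 0.0)
    grad = np.empty_like(Y)
    for m in range(M):
        t2 = 1.0 / (1.0 + q.Dm[:, :, m]) ** 2
        A = R * np.outer(Pi[:, m], Pi[:, m]) * t2
        np.fill_diagonal(A, 0.0)
        diff = Y[:, m, None, :] - Y[None, :, m, :]
        grad[:, m, :] = 4.0 * (1.0 - lam) * np.einsum("ij,ijk->ik", A, diff)
    return grad


def grad_weights(
    P: JointProbabilities | np.ndarray,
    embedding: MultiMapEmbedding,
    lam: float = 0.0,
    q: PairwiseQ | None = None,
) -> np.ndarray:
    """Analytic gradient of the objective w.r.t. the unconstrained weights Omega.

    The derivative w.r.t. pi_i^(m) of the KL term is
    -2 (1-lambda) sum_j [(p_ij - q_ij)/(q_ij Z)] pi_j^(m) (1 + d_ij^(m))^-1
    and of the penalty term 2 lambda (L pi_(.,m))_i; this is then pushed
    through the Jacobian of the negative-exponent softmax,
    d pi^(m) / d omega^(l) = pi^(m) pi^(l) - delta_ml pi^(m).
    """
    Pm = P.P if isinstance(P, JointProbabilities) else np.asarray(P, dtype=float)
    q = q or compute_q(embedding)
    Pi = embedding.pi
    n, M = Pi.shape
    R = (Pm - q.Q) / (np.maximum(q.Q, _Q_FLOOR) * q.Z)
    np.fill_diagonal(R, 0.0)
    T = 1.0 / (1.0 + q.Dm)  # (n, n, M)
    # dC/dpi: (n, M)
    g_pi = -2.0 * (1.0 - lam) * np.einsum("ij,jm,ijm->im", R, Pi, T)
    if lam > 0:
        L = graph_laplacian(Pm).L
        g_pi = g_pi + 2.0 * lam * (L @ Pi)
    # chain through the Jacobian of pi = softmax(-omega)
    dot = np.sum(g_pi * Pi, axis=1, keepdims=True)  # sum_m g_m pi_m per point
    return Pi * (dot - g_pi)
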