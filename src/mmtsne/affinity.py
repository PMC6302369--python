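"""High-dimensional affinities: turning raw inputs into the joint distribution P.

Two input paths are supported. Numeric feature vectors are converted with a
Gaussian kernel, either with one global bandwidth ``sigma`` or with per-point
bandwidths found by a perplexity bisection (the usual t-SNE calibration). A
precomputed similarity matrix in [0, 1] — the form in which disease-phenotype
or KO-profile similarities typically arrive — is thresholded and renormalized
directly, since such scores are not distances and re-kernelizing them would
discard the scale the upstream pipeline established.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VectorDataset",
    "RawSimilarityMatrix",
    "AffinityConfig",
    "JointProbabilities",
    "gaussian_joint_probabilities",
    "similarity_to_joint_probabilities",
    "read_similarity",
    "read_vectors",
    "write_similarity",
]

_SYM_TOL = 1e-9


class InputError(ValueError):
    """Raised on malformed numeric input (non-finite, asymmetric, out of range)."""


class ConfigError(ValueError):
    """Raised on invalid configuration values."""


class DegenerateInputError(ValueError):
    """Raised when filtering leaves no similarity mass to normalize."""


@dataclass(frozen=True)
class VectorDataset:
    """Feature vectors for n entities: ``X`` is n x d, ``ids`` has length n."""

    ids: tuple[str, ...]
    X: np.ndarray

    def __post_init__(self):
        X = np.asarray(self.X, dtype=float)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 1:
            raise InputError("X must be n x d with n >= 2, d >= 1")
        if not np.all(np.isfinite(X)):
            raise InputError("feature matrix contains non-finite entries")
        if len(self.ids) != X.shape[0]:
            raise InputError("ids length must match number of rows")
        if len(set(self.ids)) != len(self.ids):
            raise InputError("ids must be unique")

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class RawSimilarityMatrix:
    """Symmetric nonnegative similarity scores in [0, 1]; diagonal is ignored."""

    ids: tuple[str, ...]
    S: np.ndarray

    def __post_init__(self):
        S = np.asarray(self.S, dtype=float)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        n = S.shape[0]
        if S.ndim != 2 or S.shape[1] != n or n < 2:
            raise InputError("S must be square with n >= 2")
        if len(self.ids) != n or len(set(self.ids)) != n:
            raise InputError("ids must be unique and match S")
        if not np.all(np.isfinite(S)):
            raise InputError("similarity matrix contains non-finite entries")
        off = ~np.eye(n, dtype=bool)
        if np.any(S[off] < 0) or np.any(S[off] > 1):
            raise InputError("off-diagonal similarities must lie in [0, 1]")
        if np.max(np.abs(S - S.T)) > _SYM_TOL:
            raise InputError("similarity matrix is not symmetric")

    @property
    def n(self) -> int:
        return self.S.shape[0]


@dataclass(frozen=True)
class AffinityConfig:
    """How affinities are computed.

    mode
        ``"global_sigma"`` uses one Gaussian bandwidth ``sigma`` for every
        point; ``"perplexity"`` calibrates a per-point bandwidth so each
        conditional distribution has the requested perplexity.
    similarity_threshold
        Entries strictly below this are zeroed before normalizing a raw
        similarity matrix (default 0.5, the filtering rule applied to the
        phenotype and KO matrices this tool targets).
    """

    mode: str = "perplexity"
    sigma: float = 1.0
    perplexity: float = 30.0
    similarity_threshold: float = 0.5

    def __post_init__(self):
        if self.mode not in ("global_sigma", "perplexity"):
            raise ConfigError(f"unknown affinity mode {self.mode!r}")
        if self.mode == "global_sigma" and not self.sigma > 0:
            raise ConfigError("sigma must be positive")
        if self.mode == "perplexity" and not self.perplexity > 1:
            raise ConfigError("perplexity must exceed 1")
        if not 0.0 <= self.similarity_threshold <= 1.0:
            raise ConfigError("similarity_threshold must lie in [0, 1]")


@dataclass(frozen=True)
class JointProbabilities:
    """The joint distribution P: p_ij >= 0, zero diagonal, symmetric, sums to 1."""

    ids: tuple[str, ...]
    P: np.ndarray
    disconnected: tuple[str, ...] = field(default=())

    def __post_init__(self):
        P = np.asarray(self.P, dtype=float)
        object.__setattr__(self, "P", P)
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(self, "disconnected", tuple(self.disconnected))
        n = P.shape[0]
        if P.ndim != 2 or P.shape[1] != n:
            raise InputError("P must be square")
        if np.any(P < 0) or np.any(np.abs(np.diag(P)) > 0):
            raise InputError("P must be nonnegative with zero diagonal")
        if np.max(np.abs(P - P.T)) > _SYM_TOL:
            raise InputError("P must be symmetric")
        if abs(P.sum() - 1.0) > _SYM_TOL:
            raise InputError("P must sum to 1 over ordered pairs")

    @property
    def n(self) -> int:
        return self.P.shape[0]

    def fingerprint(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.P).tobytes())
        h.update("|".join(self.ids).encode())
        return h.hexdigest()[:16]


def _squared_distances(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X * X, axis=1)
    D = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(D, 0.0)
    return np.maximum(D, 0.0)


def _conditional_row(d_row: np.ndarray, beta: float) -> np.ndarray:
    # beta = 1/(2 sigma_i^2); stabilized softmax over the off-diagonal entries
    logits = -beta * d_row
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def _row_entropy(d_row: np.ndarray, beta: float) -> float:
    p = _conditional_row(d_row, beta)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _bisect_beta(d_row: np.ndarray, target_log2_perp: float, tol: float = 1e-6,
                 max_iter: int = 200) -> float:
    """Find beta so the conditional row has Shannon entropy target_log2_perp bits."""
    lo, hi = 0.0, np.inf
    beta = 1.0
    for _ in range(max_iter):
        h = _row_entropy(d_row, beta)
        err = h - target_log2_perp
        if abs(err) < tol:
            break
        if err > 0:  # entropy too high -> sharpen
            lo = beta
            beta = beta * 2.0 if not np.isfinite(hi) else 0.5 * (beta + hi)
        else:
            hi = beta
            beta = beta / 2.0 if lo == 0.0 else 0.5 * (beta + lo)
    return beta


def gaussian_joint_probabilities(
    data: VectorDataset, config: AffinityConfig
) -> JointProbabilities:
    """Gaussian affinities over feature vectors.

    In ``global_sigma`` mode the kernel exp(-||x_i - x_j||^2 / (2 sigma^2)) is
    normalized jointly over all ordered pairs. In ``perplexity`` mode each row's
    bandwidth is bisected to the target perplexity and the conditionals are
    symmetrized as p_ij = (p_{j|i} + p_{i|j}) / (2n).
    """
    n = data.n
    D = _squared_distances(data.X)
    if config.mode == "global_sigma":
        logits = -D / (2.0 * config.sigma**2)
        np.fill_diagonal(logits, -np.inf)
        logits -= np.max(logits[np.isfinite(logits)])
        K = np.exp(logits)
        np.fill_diagonal(K, 0.0)
        P = K / K.sum()
    else:
        if config.perplexity >= n:
            raise ConfigError("perplexity must be smaller than the number of points")
        target = float(np.log2(config.perplexity))
        cond = np.zeros((n, n))
        for i in range(n):
            d_row = np.delete(D[i], i)
            beta = _bisect_beta(d_row, target)
            row = _conditional_row(d_row, beta)
            cond[i, np.arange(n) != i] = row
        P = (cond + cond.T) / (2.0 * n)
    P = 0.5 * (P + P.T)
    P /= P.sum()
    np.fill_diagonal(P, 0.0)
    P /= P.sum()
    return JointProbabilities(ids=data.ids, P=P)


def similarity_to_joint_probabilities(
    sim: RawSimilarityMatrix, config: AffinityConfig | None = None
) -> JointProbabilities:
    """Threshold-then-normalize a raw [0, 1] similarity matrix into P.

    Entries strictly below ``similarity_threshold`` are zeroed, the diagonal is
    dropped, and the remaining mass is scaled to sum to 1 over ordered pairs.
    Entities whose every similarity is filtered out are reported in the result's
    ``disconnected`` metadata.
    """
    config = config or AffinityConfig()
    S = sim.S.copy()
    np.fill_diagonal(S, 0.0)
    S[S < config.similarity_threshold] = 0.0
    total = S.sum()
    if total <= 0:
        raise DegenerateInputError(
            "all similarities fall below the threshold; no mass to normalize"
        )
    P = 0.5 * (S + S.T) / total
    disconnected = tuple(
        sim.ids[i] for i in range(sim.n) if not np.any(P[i] > 0)
    )
    return JointProbabilities(ids=sim.ids, P=P, disconnected=disconnected)


# ---------------------------------------------------------------------------
# File I/O: TSV/CSV with auto-detected delimiter


def _sniff_sep(path) -> str:
    with open(path, "r") as fh:
        first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_similarity(path) -> RawSimilarityMatrix:
    """Read a square similarity matrix with header row and id column."""
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    ids = [str(c) for c in df.columns]
    row_ids = [str(r) for r in df.index]
    if ids != row_ids:
        raise InputError("row and column identifiers disagree")
    return RawSimilarityMatrix(ids=tuple(ids), S=df.to_numpy(dtype=float))


def read_vectors(path) -> VectorDataset:
    """Read a numeric feature matrix; first column of ids if non-numeric."""
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep)
    first = df.columns[0]
    if not np.issubdtype(df[first].dtype, np.number):
        df = df.set_index(first)
        ids = tuple(str(i) for i in df.index)
    else:
        ids = tuple(str(i) for i in range(len(df)))
    return VectorDataset(ids=ids, X=df.to_numpy(dtype=float))


def write_similarity(sim: RawSimilarityMatrix, path) -> None:
    df = pd.DataFrame(sim.S, index=list(sim.ids), columns=list(sim.ids))
    df.to_csv(path, sep="\t")
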