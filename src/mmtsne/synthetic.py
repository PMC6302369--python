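"""Synthetic data with known ground truth.

Real phenotype- and KO-similarity matrices are intransitive: a phenotype can
share symptoms with members of two disease categories that share nothing with
each other, so triples (a, b, c) arise with s(a,c) > 0, s(b,c) > 0 but
s(a,b) = 0. The generators here build such structure deliberately — clusters
with a controllable fraction of "bridge" points belonging to two clusters —
plus a three-point/two-map fixture reproducing the canonical textbook case
where a pair's mixed similarity is exactly zero because the two points have
disjoint map assignments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .affinity import RawSimilarityMatrix, VectorDataset
from .core import MultiMapEmbedding

__all__ = [
    "OverlapClusterSpec",
    "GroundTruth",
    "fig_fixture_three_points",
    "overlapping_cluster_similarity",
    "transitivity_violations",
    "gaussian_cluster_vectors",
]

# omega offset that saturates the negative-exponent softmax: e^-80 relative
# weight, far below double precision of the q entries it feeds
_SATURATE = 40.0


@dataclass(frozen=True)
class OverlapClusterSpec:
    """Overlapping-cluster similarity generator parameters.

    ``overlap_fraction`` of the points are bridges belonging to exactly two
    clusters; ``within_similarity`` must exceed the 0.5 filtering threshold so
    the signal survives thresholding.
    """

    n_clusters: int = 2
    points_per_cluster: int = 4
    overlap_fraction: float = 0.25
    within_similarity: float = 0.8
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 2 or self.points_per_cluster < 2:
            raise ValueError("need at least 2 clusters of at least 2 points")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")
        if not 0.5 < self.within_similarity <= 1.0:
            raise ValueError("within_similarity must lie in (0.5, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass(frozen=True)
class GroundTruth:
    """Cluster memberships per point: a set of 1 or 2 labels each."""

    memberships: tuple[frozenset[int], ...]


def fig_fixture_three_points() -> tuple[MultiMapEmbedding, dict]:
    """Three points A, B, C in two maps with weights (1,0), (0,1), (0.5,0.5).

    A lives only in map 1 (next to C), B only in map 2 (also next to C), so
    the mixed similarity q_AB is zero while q_AC and q_BC are both positive —
    an intransitive triple no single metric map can realize. Exact 0/1
    weights are unreachable for a softmax, so the omegas are offset by -+40,
    saturating the weights to within 1e-17.
    """
    ids = ("A", "B", "C")
    Y = np.array(
        [
            [[0.0, 0.0], [5.0, 5.0]],   # A: near C in map 1, far away in map 2
            [[5.0, 5.0], [0.0, 0.0]],   # B: near C in map 2
            [[0.5, 0.0], [0.5, 0.0]],   # C: central in both maps
        ]
    )
    Omega = np.array(
        [
            [-_SATURATE, _SATURATE],
            [_SATURATE, -_SATURATE],
            [0.0, 0.0],
        ]
    )
    emb = MultiMapEmbedding(ids=ids, Y=Y, Omega=Omega)
    expected = {
        "pi": np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]]),
        "q_AB": 0.0,
    }
    return emb, expected


def overlapping_cluster_similarity(
    spec: OverlapClusterSpec,
) -> tuple[RawSimilarityMatrix, GroundTruth]:
    """Similarity matrix where points sharing a cluster are similar, others 0.

    s_ij = within_similarity + Gaussian noise (clipped to [0, 1]) when i and j
    share at least one cluster label, else 0. Bridge points carry two labels
    and are the non-metric glue between otherwise disjoint blocks.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_clusters * spec.points_per_cluster
    n_bridge = int(round(spec.overlap_fraction * n))
    memberships = [
        frozenset({i // spec.points_per_cluster}) for i in range(n)
    ]
    # spread bridges round-robin over clusters so every cluster keeps pure
    # members; bridge k is the (k // n_clusters)-th point of cluster k % n_clusters
    for k in range(n_bridge):
        c = k % spec.n_clusters
        i = c * spec.points_per_cluster + k // spec.n_clusters
        memberships[i] = frozenset({c, (c + 1) % spec.n_clusters})
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if memberships[i] & memberships[j]:
                s = spec.within_similarity + rng.normal(0.0, spec.noise_sd)
                S[i, j] = S[j, i] = float(np.clip(s, 0.0, 1.0))
    np.fill_diagonal(S, 1.0)
    ids = tuple(f"pt{i:03d}" for i in range(n))
    return (
        RawSimilarityMatrix(ids=ids, S=S),
        GroundTruth(memberships=tuple(memberships)),
    )


def transitivity_violations(sim: RawSimilarityMatrix, threshold: float = 0.5) -> int:
    """Count unordered triples with exactly two positive similarities at or
    above threshold and the third equal to 0 — the intransitive
    configurations in the matrix.

    Exhaustive O(n^3) enumeration; intended for fixture-scale matrices.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    S = sim.S
    count = 0
    for i, j, k in itertools.combinations(range(sim.n), 3):
        edges = [S[i, j], S[i, k], S[j, k]]
        n_strong = sum(e >= threshold and e > 0 for e in edges)
        n_zero = sum(e == 0.0 for e in edges)
        if n_strong == 2 and n_zero == 1:
            count += 1
    return count


def gaussian_cluster_vectors(
    n_clusters: int = 3,
    points_per_cluster: int = 10,
    separation: float = 10.0,
    seed: int = 0,
    n_features: int = 2,
) -> VectorDataset:
    """Isotropic unit-variance Gaussian blobs around equally spaced centers."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    centers = np.zeros((n_clusters, n_features))
    centers[:, 0] = separation * np.arange(n_clusters)
    X = np.vstack(
        [
            centers[c] + rng.normal(size=(points_per_cluster, n_features))
            for c in range(n_clusters)
        ]
    )
    ids = tuple(f"pt{i:03d}" for i in range(X.shape[0]))
    return VectorDataset(ids=ids, X=X)
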