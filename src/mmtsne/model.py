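"""Model/Results interface over the multiple-maps embedding machinery.

``MultipleMapsTSNE`` is constructed from data (a similarity matrix, feature
vectors, or a ready-made joint distribution P) plus the model parameters —
the number of maps M and the Laplacian penalty weight lambda. ``fit`` runs
the chosen optimizer and returns a ``MultipleMapsTSNEResults`` carrying the
fitted positions, importance weights, cost trace and quality metrics, with a
``summary()`` in the spirit of statsmodels results objects.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .affinity import (
    AffinityConfig,
    JointProbabilities,
    RawSimilarityMatrix,
    VectorDataset,
    gaussian_joint_probabilities,
    similarity_to_joint_probabilities,
)
from .core import compute_q, regularized_cost
from .evaluate import error_rate, evaluate, neighborhood_preservation_ratio
from .optim import FitResult, OptimizerConfig, fit as _fit, iterations_to_within

__all__ = ["MultipleMapsTSNE", "MultipleMapsTSNEResults"]


class MultipleMapsTSNE:
    """Multiple-maps t-SNE with a graph-Laplacian penalty on map weights.

    Parameters
    ----------
    P : JointProbabilities
        The high-dimensional joint distribution to be matched.
    n_maps : int
        Number of 2-D maps M.
    lam : float
        Penalty weight lambda in [0, 1); 0 disables the Laplacian term.
    """

    def __init__(self, P: JointProbabilities, n_maps: int = 2, lam: float = 0.0):
        if n_maps < 1:
            raise ValueError("n_maps must be at least 1")
        if not 0.0 <= lam < 1.0:
            raise ValueError("lambda must lie in [0, 1)")
        self.P = P
        self.n_maps = n_maps
        self.lam = lam

    @classmethod
    def from_similarity(
        cls,
        sim: RawSimilarityMatrix,
        n_maps: int = 2,
        lam: float = 0.0,
        similarity_threshold: float = 0.5,
    ) -> "MultipleMapsTSNE":
        config = AffinityConfig(similarity_threshold=similarity_threshold)
        return cls(similarity_to_joint_probabilities(sim, config), n_maps, lam)

    @classmethod
    def from_vectors(
        cls,
        data: VectorDataset,
        n_maps: int = 2,
        lam: float = 0.0,
        affinity: AffinityConfig | None = None,
    ) -> "MultipleMapsTSNE":
        config = affinity or AffinityConfig(
            mode="perplexity", perplexity=min(30.0, (data.n - 1) / 3)
        )
        return cls(gaussian_joint_probabilities(data, config), n_maps, lam)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, n_maps: int = 2, lam: float = 0.0, **kwargs
    ) -> "MultipleMapsTSNE":
        """Square symmetric frame -> similarity path; otherwise feature vectors."""
        arr = df.to_numpy(dtype=float)
        ids = tuple(str(i) for i in df.index)
        if arr.shape[0] == arr.shape[1] and np.allclose(arr, arr.T, atol=1e-9):
            return cls.from_similarity(
                RawSimilarityMatrix(ids=ids, S=arr), n_maps, lam, **kwargs
            )
        return cls.from_vectors(VectorDataset(ids=ids, X=arr), n_maps, lam, **kwargs)

    def fit(
        self, config: OptimizerConfig | None = None, **kwargs
    ) -> "MultipleMapsTSNEResults":
        """Run the optimizer; keyword arguments override OptimizerConfig fields."""
        config = config or OptimizerConfig()
        if kwargs:
            config = replace(config, **kwargs)
        result = _fit(self.P, self.n_maps, self.lam, config)
        return MultipleMapsTSNEResults(self, result, config)


class MultipleMapsTSNEResults:
    """Fitted multiple-maps embedding with diagnostics."""

    def __init__(
        self, model: MultipleMapsTSNE, result: FitResult, config: OptimizerConfig
    ):
        self.model = model
        self.result = result
        self.config = config
        self.embedding = result.embedding
        self.q = compute_q(result.embedding)

    @property
    def importance_weights(self) -> np.ndarray:
        return self.embedding.pi

    @property
    def positions(self) -> np.ndarray:
        return self.embedding.Y

    @property
    def cost_trace(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "iter": t,
                    "total": c.total,
                    "kl_term": c.kl_term,
                    "penalty_term": c.penalty_term,
                }
                for t, c in enumerate(self.result.cost_trace)
            ]
        )

    @property
    def final_cost(self) -> float:
        return self.result.cost_trace[-1].total

    def error_rate(self) -> float:
        return error_rate(self.model.P, self.q)

    def npr(self, k: int = 10) -> float:
        return neighborhood_preservation_ratio(self.model.P, self.q, k)

    def iterations_to_convergence(self, rel_tol: float = 0.01) -> int:
        return iterations_to_within(self.result.cost_trace, rel_tol)

    def embedding_table(self, min_weight: float = 0.0) -> pd.DataFrame:
        """One row per (point, map): id, map_index (1-based), x, y, weight.

        ``min_weight`` filters out rows whose importance weight falls below it,
        the usual de-cluttering rule when plotting maps.
        """
        Pi = self.importance_weights
        rows = []
        for i, pid in enumerate(self.embedding.ids):
            for m in range(self.embedding.n_maps):
                if Pi[i, m] >= min_weight:
                    rows.append(
                        {
                            "id": pid,
                            "map_index": m + 1,
                            "x": self.embedding.Y[i, m, 0],
                            "y": self.embedding.Y[i, m, 1],
                            "importance_weight": Pi[i, m],
                        }
                    )
        return pd.DataFrame(rows)

    def summary(self, k: int = 10) -> str:
        final = self.result.cost_trace[-1]
        lines = [
            "Multiple-maps t-SNE results",
            "=" * 45,
            f"points                 {self.embedding.n}",
            f"maps (M)               {self.embedding.n_maps}",
            f"lambda                 {self.model.lam}",
            f"optimizer              {self.result.rule}",
            f"iterations             {len(self.result.cost_trace)}",
            f"final total cost       {final.total:.6f}",
            f"final KL term          {final.kl_term:.6f}",
            f"final penalty term     {final.penalty_term:.6f}",
            f"KL error rate          {self.error_rate():.6f}",
        ]
        if self.embedding.n > k:
            lines.append(f"NPR (k={k})             {self.npr(k):.4f}")
        lines.append(
            f"iters to 1% of final   {self.iterations_to_convergence()}"
        )
        return "\n".join(lines)

    def plot_maps(self, min_weight: float = 0.1, axes=None):
        """Scatter each map, marker size scaled by importance weight."""
        import matplotlib.pyplot as plt

        M = self.embedding.n_maps
        if axes is None:
            _, axes = plt.subplots(1, M, figsize=(4 * M, 4), squeeze=False)
            axes = axes[0]
        Pi = self.importance_weights
        for m, ax in enumerate(axes[:M]):
            keep = Pi[:, m] >= min_weight
            ax.scatter(
                self.embedding.Y[keep, m, 0],
                self.embedding.Y[keep, m, 1],
                s=200 * Pi[keep, m],
                alpha=0.7,
            )
            ax.set_title(f"Map {m + 1}")
        return axes
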