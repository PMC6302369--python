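"""Embedding quality metrics: neighborhood preservation and KL error rate.

The neighborhood preservation ratio (NPR) measures rank agreement between the
high-dimensional affinities P and the model similarities Q: for each point,
the fraction of its k strongest P-neighbors that are also among its k
strongest Q-neighbors, averaged over points. The error rate is the KL
divergence KL(P||Q) itself — the quantity the fit minimizes — in natural-log
units. Together with iterations-to-convergence these are the indicators used
to compare optimizers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .affinity import JointProbabilities
from .core import PairwiseQ

__all__ = [
    "EvaluationReport",
    "neighborhood_preservation_ratio",
    "error_rate",
    "compare_runs",
]

_LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class EvaluationReport:
    """NPR and KL error rate for one fitted embedding."""

    npr: float
    error_rate: float
    k: int
    n: int

    def to_dict(self) -> dict:
        return {
            "npr": self.npr,
            "error_rate": self.error_rate,
            "k": self.k,
            "n": self.n,
        }


def _as_matrix(obj) -> np.ndarray:
    if isinstance(obj, JointProbabilities):
        return obj.P
    if isinstance(obj, PairwiseQ):
        return obj.Q
    return np.asarray(obj, dtype=float)


def _topk(values: np.ndarray, self_idx: int, k: int) -> set[int]:
    # descending value, ties broken by ascending index (stable lexsort)
    n = values.shape[0]
    v = values.copy()
    v[self_idx] = -np.inf
    order = np.lexsort((np.arange(n), -v))
    return set(int(j) for j in order[:k])


def neighborhood_preservation_ratio(P, Q, k: int = 10) -> float:
    """Mean fraction of shared top-k neighbors between P and Q rankings.

    Ties are broken by ascending index so the statistic is deterministic even
    after thresholding produces duplicated similarity values.
    """
    Pm, Qm = _as_matrix(P), _as_matrix(Q)
    n = Pm.shape[0]
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}]")
    shared = 0.0
    for i in range(n):
        shared += len(_topk(Pm[i], i, k) & _topk(Qm[i], i, k)) / k
    return shared / n


def error_rate(P, Q) -> float:
    """KL(P||Q) with the 0 log 0 = 0 convention, natural log."""
    Pm, Qm = _as_matrix(P), _as_matrix(Q)
    mask = Pm > 0
    return float(
        np.sum(Pm[mask] * (np.log(Pm[mask]) - np.log(np.maximum(Qm[mask], _LOG_FLOOR))))
    )


def evaluate(P, Q, k: int = 10) -> EvaluationReport:
    Pm = _as_matrix(P)
    return EvaluationReport(
        npr=neighborhood_preservation_ratio(P, Q, k),
        error_rate=error_rate(P, Q),
        k=k,
        n=Pm.shape[0],
    )


def compare_runs(
    results: Sequence, labels: Sequence[str], P: JointProbabilities, k: int = 10
) -> pd.DataFrame:
    """Side-by-side metrics for fits of the same P, one row per label.

    Columns: final NPR, final KL error rate, and the first iteration whose
    cost is within 1% of the final cost. Rows are sorted by label.
    """
    from .core import compute_q
    from .optim import iterations_to_within

    if len(results) < 2:
        raise ValueError("need at least two results to compare")
    if len(results) != len(labels):
        raise ValueError("labels must match results")
    fp = P.fingerprint()
    rows = []
    for label, res in sorted(zip(labels, results), key=lambda t: t[0]):
        if res.p_fingerprint != fp:
            raise ValueError(
                f"result {label!r} was fitted on a different P than supplied"
            )
        q = compute_q(res.embedding)
        rows.append(
            {
                "label": label,
                "npr": neighborhood_preservation_ratio(P, q, k),
                "error_rate": error_rate(P, q),
                "iters_to_1pct": iterations_to_within(res.cost_trace, 0.01),
            }
        )
    return pd.DataFrame(rows).set_index("label")
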