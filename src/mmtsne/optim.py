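"""Gradient-based fitting of the multi-map embedding.

Three interchangeable first-order update rules are provided:

* ``momentum`` — classical heavy-ball: velocity accumulates the gradient
  evaluated at the current parameters.
* ``nesterov`` — accelerated gradient: the gradient is evaluated at the
  look-ahead point ``params + gamma * velocity`` before the velocity is
  applied, correcting an overshooting velocity one step sooner.
* ``nesterov_equivalent`` — the algebraically equivalent re-parametrized form
  that adds an explicit gradient-difference correction term to a standard
  momentum step; useful because it exposes the implicit second-order
  correction and lets the equivalence be verified numerically.

All rules share one schedule (learning rate, momentum ramp, early
exaggeration) so a comparison between them isolates the update rule itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .affinity import JointProbabilities
from .core import (
    CostBreakdown,
    MultiMapEmbedding,
    compute_q,
    grad_positions,
    grad_weights,
    regularized_cost,
)

__all__ = [
    "OptimizerConfig",
    "FitResult",
    "DivergenceError",
    "momentum_step",
    "nesterov_step",
    "nesterov_equivalent_step",
    "fit",
]

RULES = ("momentum", "nesterov", "nesterov_equivalent")


class DivergenceError(RuntimeError):
    """Raised when the objective or gradient becomes non-finite."""


@dataclass(frozen=True)
class OptimizerConfig:
    """Schedule shared by every update rule.

    Defaults follow standard t-SNE practice: learning rate 100, momentum
    ramped from 0.5 to 0.8 at iteration 250, 1000 iterations, and early
    exaggeration multiplying P by 4 for the first 100 iterations.
    """

    rule: str = "nesterov"
    eta: float = 100.0
    gamma_initial: float = 0.5
    gamma_final: float = 0.8
    gamma_switch_iter: int = 250
    n_iter: int = 1000
    early_exaggeration_factor: float = 4.0
    early_exaggeration_iters: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        if not self.eta > 0:
            raise ValueError("learning rate eta must be positive")
        for g in (self.gamma_initial, self.gamma_final):
            if not 0.0 <= g < 1.0:
                raise ValueError("momentum coefficients must lie in [0, 1)")
        if self.n_iter < 1:
            raise ValueError("n_iter must be at least 1")
        if self.early_exaggeration_factor < 1.0:
            raise ValueError("early exaggeration factor must be >= 1")
        if self.early_exaggeration_iters < 0:
            raise ValueError("early exaggeration iterations must be >= 0")


@dataclass(frozen=True)
class FitResult:
    """Fitted embedding plus the per-iteration cost trace."""

    embedding: MultiMapEmbedding
    cost_trace: tuple[CostBreakdown, ...]
    converged_iter: int
    rule: str
    lam: float
    p_fingerprint: str


GradFn = Callable[[np.ndarray], np.ndarray]


def _check_finite(arr: np.ndarray, what: str, iteration: int, rule: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise DivergenceError(
            f"non-finite {what} at iteration {iteration} under rule {rule!r}"
        )


def momentum_step(
    params: np.ndarray,
    velocity: np.ndarray,
    gradient_fn: GradFn,
    eta: float,
    gamma: float,
    iteration: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """v <- gamma v - eta grad(params); params <- params + v."""
    g = gradient_fn(params)
    _check_finite(g, "gradient", iteration, "momentum")
    v = gamma * velocity - eta * g
    return params + v, v


def nesterov_step(
    params: np.ndarray,
    velocity: np.ndarray,
    gradient_fn: GradFn,
    eta: float,
    gamma: float,
    iteration: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """v <- gamma v - eta grad(params + gamma v); params <- params + v."""
    g = gradient_fn(params + gamma * velocity)
    _check_finite(g, "gradient", iteration, "nesterov")
    v = gamma * velocity - eta * g
    return params + v, v


def nesterov_equivalent_step(
    params_hat: np.ndarray,
    velocity_hat: np.ndarray,
    prev_gradient: np.ndarray,
    gradient_fn: GradFn,
    eta: float,
    gamma: float,
    iteration: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Re-parametrized accelerated step with an explicit gradient correction.

    v^ <- gamma v^ - eta g - eta gamma (g - g_prev);  theta^ <- theta^ + v^,
    where g is the gradient at the current (hat) parameters. Returns the
    current gradient so the caller can feed it back as ``prev_gradient``.
    """
    g = gradient_fn(params_hat)
    _check_finite(g, "gradient", iteration, "nesterov_equivalent")
    v = gamma * velocity_hat - eta * g - eta * gamma * (g - prev_gradient)
    return params_hat + v, v, g


def _pack(Y: np.ndarray, Omega: np.ndarray) -> np.ndarray:
    return np.concatenate([Y.ravel(), Omega.ravel()])


def _unpack(theta: np.ndarray, n: int, M: int) -> tuple[np.ndarray, np.ndarray]:
    k = n * M * 2
    return theta[:k].reshape(n, M, 2), theta[k:].reshape(n, M)


def fit(
    P: JointProbabilities,
    n_maps: int = 2,
    lam: float = 0.0,
    config: OptimizerConfig | None = None,
) -> FitResult:
    """Optimize positions and weights jointly under the chosen update rule.

    Positions start at Normal(0, 1e-4) (standard deviation 1e-2) and weights
    at zero (uniform maps) under ``config.seed``. P is multiplied by the
    early-exaggeration factor for the first ``early_exaggeration_iters``
    iterations; the recorded cost trace always uses the unexaggerated P so
    traces from different runs are comparable.
    """
    config = config or OptimizerConfig()
    if n_maps < 1:
        raise ValueError("n_maps must be at least 1")
    n = P.n
    rng = np.random.default_rng(config.seed)
    Y0 = rng.normal(0.0, 1e-2, size=(n, n_maps, 2))
    Omega0 = np.zeros((n, n_maps))
    ids = P.ids
    fingerprint = P.fingerprint()

    def make_grad(Pmat: np.ndarray) -> GradFn:
        def gradient(theta: np.ndarray) -> np.ndarray:
            Y, Om = _unpack(theta, n, n_maps)
            emb = MultiMapEmbedding(ids=ids, Y=Y, Omega=Om)
            q = compute_q(emb)
            gY = grad_positions(Pmat, emb, lam, q=q)
            gO = grad_weights(Pmat, emb, lam, q=q)
            return _pack(gY, gO)

        return gradient

    theta = _pack(Y0, Omega0)
    velocity = np.zeros_like(theta)
    prev_grad = np.zeros_like(theta)
    trace: list[CostBreakdown] = []
    for t in range(config.n_iter):
        exaggerate = t < config.early_exaggeration_iters
        Pmat = P.P * config.early_exaggeration_factor if exaggerate else P.P
        grad_fn = make_grad(Pmat)
        gamma = (
            config.gamma_initial if t < config.gamma_switch_iter else config.gamma_final
        )
        if config.rule == "momentum":
            theta, velocity = momentum_step(
                theta, velocity, grad_fn, config.eta, gamma, iteration=t
            )
        elif config.rule == "nesterov":
            theta, velocity = nesterov_step(
                theta, velocity, grad_fn, config.eta, gamma, iteration=t
            )
        else:
            theta, velocity, prev_grad = nesterov_equivalent_step(
                theta, velocity, prev_grad, grad_fn, config.eta, gamma, iteration=t
            )
        Y, Om = _unpack(theta, n, n_maps)
        emb = MultiMapEmbedding(ids=ids, Y=Y, Omega=Om)
        cost = regularized_cost(P, emb, lam)
        if not np.isfinite(cost.total):
            raise DivergenceError(
                f"non-finite cost at iteration {t} under rule {config.rule!r}"
            )
        trace.append(cost)
    return FitResult(
        embedding=emb,
        cost_trace=tuple(trace),
        converged_iter=iterations_to_within(trace, 0.01),
        rule=config.rule,
        lam=lam,
        p_fingerprint=fingerprint,
    )


def iterations_to_within(
    trace: Sequence[CostBreakdown], rel_tol: float = 0.01
) -> int:
    """First iteration whose total cost is within ``rel_tol`` of the final cost."""
    final = trace[-1].total
    band = abs(final) * rel_tol
    for t, c in enumerate(trace):
        if abs(c.total - final) <= band:
            return t
    return len(trace) - 1
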