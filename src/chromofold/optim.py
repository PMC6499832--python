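"""Shared first-order optimizer: gradient descent with backtracking halving.

Each iteration starts from the configured learning rate and halves the step
(up to ``max_halvings`` times) until the cost does not increase, which makes
the cost trajectory monotone non-increasing by construction.  Termination:
relative cost change below ``rel_tol``, no acceptable step found, or
``max_iter`` iterations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .datamodel import InputError, NumericalError

__all__ = ["OptimizerConfig", "gradient_descent"]


@dataclass
class OptimizerConfig:
    learning_rate: float = 0.05
    max_iter: int = 5000
    rel_tol: float = 1e-7
    seed: int = 0
    init_scale: float = 1.0
    max_halvings: int = 30

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise InputError("learning_rate must be > 0")
        if self.max_iter < 0:
            raise InputError("max_iter must be >= 0")


def gradient_descent(
    x0: np.ndarray,
    fn: Callable[[np.ndarray], tuple[float, np.ndarray]],
    config: OptimizerConfig,
) -> tuple[np.ndarray, list[float]]:
    """Minimize ``fn`` from ``x0``; returns (x, cost trajectory).

    ``fn(x)`` must return ``(cost, gradient)``.  A non-finite cost at the
    starting point raises :class:`NumericalError`; non-finite trial steps are
    rejected by the backtracking loop.
    """
    x = np.array(x0, dtype=float)
    cost, grad = fn(x)
    if not np.isfinite(cost):
        raise NumericalError("cost is non-finite at the starting point")
    history = [float(cost)]
    for _ in range(config.max_iter):
        if not np.any(grad):
            break
        step = config.learning_rate
        accepted = False
        for _h in range(config.max_halvings + 1):
            x_new = x - step * grad
            cost_new, grad_new = fn(x_new)
            if np.isfinite(cost_new) and cost_new <= cost:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        rel_change = (cost - cost_new) / max(abs(cost), 1e-300)
        x, cost, grad = x_new, cost_new, grad_new
        history.append(float(cost))
        if rel_change < config.rel_tol:
            break
    return x, history
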