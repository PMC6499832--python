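"""Selection of the term weights (λE, λF) and (λE, λR) by grid search.

Each candidate pair is scored with

    S = (1 − C1) · v / |v − v′|,

where C1 is the stochastic-neighbor mismatch of the optimized model
(clamped to [0, 1]), v a prior volume estimate for the chromosome or TAD,
and v′ the convex-hull volume of the reconstructed model.  Larger S is
better: it rewards both Hi-C fidelity and a physically plausible size.
The denominator is regularized as max(|v − v′|, ε·v) with ε = 1e-3 so the
score stays finite when the model volume matches the prior exactly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .datamodel import Conformation, InputError
from .backbone import (
    BackboneProblem,
    compute_embedding_prob,
    kl_cost,
    optimize_backbone,
)
from .intratad import TadProblem, optimize_tad

__all__ = [
    "ScoreResult",
    "model_volume",
    "score_S",
    "prior_volume_from_powerlaw",
    "grid_search",
]

SCORE_EPSILON = 1e-3


@dataclass
class ScoreResult:
    lambda_pair: tuple[float, float]
    C1: float
    v: float
    v_prime: float
    S: float


def model_volume(conf: Conformation | np.ndarray) -> float:
    """Convex-hull volume (µm³) of the model's points; 0 with a warning for
    degenerate (coplanar/collinear) point sets."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    if len(coords) < 4:
        raise InputError("volume needs at least 4 points")
    try:
        return float(ConvexHull(coords).volume)
    except QhullError:
        warnings.warn("degenerate (coplanar) point set; volume set to 0")
        return 0.0


def score_S(C1: float, v: float, v_prime: float) -> float:
    """Model-selection score; C1 clamped to [0, 1], denominator regularized."""
    if v <= 0:
        raise InputError("prior volume v must be > 0")
    c1 = min(max(C1, 0.0), 1.0)
    return (1.0 - c1) * v / max(abs(v - v_prime), SCORE_EPSILON * v)


def prior_volume_from_powerlaw(c: float, beta: float, genomic_length: float) -> float:
    """Fallback prior volume from the FISH power law applied to the full
    genomic length: v = (4/3)π(1.29·R_g)³ with R_g = c·L^β/√6."""
    if genomic_length <= 0:
        raise InputError("genomic length must be > 0")
    rg = c * genomic_length**beta / np.sqrt(6.0)
    return float(4.0 / 3.0 * np.pi * (1.29 * rg) ** 3)


def _optimize(problem):
    if isinstance(problem, BackboneProblem):
        return optimize_backbone(problem)
    if isinstance(problem, TadProblem):
        return optimize_tad(problem)
    raise InputError(f"cannot optimize problem of type {type(problem).__name__}")


def grid_search(
    problem_builder,
    lambda1_values,
    lambda2_values,
    prior_volume: float,
) -> tuple[tuple[float, float], list[ScoreResult]]:
    """Exhaustive search over the λ grid, maximizing the mean score S.

    ``problem_builder(l1, l2)`` returns a problem (or a list of problems for
    joint selection across datasets; their scores are averaged).  Ties are
    broken toward the smaller first λ, then the smaller second λ; the grid
    is scanned in sorted order, so results are deterministic.
    """
    l1s = sorted(set(float(v) for v in np.atleast_1d(lambda1_values)))
    l2s = sorted(set(float(v) for v in np.atleast_1d(lambda2_values)))
    if not l1s or not l2s:
        raise InputError("empty λ grid")
    results: list[ScoreResult] = []
    best = None
    for l1, l2 in itertools.product(l1s, l2s):
        problems = problem_builder(l1, l2)
        if not isinstance(problems, (list, tuple)):
            problems = [problems]
        scores, c1s, vps = [], [], []
        for prob in problems:
            conf = _optimize(prob)
            c1 = kl_cost(prob.affinity, compute_embedding_prob(conf))
            vp = model_volume(conf)
            scores.append(score_S(c1, prior_volume, vp))
            c1s.append(c1)
            vps.append(vp)
        res = ScoreResult(
            lambda_pair=(l1, l2),
            C1=float(np.mean(c1s)),
            v=prior_volume,
            v_prime=float(np.mean(vps)),
            S=float(np.mean(scores)),
        )
        results.append(res)
        if best is None or res.S > best.S:
            best = res
    return best.lambda_pair, results
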