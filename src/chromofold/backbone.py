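"""TAD-level backbone embedding.

One 3D point is placed per TAD by minimizing

    C_g = C1 + λE·C2 + λF·C3,

where C1 is the Kullback–Leibler divergence between contact-derived
neighboring affinities p_ij and embedding proximities q_ij (a
stochastic-neighbor objective), C2 the polymer conformational energy, and
C3 a least-squares penalty against FISH mean pairwise distances (µm).
All pair sums follow the ordered-pair (factor-2 symmetric) convention so
that reported costs are reproducible bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datamodel import (
    ContactMap,
    Conformation,
    FishDistanceMatrix,
    InputError,
    NumericalError,
)
from .optim import OptimizerConfig, gradient_descent
from .polymer import PolymerParams, conf_energy_and_grad

__all__ = [
    "BackboneProblem",
    "compute_affinity",
    "compute_embedding_prob",
    "kl_cost",
    "fish_cost_and_grad",
    "kl_cost_and_grad",
    "backbone_cost_and_grad",
    "optimize_backbone",
]

# Paper-scale defaults for raw Hi-C counts; grid search (param_search) is the
# principled way to pick these for a new dataset, since their magnitude
# depends on the scale/normalization of the contact counts.
DEFAULT_LAMBDA_E = 5e12
DEFAULT_LAMBDA_F = 1e-8

_EPS = 1e-300


def compute_affinity(f: ContactMap | np.ndarray) -> np.ndarray:
    """Neighboring affinities p_ij = f_ij / Σ_{k≠l} f_kl (ordered pairs)."""
    m = f.matrix if isinstance(f, ContactMap) else np.asarray(f, float)
    m = m.copy()
    np.fill_diagonal(m, 0.0)
    total = m.sum()
    if total <= 0:
        raise InputError("contact map is all zero; affinities undefined")
    return m / total


def _proximity_weights(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = squareform(pdist(coords))
    w = 1.0 / (1.0 + d)
    np.fill_diagonal(w, 0.0)
    return d, w


def compute_embedding_prob(conf: Conformation | np.ndarray) -> np.ndarray:
    """Embedding proximities q_ij = (1+‖s_i−s_j‖)⁻¹ / Σ_{k≠l}(1+‖s_k−s_l‖)⁻¹."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    if len(coords) < 2:
        raise InputError("embedding probabilities require at least 2 points")
    _, w = _proximity_weights(coords)
    return w / w.sum()


def kl_cost(P: np.ndarray, Q: np.ndarray) -> float:
    """C1 = Σ_{i≠j} p_ij log(p_ij/q_ij), with 0·log 0 = 0."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    if P.shape != Q.shape:
        raise InputError("P and Q must have the same shape")
    mask = P > 0
    if np.any(Q[mask] <= 0):
        raise InputError("Q must be positive wherever P is positive")
    return float(np.sum(P[mask] * np.log(P[mask] / Q[mask])))


def kl_cost_and_grad(
    P: np.ndarray, coords: np.ndarray
) -> tuple[float, np.ndarray]:
    """C1 and its analytic gradient with respect to the 3D coordinates.

    dC1/ds_i = Σ_j 2 w_ij (p_ij − q_ij)(s_i − s_j)/d_ij with w = (1+d)⁻¹.
    """
    d, w = _proximity_weights(coords)
    q = w / w.sum()
    c1 = kl_cost(P, q)
    # both ordered elements (i,j) and (j,i) depend on the same distance d_ij
    coef = w * (P + P.T - 2.0 * q) / np.maximum(d, _EPS)
    np.fill_diagonal(coef, 0.0)
    grad = coef.sum(axis=1)[:, None] * coords - coef @ coords
    return c1, grad


def fish_cost_and_grad(
    conf: Conformation | np.ndarray, fish: FishDistanceMatrix
) -> tuple[float, np.ndarray]:
    """C3 = Σ_{i≠j defined} (‖s_i−s_j‖ − F_ij)² and its gradient.

    Missing FISH entries are skipped.  The ordered double sum means each
    unordered pair is counted twice, so the gradient carries a factor 4.
    """
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    if fish.n != len(coords):
        raise InputError(
            f"FISH matrix ({fish.n}) and conformation ({len(coords)}) sizes differ"
        )
    d = squareform(pdist(coords))
    resid = np.where(fish.defined, d - fish.matrix, 0.0)
    cost = float(np.sum(resid**2))
    coef = 4.0 * resid / np.maximum(d, _EPS)
    grad = coef.sum(axis=1)[:, None] * coords - coef @ coords
    return cost, grad


@dataclass
class BackboneProblem:
    """TAD-level embedding problem: contacts + FISH distances + weights."""

    tad_contacts: ContactMap
    fish: FishDistanceMatrix
    lambda_E: float = DEFAULT_LAMBDA_E
    lambda_F: float = DEFAULT_LAMBDA_F
    polymer: PolymerParams | None = None
    opt: OptimizerConfig | None = None
    affinity: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.tad_contacts.n != self.fish.n:
            raise InputError("contact map and FISH matrix dimensions differ")
        if self.lambda_E < 0 or self.lambda_F < 0:
            raise InputError("lambda_E and lambda_F must be >= 0")
        self.affinity = compute_affinity(self.tad_contacts)
        if self.polymer is None:
            self.polymer = PolymerParams(rest_length=self._neighbor_scale())
        if self.opt is None:
            scale = self._fish_scale()
            self.opt = OptimizerConfig(
                learning_rate=0.05 * scale, max_iter=20000, rel_tol=1e-7,
                init_scale=0.5 * scale,
            )

    def _fish_scale(self) -> float:
        vals = self.fish.matrix[self.fish.defined]
        return float(np.mean(vals)) if vals.size else 1.0

    def _neighbor_scale(self) -> float:
        n = self.fish.n
        i = np.arange(n - 1)
        nb = self.fish.matrix[i, i + 1]
        ok = self.fish.defined[i, i + 1]
        if np.any(ok):
            return float(np.median(nb[ok]))
        return self._fish_scale()

    def cost_terms(self, coords: np.ndarray) -> dict[str, float]:
        c1, _ = kl_cost_and_grad(self.affinity, coords)
        c2, _ = conf_energy_and_grad(coords, self.polymer)
        c3, _ = fish_cost_and_grad(coords, self.fish)
        return {"C1": c1, "C2": c2, "C3": c3}


def backbone_cost_and_grad(
    problem: BackboneProblem, conf: Conformation | np.ndarray
) -> tuple[float, np.ndarray]:
    """C_g = C1 + λE·C2 + λF·C3 and its full analytic gradient."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    c1, g1 = kl_cost_and_grad(problem.affinity, coords)
    cost, grad = c1, g1
    if problem.lambda_E != 0:
        c2, g2 = conf_energy_and_grad(coords, problem.polymer)
        cost = cost + problem.lambda_E * c2
        grad = grad + problem.lambda_E * g2
    if problem.lambda_F != 0:
        c3, g3 = fish_cost_and_grad(coords, problem.fish)
        cost = cost + problem.lambda_F * c3
        grad = grad + problem.lambda_F * g3
    return cost, grad


def _raise_naming_term(problem, coords) -> None:
    terms = problem.cost_terms(coords)
    bad = [k for k, v in terms.items() if not np.isfinite(v)]
    raise NumericalError(
        f"non-finite cost term(s) {bad or list(terms)} during backbone optimization"
    )


def optimize_backbone(problem: BackboneProblem) -> Conformation:
    """Minimize C_g by gradient descent from a seeded Gaussian start.

    Backtracking step halving guarantees a monotone non-increasing cost
    trajectory; the returned cost is never above the initial cost.  Two runs
    with the same seed produce identical output.
    """
    opt = problem.opt
    rng = np.random.default_rng(opt.seed)
    n = problem.tad_contacts.n
    x0 = rng.normal(scale=opt.init_scale, size=(n, 3))
    fn = lambda x: backbone_cost_and_grad(problem, x)
    try:
        coords, history = gradient_descent(x0, fn, opt)
    except NumericalError:
        _raise_naming_term(problem, x0)
    if not np.all(np.isfinite(coords)):
        _raise_naming_term(problem, coords)
    bins = list(problem.tad_contacts.bins) if problem.tad_contacts.bins else None
    return Conformation(coords, bins=bins)
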