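"""Intra-TAD 3D modeling at fixed bin resolution (default 5 kb).

Each TAD's internal conformation minimizes

    C_t = C1 + λE·C2 + λR·C4,      C4 = |R_g² − R̂g²|,

where C1/C2 are as in the backbone stage (intra-TAD contacts) and C4 pins
the model's radius of gyration to a FISH-derived target R̂g.  FISH imaging
does not resolve loci inside a TAD, but the chromosome-wide spatial-vs-
genomic power law fitted from FISH (d ≈ c·g^β) still yields a rough size
estimate: treating c·L^β as an end-to-end distance of an ideal chain gives
R̂g = c·L^β / √6 for a TAD of genomic length L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import ContactMap, Conformation, GenomicBin, InputError, NumericalError
from .backbone import compute_affinity, kl_cost_and_grad
from .optim import OptimizerConfig, gradient_descent
from .polymer import PolymerParams, conf_energy_and_grad

__all__ = [
    "TadProblem",
    "radius_of_gyration",
    "rg_cost_and_grad",
    "estimate_target_rg",
    "tad_cost_and_grad",
    "optimize_tad",
]

DEFAULT_LAMBDA_E = 5e11
DEFAULT_LAMBDA_R = 1e-7
DEFAULT_RESOLUTION = 5000  # bp


def radius_of_gyration(conf: Conformation | np.ndarray) -> float:
    """R_g = sqrt((1/N) Σ ‖y_i − ȳ‖²)."""
    y = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    y = np.atleast_2d(y)
    if len(y) < 1:
        raise InputError("radius of gyration requires at least 1 point")
    return float(np.sqrt(np.mean(np.sum((y - y.mean(axis=0)) ** 2, axis=1))))


def rg_cost_and_grad(
    conf: Conformation | np.ndarray, target_rg: float
) -> tuple[float, np.ndarray]:
    """C4 = |R_g² − R̂g²| and its subgradient (2/N)·sign(R_g²−R̂g²)·(y−ȳ).

    sign(0) = 0, so the gradient vanishes exactly at the target.
    """
    if target_rg <= 0:
        raise InputError("target radius of gyration must be > 0")
    y = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    y = np.atleast_2d(y)
    n = len(y)
    centered = y - y.mean(axis=0)
    rg2 = float(np.mean(np.sum(centered**2, axis=1)))
    diff = rg2 - target_rg**2
    cost = abs(diff)
    grad = (2.0 / n) * np.sign(diff) * centered
    return cost, grad


def estimate_target_rg(
    tad: GenomicBin | int, powerlaw: tuple[float, float],
    override: float | None = None,
) -> float:
    """R̂g from the FISH spatial-vs-genomic power law d = c·g^β.

    The TAD's genomic length L (bp) is mapped to a spatial span c·L^β and
    converted to a radius of gyration with the ideal-chain end-to-end
    relation R_g = R_ee/√6.  A user-supplied per-TAD ``override`` wins.
    """
    if override is not None:
        if override <= 0:
            raise InputError("override radius of gyration must be > 0")
        return float(override)
    c, beta = powerlaw
    length = tad.length if isinstance(tad, GenomicBin) else int(tad)
    if length <= 0:
        raise InputError("TAD genomic length must be > 0")
    if c <= 0:
        raise InputError("power-law prefactor c must be > 0")
    return float(c * length**beta / np.sqrt(6.0))


@dataclass
class TadProblem:
    """Single-TAD modeling problem at bin resolution."""

    tad: GenomicBin
    contacts: ContactMap
    target_rg: float
    lambda_E: float = DEFAULT_LAMBDA_E
    lambda_R: float = DEFAULT_LAMBDA_R
    polymer: PolymerParams | None = None
    opt: OptimizerConfig | None = None
    affinity: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.target_rg <= 0:
            raise InputError("target_rg must be > 0")
        if self.lambda_E < 0 or self.lambda_R < 0:
            raise InputError("lambda_E and lambda_R must be >= 0")
        self.affinity = compute_affinity(self.contacts)
        n = self.contacts.n
        if self.polymer is None:
            # rest length from the target size of an ideal chain of n beads
            b = self.target_rg * np.sqrt(6.0 / max(n, 2))
            self.polymer = PolymerParams(rest_length=b)
        if self.opt is None:
            self.opt = OptimizerConfig(
                learning_rate=0.05 * self.target_rg, max_iter=20000,
                rel_tol=1e-7, init_scale=self.target_rg,
            )

    def cost_terms(self, coords: np.ndarray) -> dict[str, float]:
        c1, _ = kl_cost_and_grad(self.affinity, coords)
        c2, _ = conf_energy_and_grad(coords, self.polymer)
        c4, _ = rg_cost_and_grad(coords, self.target_rg)
        return {"C1": c1, "C2": c2, "C4": c4}


def tad_cost_and_grad(
    problem: TadProblem, conf: Conformation | np.ndarray
) -> tuple[float, np.ndarray]:
    """C_t = C1 + λE·C2 + λR·C4 and its analytic gradient."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    c1, g1 = kl_cost_and_grad(problem.affinity, coords)
    cost, grad = c1, g1
    if problem.lambda_E != 0:
        c2, g2 = conf_energy_and_grad(coords, problem.polymer)
        cost = cost + problem.lambda_E * c2
        grad = grad + problem.lambda_E * g2
    if problem.lambda_R != 0:
        c4, g4 = rg_cost_and_grad(coords, problem.target_rg)
        cost = cost + problem.lambda_R * c4
        grad = grad + problem.lambda_R * g4
    return cost, grad


def optimize_tad(problem: TadProblem) -> Conformation:
    """Minimize C_t by seeded gradient descent (same contract as the backbone).

    Per-TAD problems are independent; for a multi-TAD run, seeding each
    problem with (global seed + TAD ordinal) makes parallel execution
    result-identical to sequential execution.
    """
    opt = problem.opt
    rng = np.random.default_rng(opt.seed)
    n = problem.contacts.n
    x0 = rng.normal(scale=opt.init_scale, size=(n, 3))
    fn = lambda x: tad_cost_and_grad(problem, x)
    try:
        coords, _ = gradient_descent(x0, fn, opt)
    except NumericalError:
        terms = problem.cost_terms(x0)
        bad = [k for k, v in terms.items() if not np.isfinite(v)]
        raise NumericalError(
            f"non-finite cost term(s) {bad or list(terms)} for TAD {problem.tad.index}"
        )
    # n equal genomic bins spanning the TAD
    edges = np.round(np.linspace(problem.tad.start, problem.tad.end, n + 1)).astype(int)
    bins = [
        GenomicBin(problem.tad.chrom, int(edges[k]), int(edges[k + 1]), k)
        for k in range(n)
    ]
    tad_ids = np.full(n, problem.tad.index)
    return Conformation(coords, bins=bins, tad_ids=tad_ids)
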