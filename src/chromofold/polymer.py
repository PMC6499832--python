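"""Polymer conformational-energy prior (the C2 term) and its gradient.

The prior is a minimal bead-chain model: harmonic stretching between
consecutive beads plus a soft-sphere excluded-volume penalty between
non-adjacent beads,

    E = Σ_i k_s (‖y_{i+1} − y_i‖ − b)²
      + Σ_{|i−j|>1} k_r max(0, r_c − ‖y_i − y_j‖)².

It enforces chain connectivity and non-self-intersection while remaining
invariant to rigid motions.  The functional form is isolated behind this
one interface so that richer priors (bending, torsion) can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .datamodel import Conformation, InputError

__all__ = ["PolymerParams", "conf_energy_and_grad"]

_EPS = 1e-300  # guards divisions by zero distances; those pairs get zero gradient


@dataclass
class PolymerParams:
    """Bead-chain parameters (µm length scale, unit-free stiffnesses).

    rest_length
        Equilibrium consecutive-bead distance b (µm).  Sensible defaults are
        the median FISH-implied neighbor distance for backbones, or
        c·(bin size)^β for intra-TAD chains.
    stretch_stiffness, repulsion_stiffness
        Dimensionless weights (overall energy scale is absorbed by λE).
    contact_radius
        Soft-sphere radius r_c (µm) below which non-adjacent beads repel;
        b/2 by default.
    """

    rest_length: float
    stretch_stiffness: float = 1.0
    contact_radius: float | None = None
    repulsion_stiffness: float = 1.0

    def __post_init__(self) -> None:
        if self.contact_radius is None:
            self.contact_radius = 0.5 * self.rest_length
        for name in ("rest_length", "stretch_stiffness", "contact_radius",
                     "repulsion_stiffness"):
            if getattr(self, name) <= 0:
                raise InputError(f"polymer parameter {name} must be positive")


def conf_energy_and_grad(
    conf: Conformation | np.ndarray, params: PolymerParams
) -> tuple[float, np.ndarray]:
    """Conformational energy E ≥ 0 and its analytic per-point gradient."""
    y = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    n = len(y)
    if n < 2:
        raise InputError("polymer energy requires at least 2 points")
    grad = np.zeros_like(y)

    # stretching of consecutive bonds
    dvec = y[1:] - y[:-1]
    d = np.linalg.norm(dvec, axis=1)
    dev = d - params.rest_length
    energy = params.stretch_stiffness * float(np.sum(dev**2))
    # dE/dy_i; zero-distance bonds get a zero-direction gradient
    coef = 2.0 * params.stretch_stiffness * dev / np.maximum(d, _EPS)
    bond_grad = coef[:, None] * dvec
    grad[1:] += bond_grad
    grad[:-1] -= bond_grad

    # soft-sphere repulsion between non-adjacent beads
    if n > 2:
        dm = squareform(pdist(y))
        sep = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        active = (sep > 1) & (dm < params.contact_radius)
        if np.any(active):
            overlap = np.where(active, params.contact_radius - dm, 0.0)
            # ordered-pair double count halved: use upper triangle for energy
            energy += params.repulsion_stiffness * float(
                np.sum(np.triu(overlap, k=1) ** 2)
            )
            coef = -2.0 * params.repulsion_stiffness * overlap / np.maximum(dm, _EPS)
            np.fill_diagonal(coef, 0.0)
            # grad_i = Σ_j coef_ij (y_i − y_j)
            grad += coef.sum(axis=1)[:, None] * y - coef @ y
    return energy, grad
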