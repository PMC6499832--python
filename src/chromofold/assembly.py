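"""Rigid-body assembly of intra-TAD models into the TAD-level backbone.

Each TAD model is translated so its centroid coincides with its backbone
point, then its orientation is optimized (rotations about its center, with
optional mirror reflections) to close the junction gaps between consecutive
TADs:

    C_integration = Σ_{i=1}^{n−1} (‖y_{s_{i+1}} − y_{e_i}‖ − d_{i,i+1})²,

where d_{i,i+1} is the expected linker distance, estimated from the contact
frequency between the flanking loci (d = f^α with α = −0.25) or, when that
contact is zero, from the chromosome's FISH-derived spatial-vs-genomic
power law (d = c·g^β).  TADs stay rigid throughout: internal pairwise
distances are preserved to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    ContactMap,
    Conformation,
    FishDistanceMatrix,
    InputError,
    TadSet,
)

__all__ = [
    "AssemblyParams",
    "TadPlacement",
    "AssemblyResult",
    "fit_distance_powerlaw",
    "linker_distance",
    "estimate_linker_distances",
    "integration_cost_and_grad",
    "rotate_tad_step",
    "assemble",
]

DEFAULT_ALPHA = -0.25

_EPS = 1e-300


def fit_distance_powerlaw(
    fish: FishDistanceMatrix, tads: TadSet
) -> tuple[float, float]:
    """Fit F ≈ c·g^β by OLS of log F on log g over defined TAD pairs.

    g is the center-to-center genomic separation in bp.  Returns (c, beta).
    """
    if fish.n != len(tads):
        raise InputError("FISH matrix and TAD set sizes differ")
    ii, jj = fish.defined_pairs()
    g = np.array([tads.center_separation(i, j) for i, j in zip(ii, jj)])
    F = fish.matrix[ii, jj]
    ok = (g > 0) & (F > 0)
    if ok.sum() < 3:
        raise InputError("need at least 3 usable TAD pairs for the power-law fit")
    slope, intercept = np.polyfit(np.log(g[ok]), np.log(F[ok]), 1)
    return float(np.exp(intercept)), float(slope)


@dataclass
class AssemblyParams:
    """Parameters of the TAD-orientation optimization.

    alpha_exponent: contact→distance exponent (d = f^α), −0.25 by default.
    c, beta: FISH-derived spatial-vs-genomic power law d = c·g^β (µm, bp).
    rescale_linkers: rescale the f^α linker distances so their median
        matches the median power-law estimate over the junctions, for
        contact counts on an arbitrary scale.
    """

    alpha_exponent: float = DEFAULT_ALPHA
    c: float = 1.0
    beta: float = 1.0 / 3.0
    learning_rate: float = 0.25
    max_iter: int = 200
    rel_tol: float = 1e-9
    try_reflection: bool = True
    rescale_linkers: bool = False

    def __post_init__(self) -> None:
        if self.alpha_exponent >= 0:
            raise InputError("alpha_exponent must be negative")
        if self.c <= 0:
            raise InputError("power-law prefactor c must be > 0")
        if not 0 < self.beta < 1:
            raise InputError("power-law exponent beta must be in (0, 1)")
        if self.learning_rate <= 0:
            raise InputError("learning_rate must be > 0")


@dataclass
class TadPlacement:
    """Rigid placement of one TAD: center, proper rotation, chirality flag."""

    tad: int
    center: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    reflected: bool = False


@dataclass
class AssemblyResult:
    conformation: Conformation
    placements: list[TadPlacement]
    cost_history: list[float]

    @property
    def cost(self) -> float:
        return self.cost_history[-1]


def linker_distance(f_link: float, g_link: float, params: AssemblyParams) -> float:
    """Linker distance d = f^α, or c·g^β when the contact count is zero."""
    if f_link < 0:
        raise InputError("contact frequency must be >= 0")
    if f_link != 0:
        return float(f_link**params.alpha_exponent)
    if g_link <= 0:
        raise InputError("genomic gap must be > 0 when the contact count is 0")
    return float(params.c * g_link**params.beta)


def estimate_linker_distances(
    tad_models: list[Conformation], contacts: ContactMap, params: AssemblyParams
) -> np.ndarray:
    """Per-junction linker distances from the full-resolution contact map.

    The contact used for junction (i, i+1) is between the last bin of TAD i
    and the first bin of TAD i+1; the genomic distance is center-to-center
    of those two bins (always positive, even for abutting TADs).
    """
    sizes = [len(m) for m in tad_models]
    if contacts.n != sum(sizes):
        raise InputError(
            "full-resolution contact map does not cover all intra-TAD bins"
        )
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    d = np.empty(len(tad_models) - 1)
    powerlaw_d = np.empty_like(d)
    for i in range(len(tad_models) - 1):
        last = offsets[i + 1] - 1
        first = offsets[i + 1]
        f = contacts.matrix[last, first]
        mi = tad_models[i]
        mj = tad_models[i + 1]
        if mi.bins is not None and mj.bins is not None:
            g = abs(mj.bins[0].center - mi.bins[-1].center)
        else:
            g = (contacts.resolution or 1) * 1.0
        powerlaw_d[i] = params.c * g**params.beta
        d[i] = linker_distance(f, g, params)
    if params.rescale_linkers:
        from_f = contacts.matrix[offsets[1:-1] - 1, offsets[1:-1]] > 0
        if np.any(from_f):
            med_f = np.median(d[from_f])
            med_p = np.median(powerlaw_d[from_f])
            if med_f > 0:
                d[from_f] *= med_p / med_f
    return d


def _junction_vectors(tad_models: list[Conformation]) -> np.ndarray:
    """Δy_{i,i+1} = y_{s_{i+1}} − y_{e_i} for each junction."""
    starts = np.array([m.coords[0] for m in tad_models])
    ends = np.array([m.coords[-1] for m in tad_models])
    return starts[1:] - ends[:-1]


def integration_cost_and_grad(
    tad_models: list[Conformation], d: np.ndarray
) -> tuple[float, np.ndarray]:
    """C_integration and per-junction gradients with respect to y_{s_{i+1}}.

    Returns (cost, gradients) where gradients[i] = ∂C/∂y_{s_{i+1}} =
    2(‖Δy‖ − d)·Δy/‖Δy‖ for junction (i, i+1); the gradient with respect
    to y_{e_i} is its negative.  Coincident junction points get a zero
    gradient.
    """
    d = np.asarray(d, float)
    if len(d) != len(tad_models) - 1:
        raise InputError(
            f"expected {len(tad_models) - 1} linker distances, got {len(d)}"
        )
    dy = _junction_vectors(tad_models)
    norms = np.linalg.norm(dy, axis=1)
    resid = norms - d
    cost = float(np.sum(resid**2))
    grads = 2.0 * (resid / np.maximum(norms, _EPS))[:, None] * dy
    return cost, grads


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a unit axis."""
    ux, uy, uz = axis
    K = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def _rotation_toward(
    point: np.ndarray, center: np.ndarray, target: np.ndarray,
    max_angle: float = np.pi / 2,
) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Proper rotation about ``center`` turning ``point`` toward ``target``.

    The axis is perpendicular to both radius vectors; the angle is the angle
    between them, capped at ``max_angle``.  Returns (R, axis, angle); the
    identity with axis None when the vectors are collinear or degenerate.
    """
    v = point - center
    w = target - center
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        return np.eye(3), None, 0.0
    axis = np.cross(v, w)
    na = np.linalg.norm(axis)
    if na < 1e-12 * nv * nw:
        return np.eye(3), None, 0.0
    axis = axis / na
    cosang = np.clip(np.dot(v, w) / (nv * nw), -1.0, 1.0)
    angle = min(float(np.arccos(cosang)), max_angle)
    return _rotation_matrix(axis, angle), axis, angle


def rotate_tad_step(
    fragment: Conformation,
    center: np.ndarray,
    target_point: np.ndarray,
    point_index: int = 0,
    max_angle: float = np.pi / 2,
) -> Conformation:
    """Rigidly rotate a TAD fragment about its center so that the chosen
    endpoint turns toward ``target_point`` (angle capped per step).

    The fragment's center and all intra-fragment pairwise distances are
    unchanged.  A target collinear with the endpoint radius yields the
    identity (the rotation axis is undefined there).
    """
    center = np.asarray(center, float)
    R, _, _ = _rotation_toward(fragment.coords[point_index], center,
                               np.asarray(target_point, float), max_angle)
    return fragment.with_coords((fragment.coords - center) @ R.T + center)


def _reflect(coords: np.ndarray, center: np.ndarray, normal: np.ndarray) -> np.ndarray:
    """Reflect through the plane through ``center`` with unit ``normal``."""
    rel = coords - center
    return coords - 2.0 * (rel @ normal)[:, None] * normal


def assemble(
    backbone: Conformation,
    tad_models: list[Conformation],
    contacts: ContactMap | None,
    params: AssemblyParams,
    linker_distances: np.ndarray | None = None,
) -> AssemblyResult:
    """Place TAD models on the backbone and optimize their orientations.

    Steps: (1) translate each model so its centroid equals its backbone
    point; (2) sweep the TADs in genomic order, turning each one's most
    strained endpoint toward its gradient-descent target (the junction
    gradient converted to a capped rotation about the TAD center); (3) with
    ``try_reflection``, also evaluate each TAD's mirror image through the
    center-passing plane perpendicular to the current rotation axis and keep
    the lower-cost chirality.  Updates are accepted only if the integration
    cost does not increase, so the cost history is monotone non-increasing.
    """
    n = len(tad_models)
    if len(backbone) != n:
        raise InputError(
            f"backbone has {len(backbone)} points but {n} TAD models were given"
        )
    if linker_distances is None:
        if contacts is None:
            raise InputError("either a contact map or linker distances are required")
        d = estimate_linker_distances(tad_models, contacts, params)
    else:
        d = np.asarray(linker_distances, float)
        if len(d) != n - 1:
            raise InputError(f"expected {n - 1} linker distances, got {len(d)}")

    placements = [
        TadPlacement(tad=i, center=backbone.coords[i].copy()) for i in range(n)
    ]
    frags = []
    for i, model in enumerate(tad_models):
        shift = backbone.coords[i] - model.coords.mean(axis=0)
        frags.append(model.with_coords(model.coords + shift))

    cost, _ = integration_cost_and_grad(frags, d)
    history = [cost]
    for _sweep in range(params.max_iter):
        for k in range(n):
            if len(frags[k]) < 2:
                continue
            _, jgrads = integration_cost_and_grad(frags, d)
            # endpoint gradients: start endpoint feels junction k−1,
            # end endpoint feels junction k (negated Eq.-12 gradient)
            g_start = jgrads[k - 1] if k > 0 else np.zeros(3)
            g_end = -jgrads[k] if k < n - 1 else np.zeros(3)
            if np.linalg.norm(g_start) >= np.linalg.norm(g_end):
                grad, p_idx = g_start, 0
            else:
                grad, p_idx = g_end, len(frags[k]) - 1
            center = placements[k].center
            axis = None
            if np.linalg.norm(grad) > 0:
                target = frags[k].coords[p_idx] - params.learning_rate * grad
                R, axis, angle = _rotation_toward(
                    frags[k].coords[p_idx], center, target
                )
                # accept the rotation only if the cost does not increase,
                # halving the angle when it does
                for _h in range(12):
                    if angle == 0.0:
                        break
                    Rtry = _rotation_matrix(axis, angle) if axis is not None else R
                    cand = frags[k].with_coords(
                        (frags[k].coords - center) @ Rtry.T + center
                    )
                    old = frags[k]
                    frags[k] = cand
                    c_new, _ = integration_cost_and_grad(frags, d)
                    if c_new <= cost:
                        cost = c_new
                        placements[k].rotation = Rtry @ placements[k].rotation
                        break
                    frags[k] = old
                    angle *= 0.5
            if params.try_reflection:
                normal = axis
                if normal is None:
                    v = frags[k].coords[p_idx] - center
                    nv = np.linalg.norm(v)
                    normal = v / nv if nv > 0 else None
                if normal is not None:
                    cand = frags[k].with_coords(
                        _reflect(frags[k].coords, center, normal)
                    )
                    old = frags[k]
                    frags[k] = cand
                    c_new, _ = integration_cost_and_grad(frags, d)
                    if c_new < cost:
                        cost = c_new
                        placements[k].reflected = not placements[k].reflected
                        M = np.eye(3) - 2.0 * np.outer(normal, normal)
                        placements[k].rotation = M @ placements[k].rotation
                    else:
                        frags[k] = old
        history.append(cost)
        prev = history[-2]
        if prev - cost <= params.rel_tol * max(abs(prev), 1e-300):
            break

    coords = np.vstack([f.coords for f in frags])
    tad_ids = np.concatenate([f.tad_ids for f in frags])
    bins = None
    if all(f.bins is not None for f in frags):
        bins = [b for f in frags for b in f.bins]
    conf = Conformation(coords, bins=bins, tad_ids=tad_ids)
    # improper accumulated transforms are stored as proper rotation + flag
    for p in placements:
        if np.linalg.det(p.rotation) < 0:
            p.rotation = p.rotation @ np.diag([1.0, 1.0, -1.0])
    return AssemblyResult(conformation=conf, placements=placements,
                          cost_history=history)
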