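"""Model-quality metrics.

Relative error against FISH distances, A/B compartment partitioning from
the model geometry, asphericity, TAD packing density, Hi-C↔FISH rank
consistency, and Procrustes superposition for recovery tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .datamodel import (
    ContactMap,
    Conformation,
    FishDistanceMatrix,
    GenomicBin,
    InputError,
    TadSet,
)
from .paramsearch import model_volume

__all__ = [
    "EvaluationReport",
    "relative_error_matrix",
    "partition_compartments",
    "compartment_accuracy",
    "asphericity",
    "tad_density",
    "hic_fish_consistency",
    "procrustes_align",
    "evaluate_model",
]


def _tad_centers(conf: Conformation) -> np.ndarray:
    tads = np.unique(conf.tad_ids)
    return np.array([conf.tad_centroid(t) for t in tads])


def relative_error_matrix(
    conf: Conformation, fish: FishDistanceMatrix, mode: str = "tad_level"
) -> tuple[np.ndarray, float]:
    """RE_ij = |d_ij − F_ij| / F_ij per TAD pair, plus the mean over defined
    off-diagonal entries.

    ``tad_level``: d_ij is the distance between TAD centers.  ``final``:
    d_ij is the mean pairwise distance over all cross-TAD locus pairs.
    Missing FISH entries are NaN in the output and excluded from the mean.
    """
    tads = np.unique(conf.tad_ids)
    m = len(tads)
    if m != fish.n:
        raise InputError(f"model has {m} TADs but FISH matrix is {fish.n}x{fish.n}")
    if mode == "tad_level":
        d = squareform(pdist(_tad_centers(conf)))
    elif mode == "final":
        d = np.zeros((m, m))
        groups = [conf.coords[conf.tad_slice(t)] for t in tads]
        for a in range(m):
            for b in range(a + 1, m):
                d[a, b] = d[b, a] = cdist(groups[a], groups[b]).mean()
    else:
        raise InputError(f"unknown RE mode {mode!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        re = np.abs(d - fish.matrix) / fish.matrix
    re[fish.missing] = np.nan
    np.fill_diagonal(re, 0.0)
    defined = fish.defined
    mean_re = float(np.mean(re[defined])) if np.any(defined) else float("nan")
    re_out = re.copy()
    np.fill_diagonal(re_out, np.nan)
    return re_out, mean_re


def partition_compartments(
    conf: Conformation, tads: TadSet | None = None
) -> np.ndarray:
    """Two-way spatial partition of TADs into ±1 labels.

    The pairwise TAD-center distance matrix is turned into a column-wise
    Pearson correlation matrix (TADs in the same compartment have similar
    distance profiles); the sign of the leading principal component of that
    correlation matrix labels the TADs.  This transplants the classical
    Hi-C correlation-matrix/leading-eigenvector compartment call to distance
    space.  Labels carry no intrinsic A/B identity.  Zero scores get +1.
    """
    centers = _tad_centers(conf)
    m = len(centers)
    if m < 4:
        raise InputError("compartment partitioning needs at least 4 TADs")
    d = squareform(pdist(centers))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(d, rowvar=False)
    if not np.all(np.isfinite(corr)):
        warnings.warn("degenerate distance profiles; compartments are arbitrary")
        return np.ones(m, dtype=int)
    centered = corr - corr.mean(axis=0, keepdims=True)
    # leading principal component of the correlation matrix
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    if s[0] <= 1e-12 or (len(s) > 1 and (s[0] - s[1]) <= 1e-9 * s[0]):
        warnings.warn(
            "near-degenerate leading eigenvalue; compartment split is arbitrary"
        )
    scores = u[:, 0] * s[0]
    # deterministic sign convention: first nonzero score is positive
    nz = np.flatnonzero(np.abs(scores) > 1e-12)
    if nz.size and scores[nz[0]] < 0:
        scores = -scores
    labels = np.where(scores >= 0, 1, -1)
    return labels.astype(int)


def compartment_accuracy(labels: np.ndarray, reference_labels: np.ndarray) -> float:
    """Agreement fraction, maximized over the two label permutations.

    Partition labels have no intrinsic A/B identity without epigenetic
    tracks, so a global flip counts as perfect agreement.
    """
    labels = np.asarray(labels)
    ref = np.asarray(reference_labels)
    if labels.shape != ref.shape:
        raise InputError("label vectors must have the same length")
    return max(float(np.mean(labels == ref)), float(np.mean(labels == -ref)))


def asphericity(conf: Conformation | np.ndarray) -> float:
    """Gyration-tensor asphericity b = (λ1 − (λ2+λ3)/2)/(λ1+λ2+λ3) ∈ [0, 1].

    0 for an isotropic (spherical) mass distribution, → 1 for a rod.
    """
    y = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    y = np.atleast_2d(y)
    centered = y - y.mean(axis=0)
    tensor = centered.T @ centered / len(y)
    lam = np.sort(np.linalg.eigvalsh(tensor))[::-1]
    total = lam.sum()
    if total <= 0:
        return 0.0
    return float((lam[0] - 0.5 * (lam[1] + lam[2])) / total)


def tad_density(conf: Conformation | np.ndarray, tad: GenomicBin) -> float:
    """Packing density: genomic length (bp) per convex-hull volume (µm³)."""
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf, float)
    vol = model_volume(coords)
    if vol <= 0:
        return float("inf")
    return tad.length / vol


def hic_fish_consistency(
    contacts: ContactMap, fish: FishDistanceMatrix
) -> float:
    """Fraction of pair-of-pairs whose contact and FISH orderings are
    opposite (higher contact ↔ shorter distance), ties excluded.

    1.0 means perfectly consistent data; 0.5 is the chance level.
    """
    if contacts.n != fish.n:
        raise InputError("contact map and FISH matrix dimensions differ")
    ii, jj = fish.defined_pairs()
    if ii.size < 2:
        raise InputError("need at least 2 defined TAD pairs")
    f = contacts.matrix[ii, jj]
    F = fish.matrix[ii, jj]
    df = np.subtract.outer(f, f)
    dF = np.subtract.outer(F, F)
    iu, ju = np.triu_indices(len(f), k=1)
    prod = df[iu, ju] * dF[iu, ju]
    usable = (df[iu, ju] != 0) & (dF[iu, ju] != 0)
    if not np.any(usable):
        return float("nan")
    return float(np.mean(prod[usable] < 0))


def procrustes_align(
    model: Conformation,
    reference: Conformation,
    allow_reflection: bool = True,
    allow_scale: bool = True,
) -> tuple[Conformation, float]:
    """Optimal similarity superposition of ``model`` onto ``reference``.

    Umeyama's closed-form solution: rotation (optionally improper) +
    translation + optional isotropic scale minimizing the RMSD
    sqrt(mean ‖x'_i − y_i‖²).  Returns the aligned model and the RMSD.
    """
    X = model.coords
    Y = reference.coords
    if X.shape != Y.shape:
        raise InputError("model and reference must have the same point count")
    n = len(X)
    mu_x, mu_y = X.mean(axis=0), Y.mean(axis=0)
    Xc, Yc = X - mu_x, Y - mu_y
    sigma = Yc.T @ Xc / n
    U, D, Vt = np.linalg.svd(sigma)
    S = np.eye(3)
    if not allow_reflection and np.linalg.det(U @ Vt) < 0:
        S[2, 2] = -1.0
    R = U @ S @ Vt
    if allow_scale:
        var_x = float(np.mean(np.sum(Xc**2, axis=1)))
        scale = float(np.trace(np.diag(D) @ S)) / var_x if var_x > 0 else 1.0
    else:
        scale = 1.0
    aligned = scale * Xc @ R.T + mu_y
    rmsd = float(np.sqrt(np.mean(np.sum((aligned - Y) ** 2, axis=1))))
    return model.with_coords(aligned), rmsd


@dataclass
class EvaluationReport:
    """Bundle of model-quality metrics for one reconstructed model."""

    re_matrix: np.ndarray
    mean_re: float
    compartment_labels: np.ndarray
    asphericity: float
    tad_densities: np.ndarray | None = None
    compartment_accuracy: float | None = None
    consistency: float | None = None
    mode: str = "tad_level"

    def summary(self) -> dict:
        out = {
            "mean_re": self.mean_re,
            "asphericity": self.asphericity,
            "n_tads": len(self.compartment_labels),
            "mode": self.mode,
        }
        if self.compartment_accuracy is not None:
            out["compartment_accuracy"] = self.compartment_accuracy
        if self.consistency is not None:
            out["hic_fish_consistency"] = self.consistency
        return out


def evaluate_model(
    conf: Conformation,
    fish: FishDistanceMatrix,
    tads: TadSet | None = None,
    mode: str = "tad_level",
    reference_labels: np.ndarray | None = None,
    tad_contacts: ContactMap | None = None,
) -> EvaluationReport:
    """Compute the standard metric bundle for a reconstructed model."""
    re, mean_re = relative_error_matrix(conf, fish, mode=mode)
    labels = partition_compartments(conf, tads)
    acc = (
        compartment_accuracy(labels, reference_labels)
        if reference_labels is not None
        else None
    )
    dens = None
    if tads is not None and mode == "final":
        dens = []
        for t in tads:
            frag = conf.coords[conf.tad_slice(t.index)]
            dens.append(tad_density(frag, t) if len(frag) >= 4 else float("nan"))
        dens = np.array(dens)
    cons = (
        hic_fish_consistency(tad_contacts, fish) if tad_contacts is not None else None
    )
    return EvaluationReport(
        re_matrix=re,
        mean_re=mean_re,
        compartment_labels=labels,
        asphericity=asphericity(conf),
        tad_densities=dens,
        compartment_accuracy=acc,
        consistency=cons,
        mode=mode,
    )
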