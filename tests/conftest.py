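import numpy as np
import pytest

from chromofold.synthetic import simulate_fish, simulate_hic, simulate_structure


def central_difference_gradient(fn, x, h=1e-6):
    """Central finite-difference gradient of a scalar function of an array."""
    g = np.zeros_like(x, dtype=float)
    for idx in np.ndindex(x.shape):
        xp = x.copy()
        xm = x.copy()
        xp[idx] += h
        xm[idx] -= h
        g[idx] = (fn(xp) - fn(xm)) / (2 * h)
    return g


def random_rigid_motion(rng):
    """A uniformly random proper rotation and a random translation."""
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    Q = Q * np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    t = rng.normal(scale=2.0, size=3)
    return Q, t


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_truth():
    """20-TAD, single-bead-per-TAD ground truth (backbone == structure)."""
    return simulate_structure(n_tads=20, beads_per_tad=1, seed=0)


@pytest.fixture(scope="session")
def small_bundle(small_truth):
    """(truth, TAD-level Hi-C, noiseless FISH) for backbone tests."""
    hic = simulate_hic(small_truth.backbone_truth)
    fish = simulate_fish(small_truth.backbone_truth)
    return small_truth, hic, fish


@pytest.fixture(scope="session")
def chain_truth():
    """20 TADs x 25 beads continuous-chain truth for full-pipeline tests."""
    return simulate_structure(n_tads=20, beads_per_tad=25, seed=0)
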