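import numpy as np
import pytest
from scipy.spatial.distance import pdist

from chromofold.assembly import (
    AssemblyParams,
    assemble,
    estimate_linker_distances,
    fit_distance_powerlaw,
    integration_cost_and_grad,
    linker_distance,
    rotate_tad_step,
)
from chromofold.datamodel import (
    Conformation,
    FishDistanceMatrix,
    InputError,
    TadSet,
)
from chromofold.synthetic import simulate_fish, simulate_hic, simulate_structure

from conftest import central_difference_gradient


class TestPowerLawFit:
    def test_exact_recovery(self):
        tads = TadSet([("chr1", i * 100, (i + 1) * 100) for i in range(6)])
        g = np.abs(np.subtract.outer(np.arange(6), np.arange(6))) * 100.0
        F = np.where(g > 0, 2.0 * g**0.3, 0.0)
        fish = FishDistanceMatrix(F)
        c, beta = fit_distance_powerlaw(fish, tads)
        assert c == pytest.approx(2.0, abs=1e-9)
        assert beta == pytest.approx(0.3, abs=1e-9)

    def test_constant_distances_give_zero_exponent(self):
        tads = TadSet([("chr1", i * 100, (i + 1) * 100) for i in range(5)])
        F = np.full((5, 5), 1.7)
        np.fill_diagonal(F, 0.0)
        _, beta = fit_distance_powerlaw(FishDistanceMatrix(F), tads)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_too_few_pairs_rejected(self):
        tads = TadSet([("chr1", 0, 100), ("chr1", 100, 200)])
        F = np.array([[0, 1.0], [1.0, 0]])
        with pytest.raises(InputError):
            fit_distance_powerlaw(FishDistanceMatrix(F), tads)


class TestLinkerDistance:
    def test_contact_branch(self):
        params = AssemblyParams(alpha_exponent=-0.25)
        assert linker_distance(16.0, 100, params) == pytest.approx(0.5)
        assert linker_distance(1.0, 100, params) == pytest.approx(1.0)

    def test_powerlaw_branch(self):
        params = AssemblyParams(c=1.0, beta=1 / 3)
        assert linker_distance(0.0, 8.0, params) == pytest.approx(2.0)

    def test_zero_contact_zero_gap_rejected(self):
        with pytest.raises(InputError):
            linker_distance(0.0, 0.0, AssemblyParams())

    def test_inverse_pair_with_simulated_hic(self, chain_truth):
        # noiseless f = d^-4 inverts exactly with alpha = -0.25
        hic = simulate_hic(chain_truth.truth)
        models = [
            Conformation(chain_truth.truth.coords[chain_truth.truth.tad_slice(i)],
                         tad_ids=chain_truth.truth.tad_ids[
                             chain_truth.truth.tad_slice(i)],
                         bins=[chain_truth.truth.bins[k] for k in range(
                             chain_truth.truth.tad_slice(i).start,
                             chain_truth.truth.tad_slice(i).stop)])
            for i in range(len(chain_truth.tads))
        ]
        d = estimate_linker_distances(models, hic, AssemblyParams())
        expected = [
            np.linalg.norm(models[i + 1].coords[0] - models[i].coords[-1])
            for i in range(len(models) - 1)
        ]
        np.testing.assert_allclose(d, expected, rtol=1e-9)


class TestIntegrationCost:
    def test_zero_when_gaps_match(self):
        frags = [
            Conformation(np.array([[0.0, 0, 0], [1.0, 0, 0]])),
            Conformation(np.array([[2.0, 0, 0], [3.0, 0, 0]])),
        ]
        c, g = integration_cost_and_grad(frags, np.array([1.0]))
        assert c == 0.0
        np.testing.assert_array_equal(g, 0.0)

    def test_single_junction_closed_form(self):
        # gap 2, target 1: C = 1, |dC/dy_s| = 2
        frags = [
            Conformation(np.array([[0.0, 0, 0]])),
            Conformation(np.array([[2.0, 0, 0]])),
        ]
        c, g = integration_cost_and_grad(frags, np.array([1.0]))
        assert c == pytest.approx(1.0)
        np.testing.assert_allclose(g[0], [2.0, 0, 0])

    @pytest.mark.parametrize("seed", range(3))
    def test_gradient_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        sizes = [3, 4, 2, 5]
        coords = [rng.normal(size=(s, 3)) for s in sizes]
        d = np.abs(rng.normal(size=3)) + 0.1

        def cost_of_starts(x):
            frags = []
            for i, c0 in enumerate(coords):
                c2 = c0.copy()
                if i > 0:
                    c2[0] = x[i - 1]
                frags.append(Conformation(c2))
            return integration_cost_and_grad(frags, d)[0]

        starts = np.array([c[0] for c in coords[1:]])
        _, g = integration_cost_and_grad([Conformation(c) for c in coords], d)
        gfd = central_difference_gradient(cost_of_starts, starts)
        np.testing.assert_allclose(g, gfd, rtol=1e-5, atol=1e-8)


class TestRotateTadStep:
    def test_identity_when_target_is_current(self, rng):
        frag = Conformation(rng.normal(size=(5, 3)))
        center = frag.coords.mean(axis=0)
        out = rotate_tad_step(frag, center, frag.coords[0])
        np.testing.assert_allclose(out.coords, frag.coords, atol=1e-12)

    def test_ninety_degree_rotation(self):
        frag = Conformation(np.array([[1.0, 0, 0], [0.5, 0, 0.5]]))
        out = rotate_tad_step(frag, np.zeros(3), np.array([0.0, 1.0, 0]))
        np.testing.assert_allclose(out.coords[0], [0.0, 1.0, 0], atol=1e-12)

    def test_rigid_motion_contract(self, rng):
        frag = Conformation(rng.normal(size=(8, 3)))
        center = rng.normal(size=3)
        target = rng.normal(size=3)
        out = rotate_tad_step(frag, center, target)
        np.testing.assert_allclose(pdist(out.coords), pdist(frag.coords),
                                   atol=1e-9)
        # rotation about the center leaves the center fixed
        rel0 = frag.coords - center
        rel1 = out.coords - center
        np.testing.assert_allclose(np.linalg.norm(rel0, axis=1),
                                   np.linalg.norm(rel1, axis=1), atol=1e-9)

    def test_collinear_target_is_identity(self, rng):
        frag = Conformation(rng.normal(size=(4, 3)))
        center = np.zeros(3)
        target = 3.0 * frag.coords[0]  # collinear with the radius vector
        out = rotate_tad_step(frag, center, target)
        np.testing.assert_allclose(out.coords, frag.coords, atol=1e-12)


def _cut_into_tads(truth):
    frags = []
    for i in range(len(truth.tads)):
        sl = truth.truth.tad_slice(i)
        frags.append(Conformation(truth.truth.coords[sl].copy(),
                                  tad_ids=truth.truth.tad_ids[sl].copy()))
    return frags


def _true_linkers(frags):
    return np.array([
        np.linalg.norm(frags[i + 1].coords[0] - frags[i].coords[-1])
        for i in range(len(frags) - 1)
    ])


class TestAssemble:
    def test_already_consistent_input_is_fixed_point(self):
        truth = simulate_structure(n_tads=5, beads_per_tad=10, seed=2)
        frags = _cut_into_tads(truth)
        d = _true_linkers(frags)
        backbone = truth.backbone_truth
        result = assemble(backbone, frags, None,
                          AssemblyParams(max_iter=20), linker_distances=d)
        assert result.cost == pytest.approx(0.0, abs=1e-16)
        np.testing.assert_allclose(result.conformation.coords,
                                   truth.truth.coords, atol=1e-9)

    def test_centroids_and_rigidity_and_monotone(self):
        truth = simulate_structure(n_tads=5, beads_per_tad=12, seed=4)
        frags = _cut_into_tads(truth)
        d = _true_linkers(frags)
        rng = np.random.default_rng(0)
        scrambled = []
        for f in frags:
            c = f.coords.mean(axis=0)
            Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            scrambled.append(f.with_coords((f.coords - c) @ Q.T + c))
        result = assemble(truth.backbone_truth, scrambled, None,
                          AssemblyParams(max_iter=100), linker_distances=d)
        hist = result.cost_history
        assert all(b <= a + 1e-12 for a, b in zip(hist, hist[1:]))
        out = result.conformation
        for i, f in enumerate(scrambled):
            sl = out.tad_slice(i)
            np.testing.assert_allclose(out.coords[sl].mean(axis=0),
                                       truth.backbone_truth.coords[i],
                                       atol=1e-9)
            np.testing.assert_allclose(pdist(out.coords[sl]),
                                       pdist(f.coords), atol=1e-9)
        for p in result.placements:
            np.testing.assert_allclose(p.rotation @ p.rotation.T, np.eye(3),
                                       atol=1e-9)
            assert np.linalg.det(p.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_reflection_resolves_antipodal_chirality(self):
        # TAD 2's junction endpoint points exactly away from its target and
        # its neighbor is a single point that cannot rotate, so the rotation
        # axis stays undefined forever; only the mirror step can close the
        # gap, and it must win strictly
        frag1 = Conformation(np.array([[0.0, 0.0, 0.0]]))
        frag2 = Conformation(np.array([[1.3, 0, 0], [1.0, 0.05, 0],
                                       [0.7, -0.05, 0]]), tad_ids=[1, 1, 1])
        backbone = Conformation(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        d = np.array([0.4])
        off = assemble(backbone, [frag1, frag2], None,
                       AssemblyParams(max_iter=40, try_reflection=False),
                       linker_distances=d)
        on = assemble(backbone, [frag1, frag2], None,
                      AssemblyParams(max_iter=40, try_reflection=True),
                      linker_distances=d)
        assert off.cost == pytest.approx((1.3 - 0.4) ** 2)
        assert on.cost < off.cost
        assert any(p.reflected for p in on.placements)

    def test_input_length_mismatch_rejected(self):
        truth = simulate_structure(n_tads=3, beads_per_tad=5, seed=0)
        frags = _cut_into_tads(truth)
        with pytest.raises(InputError):
            assemble(truth.backbone_truth, frags[:2], None,
                     AssemblyParams(), linker_distances=np.array([0.1, 0.1]))
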