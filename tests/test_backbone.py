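import numpy as np
import pytest

from chromofold.backbone import (
    BackboneProblem,
    backbone_cost_and_grad,
    compute_affinity,
    compute_embedding_prob,
    fish_cost_and_grad,
    kl_cost,
    kl_cost_and_grad,
    optimize_backbone,
)
from chromofold.datamodel import ContactMap, FishDistanceMatrix, InputError
from chromofold.optim import OptimizerConfig, gradient_descent
from chromofold.evaluation import relative_error_matrix
from chromofold.synthetic import (
    BENCHMARK_BACKBONE_LAMBDAS,
    simulate_fish,
    simulate_hic,
    simulate_structure,
)

from conftest import central_difference_gradient, random_rigid_motion


class TestAffinity:
    def test_uniform_map(self):
        p = compute_affinity(np.ones((3, 3)))
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(p[off], 1 / 6)

    def test_single_pair(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 5.0
        p = compute_affinity(m)
        assert p[0, 1] == p[1, 0] == pytest.approx(0.5)

    def test_normalization(self, rng):
        m = np.abs(rng.normal(size=(5, 5)))
        m = m + m.T
        assert compute_affinity(m).sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(InputError):
            compute_affinity(np.zeros((4, 4)))


class TestEmbeddingProb:
    def test_two_points(self, rng):
        q = compute_embedding_prob(rng.normal(size=(2, 3)))
        assert q[0, 1] == q[1, 0] == pytest.approx(0.5)

    def test_equilateral_triangle(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0.5, np.sqrt(3) / 2, 0]])
        q = compute_embedding_prob(pts)
        off = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(q[off], 1 / 6)

    def test_normalization(self, rng):
        q = compute_embedding_prob(rng.normal(size=(4, 3)))
        assert q.sum() == pytest.approx(1.0, abs=1e-12)


class TestKL:
    def test_zero_iff_equal(self, rng):
        coords = rng.normal(size=(5, 3))
        q = compute_embedding_prob(coords)
        assert kl_cost(q, q) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_value(self):
        # all mass on one symmetric pair vs uniform over 6 ordered pairs:
        # C1 = 2 * (1/2) * log((1/2)/(1/6)) = log 3
        P = np.zeros((3, 3))
        P[0, 1] = P[1, 0] = 0.5
        Q = np.full((3, 3), 1 / 6)
        np.fill_diagonal(Q, 0.0)
        assert kl_cost(P, Q) == pytest.approx(np.log(3.0))

    def test_positive_when_different(self, rng):
        for _ in range(20):
            P = compute_affinity(np.abs(rng.normal(size=(6, 6))) + 0.01)
            P = 0.5 * (P + P.T)
            Q = compute_embedding_prob(rng.normal(size=(6, 3)))
            assert kl_cost(P, Q) > 0


class TestFishCost:
    def test_exact_distances_zero_cost(self, rng):
        coords = rng.normal(size=(6, 3))
        fish = simulate_fish(_conf(coords))
        c, g = fish_cost_and_grad(coords, fish)
        assert c == pytest.approx(0.0, abs=1e-18)
        np.testing.assert_allclose(g, 0.0, atol=1e-9)

    def test_ordered_double_count_closed_form(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0]])
        fish = FishDistanceMatrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        c, _ = fish_cost_and_grad(coords, fish)
        assert c == pytest.approx(2.0)  # both ordered pairs count

    def test_missing_entries_skipped(self):
        coords = np.array([[0.0, 0, 0], [2.0, 0, 0], [0, 3.0, 0]])
        m = np.array([[0, 1.0, np.nan], [1.0, 0, 1.0], [np.nan, 1.0, 0]])
        fish = FishDistanceMatrix(m)
        c, _ = fish_cost_and_grad(coords, fish)
        d12 = np.linalg.norm(coords[1] - coords[2])
        assert c == pytest.approx(2 * (2 - 1) ** 2 + 2 * (d12 - 1) ** 2)


def _conf(coords):
    from chromofold.datamodel import Conformation

    return Conformation(coords)


class TestGradients:
    @pytest.mark.parametrize("seed", range(5))
    def test_kl_gradient_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(7, 3))
        P = compute_affinity(np.abs(rng.normal(size=(7, 7))) + 0.05)
        _, g = kl_cost_and_grad(P, coords)
        gfd = central_difference_gradient(
            lambda x: kl_cost_and_grad(P, x)[0], coords
        )
        np.testing.assert_allclose(g, gfd, rtol=1e-5, atol=1e-8)

    @pytest.mark.parametrize("seed", range(5))
    def test_fish_gradient_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.normal(size=(6, 3))
        fish = simulate_fish(_conf(rng.normal(size=(6, 3))))
        _, g = fish_cost_and_grad(coords, fish)
        gfd = central_difference_gradient(
            lambda x: fish_cost_and_grad(x, fish)[0], coords
        )
        np.testing.assert_allclose(g, gfd, rtol=1e-5, atol=1e-8)

    def test_full_cost_gradient_finite_differences(self, small_bundle):
        truth, hic, fish = small_bundle
        rng = np.random.default_rng(1)
        sub = slice(0, 6)
        prob = BackboneProblem(
            tad_contacts=ContactMap(hic.matrix[sub, sub]),
            fish=FishDistanceMatrix(fish.matrix[sub, sub]),
            lambda_E=0.3, lambda_F=0.7,
        )
        coords = rng.normal(size=(6, 3))
        _, g = backbone_cost_and_grad(prob, coords)
        gfd = central_difference_gradient(
            lambda x: backbone_cost_and_grad(prob, x)[0], coords
        )
        np.testing.assert_allclose(g, gfd, rtol=1e-5, atol=1e-8)


class TestCostComposition:
    def test_kl_only_when_lambdas_zero(self, small_bundle):
        _, hic, fish = small_bundle
        prob = BackboneProblem(tad_contacts=hic, fish=fish,
                               lambda_E=0.0, lambda_F=0.0)
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(hic.n, 3))
        c, _ = backbone_cost_and_grad(prob, coords)
        c1, _ = kl_cost_and_grad(prob.affinity, coords)
        assert c == pytest.approx(c1)

    def test_rigid_motion_invariance_of_cost(self, small_bundle, rng):
        _, hic, fish = small_bundle
        prob = BackboneProblem(tad_contacts=hic, fish=fish,
                               lambda_E=0.1, lambda_F=1.0)
        coords = rng.normal(size=(hic.n, 3))
        c0, _ = backbone_cost_and_grad(prob, coords)
        Q, t = random_rigid_motion(rng)
        c1, _ = backbone_cost_and_grad(prob, coords @ Q.T + t)
        assert abs(c1 - c0) < 1e-9 * abs(c0)

    def test_large_lambda_f_approaches_distance_fit(self):
        # with the FISH term dominant the optimizer reproduces the exact
        # distance geometry, like a metric (MDS-style) fit
        truth = simulate_structure(n_tads=4, beads_per_tad=1, seed=5)
        hic = simulate_hic(truth.backbone_truth)
        fish = simulate_fish(truth.backbone_truth)
        prob = BackboneProblem(
            tad_contacts=hic, fish=fish, lambda_E=0.0, lambda_F=1e4,
            opt=OptimizerConfig(learning_rate=1e-5, max_iter=8000,
                                rel_tol=1e-13, seed=0, init_scale=0.5),
        )
        conf = optimize_backbone(prob)
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(conf.coords),
                                   pdist(truth.backbone_truth.coords),
                                   rtol=0.02)


class TestOptimizer:
    def test_monotone_cost_trajectory(self, small_bundle):
        _, hic, fish = small_bundle
        lamE, lamF = BENCHMARK_BACKBONE_LAMBDAS
        prob = BackboneProblem(tad_contacts=hic, fish=fish,
                               lambda_E=lamE, lambda_F=lamF,
                               opt=OptimizerConfig(learning_rate=0.1,
                                                   max_iter=300, seed=0,
                                                   init_scale=1.0))
        rng = np.random.default_rng(0)
        x0 = rng.normal(scale=1.0, size=(hic.n, 3))
        _, history = gradient_descent(
            x0, lambda x: backbone_cost_and_grad(prob, x), prob.opt
        )
        assert all(b <= a + 1e-12 for a, b in zip(history, history[1:]))

    def test_max_iter_zero_returns_initialization(self, small_bundle):
        _, hic, fish = small_bundle
        opt = OptimizerConfig(learning_rate=0.1, max_iter=0, seed=3,
                              init_scale=1.0)
        prob = BackboneProblem(tad_contacts=hic, fish=fish, lambda_E=0.0,
                               lambda_F=1.0, opt=opt)
        conf = optimize_backbone(prob)
        expected = np.random.default_rng(3).normal(scale=1.0, size=(hic.n, 3))
        np.testing.assert_array_equal(conf.coords, expected)

    def test_same_seed_identical_output(self, small_bundle):
        _, hic, fish = small_bundle
        lamE, lamF = BENCHMARK_BACKBONE_LAMBDAS
        kwargs = dict(tad_contacts=hic, fish=fish, lambda_E=lamE,
                      lambda_F=lamF)
        a = optimize_backbone(BackboneProblem(**kwargs))
        b = optimize_backbone(BackboneProblem(**kwargs))
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_synthetic_truth_recovery(self):
        truth = simulate_structure(n_tads=20, beads_per_tad=1, seed=11)
        hic = simulate_hic(truth.backbone_truth)
        fish = simulate_fish(truth.backbone_truth)
        lamE, lamF = BENCHMARK_BACKBONE_LAMBDAS
        prob = BackboneProblem(tad_contacts=hic, fish=fish,
                               lambda_E=lamE, lambda_F=lamF)
        conf = optimize_backbone(prob)
        _, mean_re = relative_error_matrix(conf, fish, mode="tad_level")
        assert mean_re <= 0.05
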