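"""Generative structural agents: scores, losses, gradients, training."""

import numpy as np
import pytest
from scipy.stats import chisquare, rankdata

import alignsim as al
from alignsim.generative import (
    GenerativeConfig,
    GenerativeWorld,
    MonthNormalizer,
    _probe_columns_for,
    _sample_slate,
    aoa_matched_loss,
    calibrate_normalizers,
    candidate_distribution,
    generative_scores,
    selection_backward,
    selection_distribution,
    soft_alignment_loss,
    weighted_pearson,
)


@pytest.fixture(scope="module")
def gen_world():
    world = al.make_fixture("noisy30")
    return GenerativeWorld.build(
        world.pair, world.table, world.schedule, np.random.default_rng(50)
    )


def relative_error(analytic, fd):
    scale = max(np.max(np.abs(fd)), 1e-3)
    return np.max(np.abs(analytic - fd)) / scale


def finite_difference(loss_fn, x, w, eps=1e-6):
    k = len(x)
    fd_x = np.empty(k)
    fd_w = np.empty(k)
    for i in range(k):
        e = eps * np.eye(k)[i]
        fd_x[i] = (loss_fn(x + e, w) - loss_fn(x - e, w)) / (2 * eps)
        fd_w[i] = (loss_fn(x, w + e) - loss_fn(x, w - e)) / (2 * eps)
    return fd_x, fd_w


class TestGenerativeScores:
    def test_hand_computed_oracle(self):
        A = np.array([[0.2, 0.8], [0.5, 0.5], [0.9, 0.1]])
        x_hat = np.array([0.5, 0.5])
        w = np.array([1.0, 2.0])
        s = generative_scores(A, x_hat, w)
        expected = [-(0.3 * 1 + 0.3 * 2), 0.0, -(0.4 * 1 + 0.4 * 2)]
        np.testing.assert_allclose(s, expected)

    def test_target_hit_is_maximum_under_positive_weights(self, rng):
        A = rng.random((6, 3))
        x_hat = A[2].copy()
        w = np.array([0.5, 1.0, 2.0])
        s = generative_scores(A, x_hat, w)
        assert s[2] == 0.0 and np.argmax(s) == 2

    def test_zero_weights_give_all_zero_scores(self, rng):
        s = generative_scores(rng.random((5, 3)), rng.random(3), np.zeros(3))
        np.testing.assert_array_equal(s, 0.0)


class TestCandidateDistribution:
    def test_equal_scores_uniform(self):
        np.testing.assert_allclose(
            candidate_distribution(np.array([3.0, 3.0]), 0.05), [0.5, 0.5]
        )

    def test_temperature_limits(self):
        s = np.array([1.0, 0.5, 0.0])
        hot = candidate_distribution(s, 1e3)
        np.testing.assert_allclose(hot, 1 / 3, atol=1e-3)
        cold = candidate_distribution(s, 1e-3)
        assert cold[0] == pytest.approx(1.0, abs=1e-6)

    def test_two_candidate_closed_form(self):
        """Any two distinct scores standardize to +/-1, so the softmax is
        sigmoid(2/T) on the larger one."""
        from scipy.special import expit

        for pair in ([1.0, 0.0], [10.0, -3.0]):
            p = candidate_distribution(np.array(pair), 0.5)
            assert p[0] == pytest.approx(expit(4.0))

    def test_shift_invariance(self, rng):
        s = rng.random(7)
        p1 = candidate_distribution(s, 0.05)
        p2 = candidate_distribution(s + 123.4, 0.05)
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        assert p1.sum() == pytest.approx(1.0)

    def test_permutation_equivariance(self, rng):
        s = rng.random(6)
        perm = rng.permutation(6)
        np.testing.assert_allclose(
            candidate_distribution(s, 0.05)[perm],
            candidate_distribution(s[perm], 0.05),
            atol=1e-12,
        )


class TestWeightedPearson:
    def test_equal_weights_match_corrcoef(self, rng):
        x, y = rng.random(10), rng.random(10)
        r, _ = weighted_pearson(x, y, np.ones(10))
        assert r == pytest.approx(np.corrcoef(x, y)[0, 1])

    def test_gradient_matches_finite_differences(self, rng):
        x, y = rng.random(8), rng.random(8)
        wts = rng.random(8) + 0.5
        _, grad = weighted_pearson(x, y, wts)
        eps = 1e-7
        for i in range(8):
            e = np.zeros(8)
            e[i] = eps
            rp, _ = weighted_pearson(x, y, wts + e)
            rm, _ = weighted_pearson(x, y, wts - e)
            assert grad[i] == pytest.approx((rp - rm) / (2 * eps), abs=1e-5)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(50):
            r, _ = weighted_pearson(
                rng.random(6), rng.random(6), rng.random(6) + 0.1
            )
            assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12


class TestAoaMatchedLoss:
    def norm(self):
        return MonthNormalizer(16, mu=0.1, sigma=0.05, floor=0.0)

    def test_perfect_match_is_zero(self):
        q = np.array([0.3, 0.7])
        boots = np.array([[1.0, 0.3, 0.7]])
        loss, raw, _ = aoa_matched_loss(
            q, np.array([1, 2]), np.array([0]), boots, self.norm()
        )
        assert raw == pytest.approx(0.0) and loss == pytest.approx(0.0)

    def test_uniform_vs_deterministic_two_concepts(self):
        q = np.array([0.5, 0.5])
        boots = np.array([[1.0, 0.0]])
        loss, raw, _ = aoa_matched_loss(
            q, np.array([0, 1]), np.array([], dtype=int), boots, self.norm()
        )
        assert raw == pytest.approx(0.25)

    def test_z_shift_arithmetic(self):
        """raw 0.2 with (mu, sigma) = (0.1, 0.05): z(raw) - z(0) = 4."""
        norm = self.norm()
        assert norm.normalize(0.2) == pytest.approx(
            (0.2 - 0.1) / 0.05 - (0.0 - 0.1) / 0.05
        )
        assert norm.normalize(0.2) == pytest.approx(4.0)

    def test_candidates_outside_table_ignored(self):
        q = np.array([0.4, 0.6])
        boots = np.array([[0.5, 0.5]])
        loss1, raw1, gq = aoa_matched_loss(
            q, np.array([0, -1]), np.array([], dtype=int), boots, self.norm()
        )
        assert gq[1] == 0.0
        # raw MSE: concept0 (0.4-0.5)^2, concept1 (0-0.5)^2, over 2 concepts
        assert raw1 == pytest.approx((0.01 + 0.25) / 2)


class TestSoftAlignmentLoss:
    def norm(self):
        return MonthNormalizer(16, mu=-0.1, sigma=0.05, floor=-2.0)

    def test_symmetric_pair_gives_zero_margin(self):
        """Probe columns identical for the two items: swapping changes
        nothing, the margin is 0 and the loss is (0+2)/sigma."""
        cols = np.array([[[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]]])
        norm = self.norm()
        loss, raw, _ = soft_alignment_loss(
            np.array([0.5, 0.5]), 1, cols, cols, norm
        )
        assert raw == pytest.approx(0.0)
        assert loss == pytest.approx(2.0 / 0.05)

    def test_disambiguating_state_gives_negative_margin(self, mirror10, rng):
        """In a mirrored world a knowledge state separates correct from
        incorrect mappings: s_correct > s_incorrect, raw margin < 0."""
        world = mirror10
        gw = GenerativeWorld.build(
            world.pair, world.table, world.schedule, rng
        )
        cand_ids = np.arange(6)
        pairs = np.array([[7, 8], [8, 9], [7, 9]])
        vis, lin = _probe_columns_for(gw, pairs, cand_ids)
        q = np.array([0.5, 0.5])  # 4 acquired + 2 candidates
        _, raw, _ = soft_alignment_loss(q, 4, vis, lin, self.norm())
        assert raw < 0

    def test_margin_bounded_by_two(self, rng):
        for trial in range(30):
            n_cand = 5
            vis = rng.random((2, 2, n_cand))
            lin = rng.random((2, 2, n_cand))
            q = rng.random(2) + 0.1
            _, raw, _ = soft_alignment_loss(q, 3, vis, lin, self.norm())
            assert -2.0 - 1e-9 <= raw <= 2.0 + 1e-9

    def test_floor_shift_makes_loss_nonnegative(self):
        norm = self.norm()
        assert norm.normalize(-2.0) == 0.0
        assert norm.normalize(-1.5) > 0.0


class TestGradients:
    def test_selection_head_with_aoa_loss(self, gen_world, rng):
        gw = gen_world
        state = list(gw.pair.shared_concepts[:4])
        cands = list(gw.pair.shared_concepts[4:14])
        A = gw.feature_space.candidate_matrix(state, cands)
        k = A.shape[1]
        x, w = rng.uniform(0, 1, k), rng.uniform(0.01, 0.2, k)
        boot = al.bootstrap_distributions(
            gw.table, 4, 10, gw.schedule, np.random.default_rng(2)
        )
        boots = boot.train[:, :, 0]
        cand_pos = np.array([gw.table_index.get(c, -1) for c in cands])
        acq_pos = np.array(
            [gw.table_index[c] for c in state if c in gw.table_index], dtype=int
        )
        norm = MonthNormalizer(16, 0.05, 0.02, 0.0)

        def loss_fn(x_, w_):
            q, _ = selection_distribution(A, x_, w_, 0.05)
            return aoa_matched_loss(q, cand_pos, acq_pos, boots, norm)[0]

        q, cache = selection_distribution(A, x, w, 0.05)
        _, _, gq = aoa_matched_loss(q, cand_pos, acq_pos, boots, norm)
        gx, gw_ = selection_backward(cache, gq)
        fd_x, fd_w = finite_difference(loss_fn, x, w)
        assert relative_error(gx, fd_x) < 1e-4
        assert relative_error(gw_, fd_w) < 1e-4

    def test_selection_head_with_task_loss(self, gen_world, rng):
        gw = gen_world
        state = list(gw.pair.shared_concepts[:4])
        cands = list(gw.pair.shared_concepts[4:14])
        A = gw.feature_space.candidate_matrix(state, cands)
        k = A.shape[1]
        x, w = rng.uniform(0, 1, k), rng.uniform(0.01, 0.2, k)
        cand_ids = np.array([gw.index[c] for c in state + cands])
        outside = np.array(
            [gw.index[c] for c in gw.pair.shared_concepts
             if c not in set(state + cands)]
        )
        slate = _sample_slate(outside, 8, rng)
        vis, lin = _probe_columns_for(gw, slate, cand_ids)
        norm = MonthNormalizer(16, -0.1, 0.05, -2.0)

        def loss_fn(x_, w_):
            q, _ = selection_distribution(A, x_, w_, 0.05)
            return soft_alignment_loss(q, len(state), vis, lin, norm)[0]

        q, cache = selection_distribution(A, x, w, 0.05)
        _, _, gq = soft_alignment_loss(q, len(state), vis, lin, norm)
        gx, gw_ = selection_backward(cache, gq)
        fd_x, fd_w = finite_difference(loss_fn, x, w)
        assert relative_error(gx, fd_x) < 1e-4
        assert relative_error(gw_, fd_w) < 1e-4


class TestCalibration:
    def test_monte_carlo_stability(self, gen_world):
        gw = gen_world
        boot = al.bootstrap_distributions(
            gw.table, 4, 15, gw.schedule, np.random.default_rng(4)
        )
        n1 = calibrate_normalizers(
            "aoa_matched", gw, np.random.default_rng(0), boot=boot,
            n_samples=400,
        )
        n2 = calibrate_normalizers(
            "aoa_matched", gw, np.random.default_rng(1), boot=boot,
            n_samples=800,
        )
        for month in gw.schedule.months:
            sem = n1[month].sigma / np.sqrt(400)
            assert abs(n1[month].mu - n2[month].mu) < 4 * sem + 1e-9

    def test_normalized_losses_nonnegative(self, gen_world):
        gw = gen_world
        rng = np.random.default_rng(9)
        norms = calibrate_normalizers(
            "task_optimized", gw, rng, n_samples=150,
            candidate_set_size=20,
        )
        for month, norm in norms.items():
            assert norm.floor == -2.0
            for _ in range(50):
                raw = rng.uniform(-2.0, 2.0)
                assert norm.normalize(raw) >= 0.0

    def test_degenerate_sigma_raises(self):
        with pytest.raises(ValueError, match="sigma"):
            MonthNormalizer(16, 0.5, 0.0, 0.0)


class TestTrainingAndGeneration:
    def test_zero_learning_rate_keeps_initialization(self, gen_world):
        gw = gen_world
        boot = al.bootstrap_distributions(
            gw.table, 4, 10, gw.schedule, np.random.default_rng(6)
        )
        models = []
        for epochs in (1, 3):
            config = GenerativeConfig(
                epochs=epochs, restarts=1, learning_rate=0.0,
                normalizer_samples=100, seed=77,
            ).scaled_for_vocab(gw.pair.n_concepts)
            model, _ = al.train_agent(
                "aoa_matched", config, gw, boot=boot
            )
            models.append(model)
        np.testing.assert_array_equal(models[0].x_hat, models[1].x_hat)
        np.testing.assert_array_equal(models[0].w, models[1].w)

    def test_training_reproducible_with_seed(self, gen_world):
        gw = gen_world
        boot = al.bootstrap_distributions(
            gw.table, 4, 10, gw.schedule, np.random.default_rng(6)
        )
        config = GenerativeConfig(
            epochs=2, restarts=2, normalizer_samples=100, seed=11
        ).scaled_for_vocab(gw.pair.n_concepts)
        m1, h1 = al.train_agent("aoa_matched", config, gw, boot=boot)
        m2, h2 = al.train_agent("aoa_matched", config, gw, boot=boot)
        np.testing.assert_array_equal(m1.x_hat, m2.x_hat)
        assert h1.equals(h2)

    def test_zero_weight_model_samples_uniformly(self):
        """With w = 0 every candidate scores equally: the selected concept
        is uniform over the remaining candidates."""
        config = al.SyntheticConfig(
            n_concepts=6, n_clusters=2, alignment_noise=0.1,
            aoa_fraction=0.9, seed=31,
        )
        world = al.generate_world(config)
        table = world.table
        schedule = al.MonthSchedule((16,), (3,))
        gw = GenerativeWorld.build(
            world.pair, table, schedule, np.random.default_rng(1)
        )
        model = al.InternalModel(
            gw.feature_space.names,
            np.full(len(gw.feature_space.names), 0.5),
            np.zeros(len(gw.feature_space.names)),
        )
        gen_config = GenerativeConfig(seed=0).scaled_for_vocab(6)
        rng = np.random.default_rng(123)
        counts = {c: 0 for c in world.pair.shared_concepts}
        n_runs = 1500
        for _ in range(n_runs):
            states = al.generate_sequence(model, gw, gen_config, rng)
            for c in states[-1].concepts:
                counts[c] += 1
        # every concept acquired equally often across runs
        observed = np.array(list(counts.values()))
        chi = chisquare(observed)
        assert chi.pvalue > 0.001

    def test_generated_states_match_schedule_sizes(self, gen_world):
        gw = gen_world
        k = len(gw.feature_space.names)
        model = al.InternalModel(
            gw.feature_space.names,
            np.full(k, 0.5),
            np.full(k, 0.1),
        )
        config = GenerativeConfig(seed=0).scaled_for_vocab(gw.pair.n_concepts)
        states = al.generate_sequence(
            model, gw, config, np.random.default_rng(5)
        )
        sizes = [len(s) for s in states]
        assert sizes == list(gw.schedule.cumulative)
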