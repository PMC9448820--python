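import math

import numpy as np
import pytest
from autograd import grad
from autograd.misc.flatten import flatten

from thyropanel import CohortConfig, generate_cohort, split_cohort
from thyropanel import dmt
from thyropanel.metrics import roc_auc
from thyropanel.preprocess import fit_normalizer, apply_normalizer, filter_by_missing_rate

from _oracles import (
    similarities_loops,
    symmetrize_loops,
    t_density_kernel,
    two_way_divergence_loops,
    weighted_ce_loops,
)


def tiny_config(**overrides):
    kwargs = dict(layer_widths=(8, 6), latent_dim=4, epochs=25, batch_size=64, n_folds=3, seed=0)
    kwargs.update(overrides)
    return dmt.NetConfig(**kwargs)


class TestTKernel:
    def test_zero_distance_nu_one_is_inv_pi(self):
        val = np.asarray(dmt.t_kernel(np.array([[0.0]]), 1.0))
        assert val[0, 0] == pytest.approx(1 / math.pi, rel=1e-12)

    def test_strictly_decreasing_in_distance(self):
        for nu in (0.5, 1.0, 10.0, 100.0):
            d = np.linspace(0, 10, 50)
            vals = np.asarray(dmt.t_kernel(d, nu))
            assert np.all(np.diff(vals) < 0)

    def test_matches_log_gamma_oracle_at_two(self):
        val = float(dmt.t_kernel(np.array([2.0]), 100.0)[0])
        assert val == pytest.approx(t_density_kernel(2.0, 100.0), rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            dmt.t_kernel(np.array([0.0]), 0.0)
        with pytest.raises(ValueError):
            dmt.t_kernel(np.array([np.inf]), 1.0)


class TestSymmetrize:
    def test_symmetric_entry_formula(self):
        a = 0.3
        A = np.full((2, 2), a)
        S = dmt.symmetrize(A)
        assert S[0, 1] == pytest.approx(2 * a * (1 - a))

    def test_all_ones_gives_zero(self):
        S = dmt.symmetrize(np.ones((3, 3)))
        np.testing.assert_array_equal(S, np.zeros((3, 3)))

    def test_random_matrix_against_loop_oracle(self, rng):
        A = rng.uniform(0.05, 0.95, (4, 4))
        S = dmt.symmetrize(A)
        np.testing.assert_allclose(S, symmetrize_loops(A), rtol=1e-12)
        np.testing.assert_allclose(S, S.T, rtol=1e-12)
        assert np.all(S > 0) and np.all(S < 1)


class TestPairwiseSimilarities:
    def test_identical_vectors_nu_one(self):
        X = np.zeros((2, 3))
        # pre-symmetrization similarity at distance 0 is 2*pi*kappa(0,1)^2
        pre = 2 * math.pi * t_density_kernel(0.0, 1.0) ** 2
        assert pre == pytest.approx(2 / math.pi, rel=1e-12)
        S = np.asarray(dmt.pairwise_similarities(X, 1.0))
        assert S[0, 1] == pytest.approx(2 * pre * (1 - pre), rel=1e-10)

    def test_identical_vectors_nu_hundred(self):
        pre = 2 * math.pi * t_density_kernel(0.0, 100.0) ** 2
        assert pre == pytest.approx(0.995, abs=1e-3)
        assert pre < 1.0

    @pytest.mark.parametrize("nu", [0.5, 1.0, 10.0, 100.0])
    def test_preclamp_similarity_in_unit_interval(self, nu):
        for d in np.linspace(0, 50, 200):
            val = 2 * math.pi * t_density_kernel(d, nu) ** 2
            assert 0.0 < val < 1.0

    def test_single_vector_rejected(self):
        with pytest.raises(ValueError):
            dmt.pairwise_similarities(np.zeros((1, 3)), 1.0)

    def test_matches_loop_oracle(self, rng):
        X = rng.standard_normal((5, 4))
        S = np.asarray(dmt.pairwise_similarities(X, 100.0, 1e-6))
        np.testing.assert_allclose(S, similarities_loops(X, 100.0, 1e-6), rtol=1e-10)


class TestDMTLoss:
    def test_zero_when_equal(self, rng):
        P = rng.uniform(0.1, 0.9, (4, 4))
        P = (P + P.T) / 2
        assert float(dmt.dmt_loss(P, P)) == 0.0

    def test_single_pair_example(self):
        P = np.array([[0.5, 0.8], [0.8, 0.5]])
        Q = np.array([[0.5, 0.2], [0.2, 0.5]])
        expected = 2 * (0.8 * math.log(4) + 0.2 * math.log(0.25))
        assert float(dmt.dmt_loss(P, Q)) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.6636, abs=1e-4)

    def test_nonnegative_on_random_draws(self, rng):
        for _ in range(1000):
            P = rng.uniform(0.01, 0.99, (3, 3))
            Q = rng.uniform(0.01, 0.99, (3, 3))
            assert float(dmt.dmt_loss(P, Q)) >= 0.0

    def test_permutation_invariance(self, rng):
        P = rng.uniform(0.1, 0.9, (5, 5))
        Q = rng.uniform(0.1, 0.9, (5, 5))
        perm = rng.permutation(5)
        before = float(dmt.dmt_loss(P, Q))
        after = float(dmt.dmt_loss(P[np.ix_(perm, perm)], Q[np.ix_(perm, perm)]))
        assert after == pytest.approx(before, rel=1e-12)

    def test_matches_loop_oracle(self, rng):
        P = rng.uniform(0.1, 0.9, (5, 5))
        Q = rng.uniform(0.1, 0.9, (5, 5))
        assert float(dmt.dmt_loss(P, Q)) == pytest.approx(
            two_way_divergence_loops(P, Q), rel=1e-10
        )


class TestWeightedCrossEntropy:
    def test_beta_one_is_standard_bce(self, rng):
        y = rng.integers(0, 2, 20)
        p = rng.uniform(0.05, 0.95, 20)
        ours = float(dmt.weighted_cross_entropy(y, p, 1.0))
        standard = -float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        assert ours == pytest.approx(standard, rel=1e-12)

    def test_single_benign_at_half(self):
        val = float(dmt.weighted_cross_entropy(np.array([1]), np.array([0.5]), 1.6))
        assert val == pytest.approx(1.6 * math.log(2), rel=1e-12)
        assert val == pytest.approx(1.1090, abs=1e-4)

    def test_perfect_predictions_vanish_with_eps(self):
        y = np.array([1, 0])
        p = np.array([1.0, 0.0])
        losses = [
            float(dmt.weighted_cross_entropy(y, p, 1.6, eps_clamp=e))
            for e in (1e-2, 1e-4, 1e-8)
        ]
        assert losses[0] > losses[1] > losses[2]
        assert losses[2] < 1e-6

    def test_matches_loop_oracle(self, rng):
        y = rng.integers(0, 2, 5)
        p = rng.uniform(0.05, 0.95, 5)
        assert float(dmt.weighted_cross_entropy(y, p, 1.6)) == pytest.approx(
            weighted_ce_loops(y, p, 1.6, 1e-6), rel=1e-10
        )


class TestTotalLoss:
    def setup_method(self):
        self.rng = np.random.default_rng(8)
        self.X = self.rng.standard_normal((4, 3))
        self.y = np.array([0, 1, 1, 0])

    def test_alpha_zero_reduces_to_divergence(self):
        config = tiny_config(alpha1=0.0, alpha2=0.0)
        params = dmt.init_params(3, config, np.random.default_rng(0))
        total = float(dmt.total_loss(params, self.X, self.y, config))
        P = dmt.pairwise_similarities(self.X, config.nu_x, config.eps_clamp)
        V = dmt.forward_latent(params, self.X)
        Q = dmt.pairwise_similarities(V, config.nu_z, config.eps_clamp)
        assert total == pytest.approx(float(dmt.dmt_loss(P, Q)), rel=1e-12)

    def test_zero_weights_zero_l2(self):
        config = tiny_config()
        params = dmt.init_params(3, config, np.random.default_rng(0))
        zeroed = {
            part: [(np.zeros_like(W), b) for W, b in params[part]] for part in ("fe", "head")
        }
        assert float(dmt.l2_penalty(zeroed)) == 0.0

    def test_componentwise_oracle_on_toy_batch(self):
        config = tiny_config(layer_widths=(5,), latent_dim=2)
        params = dmt.init_params(3, config, np.random.default_rng(3))
        # independent recomputation: loop-based similarities and losses
        P = similarities_loops(self.X, config.nu_x, config.eps_clamp)
        V = np.asarray(dmt.forward_latent(params, self.X))
        Q = similarities_loops(V, config.nu_z, config.eps_clamp)
        probs = np.asarray(dmt.forward_probs(params, self.X))
        expected = (
            two_way_divergence_loops(P, Q)
            + config.alpha1 * weighted_ce_loops(self.y, probs[:, 1], config.beta, config.eps_clamp)
            + config.alpha2 * sum(float(np.sum(W**2)) for part in ("fe", "head") for W, _ in params[part])
        )
        total = float(dmt.total_loss(params, self.X, self.y, config))
        assert total == pytest.approx(expected, rel=1e-10)
        components = dmt.loss_components(params, self.X, self.y, config)
        assert components["total"] == pytest.approx(expected, rel=1e-10)

    def test_gradient_matches_finite_differences(self):
        config = tiny_config(layer_widths=(6, 4), latent_dim=3)
        X = self.rng.standard_normal((6, 5))
        y = np.array([0, 1, 0, 1, 1, 0])
        for point_seed in range(2):
            params = dmt.init_params(5, config, np.random.default_rng(point_seed))
            flat, unflatten = flatten(params)
            flat = flat * 0.3

            def f(fp):
                return dmt.total_loss(unflatten(fp), X, y, config)

            g = grad(f)(flat)
            h = 1e-5
            fd = np.empty_like(flat)
            for i in range(len(flat)):
                e = np.zeros_like(flat)
                e[i] = h
                fd[i] = (f(flat + e) - f(flat - e)) / (2 * h)
            assert np.linalg.norm(g - fd) / np.linalg.norm(fd) < 1e-4


@pytest.fixture(scope="module")
def separable_panel():
    """Normalized 5-protein panel with a strong planted effect."""
    config = CohortConfig(
        n_per_histotype={"MNG": 50, "FA": 30, "FTC": 30, "PTC": 50},
        n_proteins=30,
        n_informative=5,
        effect_size=3.0,
        missing_fraction_target=0.3,
        seed=77,
    )
    cohort = generate_cohort(config)
    train_set, test_set = split_cohort(cohort, (0.75, 0.25), seed=5)
    model = fit_normalizer(filter_by_missing_rate(train_set.matrix, 0.9))
    panel = sorted(cohort.truth_informative)
    Xtr = apply_normalizer(model, train_set.matrix).subset_proteins(panel).values
    Xte = apply_normalizer(model, test_set.matrix).subset_proteins(panel).values
    ytr = dmt.labels_to_y(train_set.labels.to_numpy())
    yte = dmt.labels_to_y(test_set.labels.to_numpy())
    return Xtr, ytr, Xte, yte


class TestTraining:
    def test_separable_panel_high_validation_auc(self, separable_panel):
        Xtr, ytr, _, _ = separable_panel
        clf = dmt.train(Xtr, ytr, tiny_config())
        assert max(clf.fold_aucs) >= 0.95
        assert clf.fold_aucs[clf.best_fold] == max(clf.fold_aucs)

    def test_permuted_labels_null_auc(self, separable_panel):
        Xtr, ytr, Xte, yte = separable_panel
        rng = np.random.default_rng(4)
        y_perm = rng.permutation(ytr)
        if len(set(y_perm)) < 2:  # pragma: no cover
            pytest.skip("degenerate permutation")
        clf = dmt.train(Xtr, y_perm, tiny_config())
        pred = dmt.predict(clf, Xte)
        truth = np.where(yte == 0, "malignant", "benign")
        assert 0.35 <= roc_auc(pred.y_malignant, truth) <= 0.65

    def test_bitwise_reproducibility(self, separable_panel):
        Xtr, ytr, _, _ = separable_panel
        config = tiny_config(epochs=5)
        a = dmt.train(Xtr, ytr, config)
        b = dmt.train(Xtr, ytr, config)
        fa, _ = flatten(a.params)
        fb, _ = flatten(b.params)
        np.testing.assert_array_equal(fa, fb)
        assert a.fold_aucs == b.fold_aucs

    def test_auc_monotone_in_effect_size(self):
        aucs = []
        for effect in (0.5, 1.0, 2.0, 3.0):
            repeat_aucs = []
            for seed in range(3):
                config = CohortConfig(
                    n_per_histotype={"MNG": 40, "FA": 20, "FTC": 20, "PTC": 40},
                    n_proteins=12,
                    n_informative=4,
                    effect_size=effect,
                    missing_fraction_target=0.2,
                    seed=100 + seed,
                )
                cohort = generate_cohort(config)
                tr, te = split_cohort(cohort, (0.75, 0.25), seed=seed)
                model = fit_normalizer(filter_by_missing_rate(tr.matrix, 0.95))
                panel = sorted(set(cohort.truth_informative) & set(model.feature_ids))
                Xtr = apply_normalizer(model, tr.matrix).subset_proteins(panel).values
                Xte = apply_normalizer(model, te.matrix).subset_proteins(panel).values
                clf = dmt.train(
                    Xtr,
                    dmt.labels_to_y(tr.labels.to_numpy()),
                    tiny_config(epochs=15, n_folds=2, seed=seed),
                )
                truth = np.where(dmt.labels_to_y(te.labels.to_numpy()) == 0, "malignant", "benign")
                repeat_aucs.append(roc_auc(dmt.predict(clf, Xte).y_malignant, truth))
            aucs.append(np.mean(repeat_aucs))
        assert all(a <= b + 0.02 for a, b in zip(aucs, aucs[1:])), aucs
        assert aucs[-1] > aucs[0]

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergent_training_aborts(self, separable_panel):
        Xtr, ytr, _, _ = separable_panel
        config = tiny_config(learning_rate=1e200, clip_norm=np.inf, epochs=2)
        with pytest.raises(FloatingPointError):
            dmt.train(Xtr * 100, ytr, config)

    def test_requires_complete_input(self):
        X = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValueError, match="complete"):
            dmt.train(X, np.array([0, 1]), tiny_config())


@pytest.fixture(scope="module")
def trained(separable_panel):
    Xtr, ytr, _, _ = separable_panel
    return dmt.train(Xtr, ytr, tiny_config(epochs=10))


class TestPredictEmbed:

    def test_probabilities_sum_to_one(self, trained, separable_panel):
        _, _, Xte, _ = separable_panel
        pred = dmt.predict(trained, Xte)
        np.testing.assert_allclose(pred.y_malignant + pred.y_benign, 1.0, atol=1e-12)

    def test_label_rule(self, trained, separable_panel):
        _, _, Xte, _ = separable_panel
        pred = dmt.predict(trained, Xte)
        np.testing.assert_array_equal(pred.label, (pred.y_malignant < pred.y_benign).astype(int))
        assert set(pred.label) <= {0, 1}

    def test_score_is_benign_probability(self, trained, separable_panel):
        _, _, Xte, _ = separable_panel
        pred = dmt.predict(trained, Xte)
        np.testing.assert_array_equal(pred.score, pred.y_benign)
        # score > 0.5 exactly when the call is benign
        np.testing.assert_array_equal(pred.score > 0.5, pred.label == 1)

    def test_tie_goes_to_malignant(self):
        # y0 = y1 = 0.5 must yield label 0
        y0 = np.array([0.5, 0.6, 0.1])
        label = np.where(y0 < 1 - y0, 1, 0)
        assert list(label) == [0, 0, 1]

    def test_embedding_deterministic_and_sized(self, trained, separable_panel):
        _, _, Xte, _ = separable_panel
        v1 = dmt.embed(trained, Xte)
        v2 = dmt.embed(trained, Xte)
        np.testing.assert_array_equal(v1, v2)
        assert v1.shape == (Xte.shape[0], trained.config.latent_dim)

    def test_latent_class_contrast(self, trained, separable_panel):
        _, _, Xte, yte = separable_panel
        V = dmt.embed(trained, Xte)
        d = np.linalg.norm(V[:, None, :] - V[None, :, :], axis=-1)
        same = yte[:, None] == yte[None, :]
        off_diag = ~np.eye(len(yte), dtype=bool)
        intra = d[same & off_diag].mean()
        inter = d[~same].mean()
        assert inter > intra

    def test_feature_count_mismatch(self, trained):
        with pytest.raises(ValueError, match="features"):
            dmt.predict(trained, np.zeros((2, 99)))

    def test_serialization_round_trip(self, trained, separable_panel, tmp_path):
        _, _, Xte, _ = separable_panel
        path = tmp_path / "clf.json"
        trained.save_json(path)
        back = dmt.TrainedClassifier.load_json(path)
        p1 = dmt.predict(trained, Xte)
        p2 = dmt.predict(back, Xte)
        np.testing.assert_allclose(p1.score, p2.score, atol=1e-15)
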