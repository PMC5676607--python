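"""Core classifier: forward pass, objective, gradients, evidence updates."""

import warnings

import numpy as np
import pytest
from scipy.stats import spearmanr

from silymap.ard import (
    MLPARDModel,
    TrainConfig,
    WeightGroups,
    cross_entropy,
    fit,
    forward,
    gauss_newton_hessian,
    group_penalty,
    initialize_model,
    load_model,
    objective,
    objective_gradient,
    objective_hessian,
    reestimate_alphas,
    save_model,
    train_inner,
)
from silymap.features import PixelDataset


def random_model(n: int, h: int, rng: np.random.Generator, scale: float = 0.8) -> MLPARDModel:
    return MLPARDModel(
        u=rng.normal(scale=scale, size=(h, n)),
        b1=rng.normal(scale=scale, size=h),
        v=rng.normal(scale=scale, size=h),
        b2=float(rng.normal(scale=scale)),
    )


def random_dataset(n_samples: int, n_features: int, rng: np.random.Generator) -> PixelDataset:
    return PixelDataset(
        features=rng.normal(size=(n_samples, n_features)),
        labels=rng.integers(0, 2, size=n_samples),
        coords=np.stack([np.arange(n_samples)] * 2, axis=1),
    )


class TestForward:
    def test_zero_network_outputs_one_half(self):
        m = MLPARDModel(u=np.zeros((3, 2)), b1=np.zeros(3), v=np.zeros(3), b2=0.0)
        assert forward(m, np.zeros(2)) == 0.5

    def test_monotone_in_output_bias(self):
        rng = np.random.default_rng(0)
        m = random_model(2, 3, rng)
        x = rng.normal(size=2)
        ys = [forward(MLPARDModel(m.u, m.b1, m.v, b2), x) for b2 in (-50, 0.0, 50)]
        assert ys[0] < ys[1] < ys[2]
        assert ys[2] > 1 - 1e-12

    def test_matches_explicit_composition_oracle(self):
        rng = np.random.default_rng(1)
        m = random_model(4, 3, rng)
        X = rng.normal(size=(6, 4))
        hidden = np.tanh(X @ m.u.T + m.b1)
        expected = 1.0 / (1.0 + np.exp(-(hidden @ m.v + m.b2)))
        np.testing.assert_allclose(forward(m, X), expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self):
        m = random_model(4, 3, np.random.default_rng(2))
        with pytest.raises(ValueError):
            forward(m, np.zeros(5))


class TestObjective:
    def test_cross_entropy_single_uncertain_sample(self):
        m = MLPARDModel(u=np.zeros((2, 2)), b1=np.zeros(2), v=np.zeros(2), b2=0.0)
        ds = PixelDataset(np.zeros((1, 2)), np.array([1]), np.zeros((1, 2), int))
        assert cross_entropy(m, ds) == pytest.approx(np.log(2), abs=1e-12)

    def test_cross_entropy_term_by_term_oracle(self):
        rng = np.random.default_rng(3)
        m = random_model(3, 4, rng)
        ds = random_dataset(20, 3, rng)
        y = forward(m, ds.features)
        expected = -sum(
            t * np.log(yi) + (1 - t) * np.log(1 - yi) for t, yi in zip(ds.labels, y)
        )
        assert cross_entropy(m, ds) == pytest.approx(expected, abs=1e-12)

    def test_saturated_perfect_fit_is_finite_and_small(self):
        m = MLPARDModel(u=np.full((1, 1), 50.0), b1=np.zeros(1), v=np.array([50.0]), b2=0.0)
        ds = PixelDataset(np.array([[5.0], [-5.0]]), np.array([1, 0]), np.zeros((2, 2), int))
        g = cross_entropy(m, ds)
        assert 0 <= g < 1e-9

    def test_group_penalty_half_sum_of_squares(self):
        m = MLPARDModel(u=np.array([[3.0], [4.0]]), b1=np.zeros(2), v=np.zeros(2), b2=0.0)
        groups = WeightGroups.for_network(1, 2)
        assert group_penalty(m, groups, 0) == pytest.approx(12.5)
        for k in range(1, len(groups)):
            assert group_penalty(m, groups, k) == 0.0
        with pytest.raises(IndexError):
            group_penalty(m, groups, len(groups))

    def test_objective_decomposition_exact(self):
        rng = np.random.default_rng(4)
        m = random_model(4, 3, rng)
        groups = WeightGroups.for_network(4, 3)
        alphas = rng.uniform(0.1, 5.0, size=len(groups))
        ds = random_dataset(15, 4, rng)
        f = objective(m, groups, alphas, ds)
        g = cross_entropy(m, ds)
        penalty = sum(a * group_penalty(m, groups, k) for k, a in enumerate(alphas))
        assert f - g == pytest.approx(penalty, abs=1e-12)
        assert f >= g

    def test_zero_alphas_only_in_testing_mode(self):
        rng = np.random.default_rng(5)
        m = random_model(2, 2, rng)
        groups = WeightGroups.for_network(2, 2)
        ds = random_dataset(5, 2, rng)
        zeros = np.zeros(len(groups))
        with pytest.raises(ValueError):
            objective(m, groups, zeros, ds)
        f = objective(m, groups, zeros, ds, allow_zero_alphas=True)
        assert f == pytest.approx(cross_entropy(m, ds), abs=1e-12)


class TestWeightGroups:
    @pytest.mark.parametrize("n,h", [(4, 8), (3, 5), (1, 2), (6, 3)])
    def test_partition_covers_every_parameter_once(self, n, h):
        groups = WeightGroups.for_network(n, h)
        assert len(groups) == n + 3
        all_idx = np.concatenate(groups.indices)
        assert len(all_idx) == h * n + 2 * h + 1
        assert len(np.unique(all_idx)) == len(all_idx)
        assert set(all_idx) == set(range(h * n + 2 * h + 1))

    def test_feature_group_selects_that_feature_column(self):
        groups = WeightGroups.for_network(3, 4)
        m = MLPARDModel(u=np.arange(12, dtype=float).reshape(4, 3), b1=np.zeros(4), v=np.zeros(4), b2=0.0)
        w = m.to_vector()
        np.testing.assert_array_equal(w[groups.indices[1]], m.u[:, 1])


class TestGradient:
    def _finite_difference(self, m, groups, alphas, ds, h=1e-6):
        w0 = m.to_vector()
        grad = np.empty_like(w0)
        for i in range(len(w0)):
            wp, wm = w0.copy(), w0.copy()
            wp[i] += h
            wm[i] -= h
            fp = objective(MLPARDModel.from_vector(wp, m.n, m.hidden_count), groups, alphas, ds)
            fm = objective(MLPARDModel.from_vector(wm, m.n, m.hidden_count), groups, alphas, ds)
            grad[i] = (fp - fm) / (2 * h)
        return grad

    @pytest.mark.parametrize("instance", range(20))
    def test_analytic_gradient_matches_central_differences(self, instance):
        rng = np.random.default_rng(100 + instance)
        m = random_model(4, 2, rng)
        groups = WeightGroups.for_network(4, 2)
        alphas = rng.uniform(0.05, 2.0, size=len(groups))
        ds = random_dataset(10, 4, rng)
        analytic = objective_gradient(m, groups, alphas, ds)
        numeric = self._finite_difference(m, groups, alphas, ds)
        rel = np.abs(analytic - numeric) / np.maximum(np.abs(numeric), 1e-6)
        assert rel.max() <= 1e-6

    def test_penalty_component_linear_in_alpha(self):
        rng = np.random.default_rng(6)
        m = random_model(3, 3, rng)
        groups = WeightGroups.for_network(3, 3)
        alphas = rng.uniform(0.1, 1.0, size=len(groups))
        ds = random_dataset(12, 3, rng)
        g1 = objective_gradient(m, groups, alphas, ds)
        g2 = objective_gradient(m, groups, 2 * alphas, ds)
        pen1 = g1 - objective_gradient(m, groups, 1e-300 * np.ones(len(groups)), ds)
        pen2 = g2 - objective_gradient(m, groups, 1e-300 * np.ones(len(groups)), ds)
        np.testing.assert_allclose(pen2, 2 * pen1, atol=1e-10)

    def test_output_bias_gradient_zero_under_label_flip_symmetry(self):
        m = MLPARDModel(u=np.zeros((2, 2)), b1=np.zeros(2), v=np.zeros(2), b2=0.0)
        groups = WeightGroups.for_network(2, 2)
        X = np.array([[1.0, 2.0], [-1.0, -2.0]])
        ds = PixelDataset(X, np.array([1, 0]), np.zeros((2, 2), int))
        grad = objective_gradient(m, groups, np.full(len(groups), 1e-300), ds)
        assert grad[-1] == pytest.approx(0.0, abs=1e-14)


class TestHessian:
    def test_exact_hessian_matches_gradient_differences(self):
        rng = np.random.default_rng(7)
        m = random_model(3, 2, rng)
        groups = WeightGroups.for_network(3, 2)
        alphas = rng.uniform(0.1, 1.0, size=len(groups))
        ds = random_dataset(8, 3, rng)
        H = objective_hessian(m, groups, alphas, ds)
        w0 = m.to_vector()
        step = 1e-6
        for i in range(len(w0)):
            wp, wm = w0.copy(), w0.copy()
            wp[i] += step
            wm[i] -= step
            gp = objective_gradient(MLPARDModel.from_vector(wp, 3, 2), groups, alphas, ds)
            gm = objective_gradient(MLPARDModel.from_vector(wm, 3, 2), groups, alphas, ds)
            np.testing.assert_allclose(H[i], (gp - gm) / (2 * step), atol=1e-6, rtol=1e-5)

    def test_gauss_newton_is_symmetric_positive_definite(self):
        rng = np.random.default_rng(8)
        m = random_model(4, 3, rng)
        groups = WeightGroups.for_network(4, 3)
        alphas = rng.uniform(0.1, 1.0, size=len(groups))
        ds = random_dataset(30, 4, rng)
        A = gauss_newton_hessian(m, groups, alphas, ds)
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        assert np.linalg.eigvalsh(A).min() > 0


class TestTraining:
    def _separable_dataset(self, rng):
        X = np.vstack([rng.normal(loc=2.0, size=(30, 2)), rng.normal(loc=-2.0, size=(30, 2))])
        t = np.concatenate([np.ones(30, int), np.zeros(30, int)])
        return PixelDataset(X, t, np.zeros((60, 2), int))

    def test_inner_loop_fits_separable_toy_problem(self):
        rng = np.random.default_rng(9)
        ds = self._separable_dataset(rng)
        config = TrainConfig(hidden_count=3, seed=9)
        groups = WeightGroups.for_network(2, 3)
        model = initialize_model(2, config)
        alphas = np.full(len(groups), 0.01)
        model, trace = train_inner(model, groups, alphas, ds, config)
        pred = (np.asarray(forward(model, ds.features)) >= 0.5).astype(int)
        assert np.array_equal(pred, ds.labels)
        assert trace[-1] <= trace[0]
        diffs = np.diff(trace)
        assert np.all(diffs <= 1e-8)

    def test_restart_at_minimum_leaves_objective_unchanged(self):
        rng = np.random.default_rng(10)
        ds = self._separable_dataset(rng)
        config = TrainConfig(hidden_count=3, inner_iters=500, seed=10)
        groups = WeightGroups.for_network(2, 3)
        alphas = np.full(len(groups), 0.5)
        model, _ = train_inner(initialize_model(2, config), groups, alphas, ds, config)
        f1 = objective(model, groups, alphas, ds)
        model2, _ = train_inner(model, groups, alphas, ds, config)
        f2 = objective(model2, groups, alphas, ds)
        assert f2 <= f1
        assert f1 - f2 < 1e-6

    def test_fit_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(11)
        ds = self._separable_dataset(rng)
        config = TrainConfig(hidden_count=3, outer_cycles=3, seed=11)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            a = fit(ds, config)
            b = fit(ds, config)
        np.testing.assert_array_equal(a.model.to_vector(), b.model.to_vector())
        np.testing.assert_array_equal(a.hyperparameters.alphas, b.hyperparameters.alphas)

    def test_single_class_training_set_rejected(self):
        ds = PixelDataset(np.zeros((5, 2)), np.ones(5, int), np.zeros((5, 2), int))
        with pytest.raises(ValueError):
            fit(ds, TrainConfig(outer_cycles=1))


class TestEvidenceUpdate:
    def test_production_trace_matches_dense_inverse_oracle(self):
        """Cholesky-solve trace path vs an explicit dense matrix inverse, 4-3-1 net."""
        rng = np.random.default_rng(12)
        ds = random_dataset(40, 4, rng)
        config = TrainConfig(hidden_count=3, inner_iters=500, seed=12)
        groups = WeightGroups.for_network(4, 3)
        alphas = np.full(len(groups), 0.3)
        model, _ = train_inner(initialize_model(4, config), groups, alphas, ds, config)
        hp = reestimate_alphas(model, groups, alphas, ds, hessian="gauss-newton")
        # independent oracle: same update from the dense explicit inverse
        A = gauss_newton_hessian(model, groups, alphas, ds)
        diag_inv = np.diag(np.linalg.inv(A))
        for k, idx in enumerate(groups.indices):
            gamma = len(idx) - alphas[k] * diag_inv[idx].sum()
            gamma = min(max(gamma, 0.0), len(idx))
            assert hp.gammas[k] == pytest.approx(gamma, abs=1e-8)
            e_w = group_penalty(model, groups, k)
            expected_alpha = 1e6 if (gamma <= 0 or e_w <= 1e-300) else np.clip(gamma / (2 * e_w), 0.1, 1e6)
            assert hp.alphas[k] == pytest.approx(expected_alpha, rel=1e-8)

    def test_gamma_bounds_and_positive_alphas(self):
        rng = np.random.default_rng(13)
        ds = random_dataset(25, 3, rng)
        groups = WeightGroups.for_network(3, 3)
        model = random_model(3, 3, rng)
        alphas = np.full(len(groups), 0.2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            hp = reestimate_alphas(model, groups, alphas, ds)
        sizes = groups.sizes()
        assert np.all(hp.gammas >= 0)
        assert np.all(hp.gammas <= sizes)
        assert np.all(hp.alphas > 0)
        assert np.all(hp.alphas <= 1e6)

    def test_collapsed_group_clamps_to_alpha_max(self):
        rng = np.random.default_rng(14)
        ds = random_dataset(25, 2, rng)
        groups = WeightGroups.for_network(2, 2)
        # biases exactly zero -> their groups have E_w = 0
        model = MLPARDModel(u=rng.normal(size=(2, 2)), b1=np.zeros(2), v=rng.normal(size=2), b2=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            hp = reestimate_alphas(model, groups, np.full(len(groups), 0.2), ds)
        assert hp.alphas[2] == 1e6  # hidden-bias group
        assert hp.alphas[4] == 1e6  # output-bias group


class TestTrainedModel:
    def test_alpha_norm_relation_is_inverse(self, default_run):
        """Relevant groups end with large norms and small alphas (negative rank correlation)."""
        result = default_run.fit_result
        alphas = result.hyperparameters.alphas
        norms = [
            np.sqrt(2 * group_penalty(result.model, result.groups, k)) for k in range(len(result.groups))
        ]
        rho = spearmanr(alphas, norms).statistic
        assert rho < 0

    def test_noise_features_shrink_more_than_informative(self, default_run):
        """Soft feature selection: green/red group norms collapse below nir/texture."""
        result = default_run.fit_result
        e_w = [group_penalty(result.model, result.groups, k) for k in range(4)]
        green, red, nir, texture = e_w
        assert max(green, red) < min(nir, texture)

    def test_group_norms_invariant_to_hidden_unit_permutation(self, default_run):
        result = default_run.fit_result
        m = result.model
        perm = np.random.default_rng(0).permutation(m.hidden_count)
        pm = MLPARDModel(u=m.u[perm], b1=m.b1[perm], v=m.v[perm], b2=m.b2)
        for k in range(m.n):
            assert group_penalty(pm, result.groups, k) == pytest.approx(
                group_penalty(m, result.groups, k), rel=1e-12
            )


class TestSerialization:
    def test_round_trip_is_bit_identical(self, tmp_path, default_run):
        result = default_run.fit_result
        path = tmp_path / "model.json"
        save_model(path, result.model, result.hyperparameters, default_run.standardization)
        model, hp, std, _ = load_model(path)
        np.testing.assert_array_equal(model.to_vector(), result.model.to_vector())
        np.testing.assert_array_equal(hp.alphas, result.hyperparameters.alphas)
        np.testing.assert_array_equal(std.location, default_run.standardization.location)
        x = np.linspace(-1, 1, 4)
        assert forward(model, x) == forward(result.model, x)
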