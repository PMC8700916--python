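import numpy as np
import pytest

from omicsmkl import (
    OmicsMKL,
    generate_multiomics,
    solve_svm_fixed_weights,
    train_simplemkl,
)

from conftest import small_two_block_config
from oracles import svm_dual_qp


def _random_kernel(rng, n):
    X = rng.normal(size=(n, 5))
    d2 = ((X[:, None] - X[None]) ** 2).sum(-1)
    return np.exp(-d2 / (2 * np.median(d2)))


class TestSvmFixedWeights:
    def test_two_point_problem(self):
        # orthonormal kernel, one sample per class: both are support
        # vectors and the decision boundary sits midway
        K = np.eye(2)
        y = np.array([1, -1])
        sol = solve_svm_fixed_weights(K, y, C=10.0)
        assert np.count_nonzero(sol.signed_dual) == 2
        f = K @ sol.signed_dual + sol.bias
        assert f[0] > 0 > f[1]
        assert f[0] == pytest.approx(-f[1], abs=1e-8)

    def test_dual_equality_and_box_constraints(self):
        rng = np.random.default_rng(0)
        for C in (0.5, 1.0, 10.0):
            K = _random_kernel(rng, 30)
            y = np.where(rng.random(30) < 0.4, 1, -1)
            sol = solve_svm_fixed_weights(K, y, C=C)
            assert abs(sol.signed_dual.sum()) < 1e-6
            alpha = sol.signed_dual * y
            assert alpha.min() >= -1e-9
            assert alpha.max() <= C + 1e-9

    def test_matches_generic_qp_oracle_on_toy_kernel(self):
        rng = np.random.default_rng(1)
        K = _random_kernel(rng, 8)
        y = np.array([1, 1, 1, -1, -1, -1, 1, -1])
        # C=2 leaves interior support vectors, so the bias is unique
        sol = solve_svm_fixed_weights(K, y, C=2.0)
        a_qp, b_qp, obj_qp = svm_dual_qp(K, y, C=2.0)
        assert sol.objective == pytest.approx(obj_qp, abs=1e-5)
        f_ours = K @ sol.signed_dual + sol.bias
        f_qp = K @ a_qp + b_qp
        assert np.allclose(f_ours, f_qp, atol=1e-5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            solve_svm_fixed_weights(np.eye(3), np.ones(3))


class TestTrainSimpleMKL:
    def test_single_kernel_degenerates_to_plain_svm(self):
        rng = np.random.default_rng(2)
        K = _random_kernel(rng, 25)
        y = np.where(rng.random(25) < 0.4, 1, -1)
        fit = train_simplemkl([K], y, C=1.0)
        assert fit.kernel_weights.tolist() == [1.0]
        ref = solve_svm_fixed_weights(K, y, C=1.0)
        assert np.allclose(fit.signed_dual, ref.signed_dual, atol=1e-10)
        assert fit.bias == pytest.approx(ref.bias, abs=1e-10)

    def test_duplicate_kernels_leave_objective_flat(self):
        rng = np.random.default_rng(3)
        K = _random_kernel(rng, 20)
        y = np.where(rng.random(20) < 0.5, 1, -1)
        single = solve_svm_fixed_weights(K, y, C=1.0).objective
        for d0 in (0.0, 0.3, 1.0):
            obj = solve_svm_fixed_weights(d0 * K + (1 - d0) * K, y, C=1.0).objective
            assert obj == pytest.approx(single, abs=1e-8)
        fit = train_simplemkl([K, K.copy()], y, C=1.0)
        assert fit.objective == pytest.approx(single, abs=1e-6)
        assert fit.convergence.converged

    def test_simplex_held_at_every_iteration_and_objective_monotone(self):
        rng = np.random.default_rng(4)
        kernels = [_random_kernel(rng, 40) for _ in range(4)]
        y = np.where(rng.random(40) < 0.4, 1, -1)
        fit = train_simplemkl(kernels, y, C=1.0)
        for d in fit.convergence.weight_history:
            assert d.min() >= -1e-10
            assert abs(d.sum() - 1.0) < 1e-10
        J = fit.convergence.objective_history
        assert all(b <= a + 1e-12 for a, b in zip(J, J[1:]))

    def test_converged_runs_meet_gap_tolerance(self):
        rng = np.random.default_rng(5)
        kernels = [_random_kernel(rng, 35) for _ in range(3)]
        y = np.where(rng.random(35) < 0.5, 1, -1)
        fit = train_simplemkl(kernels, y, C=1.0, tol=1e-3)
        assert fit.convergence.converged
        assert fit.convergence.final_gap <= 1e-3

    def test_no_kernels_rejected(self):
        with pytest.raises(ValueError):
            train_simplemkl([], np.array([1, -1]))

    def test_signal_kernel_dominates_noise_kernel(self):
        """Two Gaussian kernels, one over an informative block and one over
        pure noise: the weight must concentrate on the signal kernel."""
        from omicsmkl.kernels import FittedKernel, KernelSpec

        signal_wins = sparse_noise = 0
        n_runs = 20
        for seed in range(n_runs):
            ds, _ = generate_multiomics(small_two_block_config(seed=seed))
            Xs = ds.block("signal").values
            Xn = ds.block("noise").values
            ks = FittedKernel(Xs, KernelSpec("signal", "gaussian")).gram()
            kn = FittedKernel(Xn, KernelSpec("noise", "gaussian")).gram()
            fit = train_simplemkl([ks, kn], ds.labels, C=1.0)
            signal_wins += fit.kernel_weights[0] > 0.5
            sparse_noise += fit.kernel_weights[1] < 0.2
        assert signal_wins >= 18
        assert sparse_noise >= 0.8 * n_runs


class TestOmicsMKLModel:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted():
        ds, _ = generate_multiomics(small_two_block_config(seed=7))
        return ds, OmicsMKL(ds, n_features=20, cap=30).fit()

    def test_training_samples_reproduce_training_decision_values(self, fitted):
        ds, res = fitted
        train_gram = np.zeros((ds.n_samples, ds.n_samples))
        for w, fk in zip(res.kernel_weights_, res._kernels):
            train_gram += w * fk.gram().values
        direct = train_gram @ res.dual_coef_ + res.intercept_
        assert np.allclose(res.decision_function(ds), direct, atol=1e-10)

    def test_predict_is_sign_of_decision_with_positive_ties(self, fitted):
        ds, res = fitted
        scores = res.decision_function(ds)
        assert np.array_equal(res.predict(ds), np.where(scores >= 0, 1, -1))
        assert set(res.predict(ds)) <= {-1, 1}

    def test_missing_feature_is_named(self, fitted):
        ds, res = fitted
        broken = ds.take(np.arange(ds.n_samples))
        used = res.selected_features_[0].ref
        block = broken.block(used.block_name)
        block.feature_ids[used.column_index] = "renamed_away"
        with pytest.raises(KeyError, match=used.feature_id):
            res.decision_function(broken)

    def test_kernel_weights_on_simplex(self, fitted):
        _, res = fitted
        assert res.kernel_weights_.min() >= 0
        assert res.kernel_weights_.sum() == pytest.approx(1.0, abs=1e-10)

    def test_summary_reports_weights_and_convergence(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "kernel" in text and "weight" in text
        assert f"{len(res.selected_features_)}" in text

    def test_m1_model_matches_reference_single_kernel_svm(self):
        """A one-block gaussian-only model must reproduce an independently
        computed single-kernel SVM decision function."""
        from sklearn.svm import SVC

        from omicsmkl.kernels import FittedKernel, KernelSpec

        ds, _ = generate_multiomics(small_two_block_config(seed=9))
        one = ds.select_blocks(["signal"])
        res = OmicsMKL(one, n_features=10, cap=10,
                       kernel_families=("gaussian",)).fit()
        # reference: plain SVC on the same standardized selected features
        mu, sd, cols = res._scalers["signal"]
        X = (one.block("signal").values[:, cols] - mu) / sd
        fk = FittedKernel(X, KernelSpec("signal", "gaussian"))
        svc = SVC(kernel="precomputed", C=1.0, tol=1e-8).fit(fk.gram().values, one.labels)
        ref = svc.decision_function(fk.gram().values)
        assert np.allclose(res.decision_function(one), ref, atol=1e-6)


def test_blocks_without_selected_features_are_omitted(caplog):
    ds, _ = generate_multiomics(small_two_block_config(seed=13))
    with caplog.at_level("WARNING"):
        res = OmicsMKL(ds, n_features=4, cap=4).fit()
    blocks_used = {s.block_name for s in res.kernel_specs_}
    assert blocks_used == {"signal"}
    assert any("omitted" in r.message for r in caplog.records)
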