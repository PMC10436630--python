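import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hipca import HiPCA, chi2_upper, fit_pca, tune_thresholds
from hipca.monitor import HiPCAResults
from hipca.preprocess import TransformParams


def make_results(P, eigvals, eigvals_res, confidence=None):
    """Hand-built model on an already-normalized feature axis."""
    P = np.asarray(P, dtype=float)
    D = P.shape[0]
    features = [f"f{i}" for i in range(D)]
    res = HiPCAResults(
        P=P,
        eigvals=np.asarray(eigvals, dtype=float),
        eigvals_res=np.asarray(eigvals_res, dtype=float),
        d=P.shape[1],
        features=features,
        transform=TransformParams(1e-5, np.zeros(D), np.ones(D), features),
        n_train=100,
    )
    if confidence is not None:
        res.compute_limits(confidence)
    return res


class TestFitPca:
    def test_equal_eigenvalues_need_both_components(self):
        # two orthogonal features with equal variance: one PC explains 0.5
        X = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        _, _, d = fit_pca(X, pve=0.9)
        assert d == 2

    def test_rank_one_data(self, rng):
        t = rng.normal(size=60)
        v = np.array([1.0, 2.0, -1.0, 0.5, 3.0])
        X = np.outer(t, v)
        eigvals, _, d = fit_pca(X, pve=0.9)
        assert d == 1
        assert np.sum(eigvals[1:]) == 0.0  # theta1 of the residual spectrum

    def test_projector_identity(self, rng):
        X = rng.normal(size=(200, 10))
        X -= X.mean(axis=0)
        eigvals, eigvecs, d = fit_pca(X, pve=0.8)
        res = make_results(eigvecs[:, :d], eigvals[:d], eigvals[d:])
        np.testing.assert_allclose(res.C + res.C_tilde, np.eye(10), atol=1e-10)

    def test_invalid_pve(self, rng):
        with pytest.raises(ValueError, match="pve"):
            fit_pca(rng.normal(size=(10, 3)), pve=1.5)


class TestIndices:
    def test_t2_closed_form(self):
        res = make_results(np.eye(2), [4.0, 1.0], [])
        assert res.t2([[0.0, 0.0]])[0] == 0.0
        assert res.t2([[2.0, 1.0]])[0] == pytest.approx(2.0)  # 4/4 + 1/1

    def test_t2_chi2_moment(self, rng):
        """Mean T2 over draws from the model covariance equals d."""
        X = rng.normal(size=(500, 10)) @ rng.normal(size=(10, 10))
        X -= X.mean(axis=0)
        eigvals, eigvecs, d = fit_pca(X, pve=0.9)
        res = make_results(eigvecs[:, :d], eigvals[:d], eigvals[d:])
        # sample exactly from N(0, S_model)
        L = eigvecs * np.sqrt(np.maximum(eigvals, 0.0))
        draws = rng.standard_normal((100_000, 10)) @ L.T
        assert res.t2(draws).mean() == pytest.approx(d, rel=0.02)

    def test_q_zero_in_pc_span_and_residual_norm(self):
        res = make_results(np.array([[1.0], [0.0]]), [5.0], [1.0])
        assert res.q([[3.0, 0.0]])[0] == pytest.approx(0.0, abs=1e-12)
        assert res.q([[3.0, 4.0]])[0] == pytest.approx(16.0)

    def test_q_trace_identity(self, rng):
        """Mean Q over draws from the model covariance equals theta1."""
        X = rng.normal(size=(500, 8)) @ rng.normal(size=(8, 8))
        X -= X.mean(axis=0)
        eigvals, eigvecs, d = fit_pca(X, pve=0.7)
        res = make_results(eigvecs[:, :d], eigvals[:d], eigvals[d:])
        L = eigvecs * np.sqrt(np.maximum(eigvals, 0.0))
        draws = rng.standard_normal((100_000, 8)) @ L.T
        assert res.q(draws).mean() == pytest.approx(res.theta1, rel=0.02)

    def test_q_requires_residual_subspace(self):
        res = make_results(np.eye(2), [2.0, 1.0], [])
        with pytest.raises(ValueError, match="residual"):
            res.q([[1.0, 1.0]])

    def test_phi_decomposition_homogeneity_and_balance(self, rng):
        res = make_results(np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 0.0]]),
                           [4.0, 2.0], [0.5], confidence=0.9)
        x = rng.normal(size=(20, 3))
        np.testing.assert_allclose(
            res.phi(x), res.t2(x) / res.tau2 + res.q(x) / res.delta2, atol=1e-12
        )
        np.testing.assert_allclose(res.phi(2 * x) / res.phi(x), 4.0, atol=1e-10)
        # x with T2 = tau2 (PC subspace) plus Q = delta2 (residual) gives phi = 2
        x_pc = np.array([np.sqrt(res.tau2 * 4.0), 0.0, 0.0])
        x_res = np.array([0.0, 0.0, np.sqrt(res.delta2)])
        assert res.phi([x_pc + x_res])[0] == pytest.approx(2.0, rel=1e-10)

    def test_sign_flip_invariance(self, fitted, dense_cohort):
        import dataclasses

        table, _ = dense_cohort
        flipped = dataclasses.replace(fitted, P=fitted.P * -1.0)
        a = fitted.score(table.data)
        b = flipped.score(table.data)
        for col in ("T2", "Q", "phi"):
            np.testing.assert_allclose(a[col], b[col], atol=1e-10)


class TestControlLimits:
    def test_t2_limit_is_chi2_quantile(self):
        res = make_results(np.eye(3)[:, :2], [3.0, 1.0], [0.5], confidence=0.95)
        assert res.tau2 == pytest.approx(stats.chi2.ppf(0.95, 2))
        assert res.tau2 == pytest.approx(5.991, abs=5e-4)

    def test_q_limit_formula(self):
        res = make_results(np.eye(4)[:, :2], [3.0, 2.0], [1.0, 0.5], confidence=0.9)
        theta1, theta2 = 1.5, 1.25
        assert res.theta1 == pytest.approx(theta1)
        assert res.theta2 == pytest.approx(theta2)
        expected = (theta2 / theta1) * stats.chi2.ppf(0.9, theta1**2 / theta2)
        assert res.delta2 == pytest.approx(expected, rel=1e-12)

    def test_phi_limit_formula(self):
        res = make_results(np.eye(4)[:, :2], [3.0, 2.0], [1.0, 0.5], confidence=0.9)
        g_num = res.d / res.tau2**2 + res.theta2 / res.delta2**2
        g_den = res.d / res.tau2 + res.theta1 / res.delta2
        expected = (g_num / g_den) * stats.chi2.ppf(0.9, g_den**2 / g_num)
        assert res.zeta2 == pytest.approx(expected, rel=1e-12)

    def test_limit_monotone_in_confidence(self):
        dofs = 2
        limits = [chi2_upper(c, dofs) for c in (0.5, 0.9, 0.99)]
        assert limits == sorted(limits)
        assert chi2_upper(1e-9, dofs) == pytest.approx(0.0, abs=1e-6)

    def test_no_residual_subspace_restricts_to_t2(self):
        res = make_results(np.eye(2), [2.0, 1.0], [])
        res.compute_limits(0.9)
        assert res.tau2 > 0 and res.delta2 is None and res.zeta2 is None
        with pytest.raises(ValueError, match="residual"):
            res.phi([[1.0, 1.0]])


class TestPredict:
    def test_flags_match_limits(self, fitted, dense_cohort):
        table, _ = dense_cohort
        scores = fitted.score(table.data, rule="combined")
        np.testing.assert_array_equal(scores["flag_T2"], scores["T2"] > fitted.tau2)
        np.testing.assert_array_equal(scores["flag_Q"], scores["Q"] > fitted.delta2)
        np.testing.assert_array_equal(scores["flag_phi"], scores["phi"] > fitted.zeta2)
        np.testing.assert_array_equal(
            scores["decision"] == "unhealthy", scores["flag_phi"]
        )

    def test_rule_semantics(self, fitted, dense_cohort):
        table, _ = dense_cohort
        combined = fitted.score(table.data, rule="combined")
        majority = fitted.score(table.data, rule="majority")
        any_rule = fitted.score(table.data, rule="any")
        n_flags = (
            combined[["flag_T2", "flag_Q", "flag_phi"]].astype(int).sum(axis=1)
        )
        np.testing.assert_array_equal(
            majority["decision"] == "unhealthy", n_flags >= 2
        )
        np.testing.assert_array_equal(
            any_rule["decision"] == "unhealthy", n_flags >= 1
        )

    def test_unknown_rule(self, fitted, dense_cohort):
        table, _ = dense_cohort
        with pytest.raises(ValueError, match="rule"):
            fitted.score(table.data, rule="unanimous")

    def test_frozen_parameters_bit_identical(self, fitted, dense_cohort):
        table, _ = dense_cohort
        a = fitted.score(table.data)
        b = fitted.score(table.data)
        pd.testing.assert_frame_equal(a, b)


class TestTuneThresholds:
    def test_single_cell_grid(self, dense_cohort):
        table, _ = dense_cohort
        model = HiPCA.from_abundance(table)
        best = tune_thresholds(
            model, table.data, table.metadata["label"], [0.8], [0.9]
        )
        assert (best.pve, best.confidence) == (0.8, 0.9)
        assert len(best.grid) == 1

    def test_pi_half_is_balanced_accuracy(self, dense_cohort):
        table, _ = dense_cohort
        model = HiPCA.from_abundance(table)
        best = tune_thresholds(
            model, table.data, table.metadata["label"], [0.9], [0.9], w=0.5
        )
        row = best.grid.iloc[0]
        assert row["pi"] == pytest.approx(row["balanced_accuracy"])

    def test_argmax_over_exhaustive_grid(self, dense_cohort):
        from hipca.evaluate import evaluate_predictions

        table, _ = dense_cohort
        model = HiPCA.from_abundance(table)
        best = tune_thresholds(
            model, table.data, table.metadata["label"], [0.7, 0.9], [0.9, 0.95]
        )
        # recompute PI independently for every cell
        for _, row in best.grid.iterrows():
            fitted = model.fit(pve=row["pve"], confidence=row["confidence"])
            scores = fitted.score(table.data)
            rep = evaluate_predictions(scores["decision"], table.metadata["label"])
            assert rep.pi(0.5) == pytest.approx(row["pi"])
            assert row["pi"] <= best.pi + 1e-12

    def test_single_class_rejected(self, dense_cohort):
        table, _ = dense_cohort
        model = HiPCA.from_abundance(table)
        healthy = table.subset("healthy")
        with pytest.raises(ValueError, match="both classes"):
            tune_thresholds(
                model, healthy.data, healthy.metadata["label"], [0.9], [0.9]
            )
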