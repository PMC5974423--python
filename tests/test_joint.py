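"""Joint confound + classifier estimation: objective reductions, block
updates against closed-form oracles, limit behaviour, pipeline variants."""

import numpy as np
import pytest

from joigam import (
    fit_gam,
    fit_joint,
    gamma_from_sigma,
    joint_objective,
    logistic_loss,
    make_fig1_cohort,
    residualize,
    run_pipeline,
)
from joigam.gam import noise_scaler, ols_phi
from joigam.joint import (
    _JointProblem,
    update_classifier_continuous,
    update_confound_map,
)


@pytest.fixture
def small_problem():
    rng = np.random.default_rng(42)
    n, nf = 40, 3
    age = rng.uniform(12, 21, n)
    ses = rng.uniform(10, 20, n)
    D = np.column_stack([np.ones(n), age, age ** 2, ses])
    z = np.array([-1] * 28 + [1] * 12).astype(float)
    I = rng.normal(size=(n, nf)) + 0.1 * age[:, None]
    I[z == 1, 0] += 1.5
    cmask = z == -1
    return I, D, z, cmask


class TestJointObjective:
    def test_gamma_zero_rho_zero_reduces_to_logistic_loss(self, small_problem):
        I, D, z, cmask = small_problem
        rng = np.random.default_rng(0)
        Phi = rng.normal(size=(3, 4))
        psi = rng.normal(size=3)
        obj = joint_objective(Phi, 0.3, psi, psi, 0.0, 0.0, I, D, z, cmask)
        R = I - D @ Phi.T
        assert obj == pytest.approx(logistic_loss(psi, 0.3, R, z))

    def test_gamma_near_one_approaches_gam_cost_plus_entropy(self):
        # two-subject toy evaluated symbolically: psi = 0 makes L = N*ln2
        I = np.array([[1.0], [2.0]])
        D = np.array([[1.0, 15, 225, 12], [1.0, 18, 324, 14]])
        z = np.array([-1.0, 1.0])
        cmask = z == -1
        Phi = np.zeros((1, 4))
        g = 1 - 1e-9
        obj = joint_objective(Phi, 0.0, np.zeros(1), np.zeros(1), g, 0.0, I, D, z, cmask)
        G = 1.0  # control subject's squared residual
        expected = (1 - g) * 2 * np.log(2) + g * G
        assert obj == pytest.approx(expected, rel=1e-12)

    def test_case_subjects_do_not_enter_gam_term(self, small_problem):
        I, D, z, cmask = small_problem
        Phi = np.zeros((3, 4))
        psi = np.zeros(3)
        base = joint_objective(Phi, 0.0, psi, psi, 0.5, 0.0, I, D, z, cmask)
        # append one case subject: L grows by ln 2, G unchanged
        I2 = np.vstack([I, np.ones(3)])
        D2 = np.vstack([D, [1.0, 19, 361, 15]])
        z2 = np.append(z, 1.0)
        cmask2 = np.append(cmask, False)
        grown = joint_objective(Phi, 0.0, psi, psi, 0.5, 0.0, I2, D2, z2, cmask2)
        assert grown - base == pytest.approx((1 - 0.5) * np.log(2))

    def test_invalid_gamma_rejected(self, small_problem):
        I, D, z, cmask = small_problem
        with pytest.raises(ValueError):
            joint_objective(np.zeros((3, 4)), 0, np.zeros(3), np.zeros(3), 1.0, 0.0,
                            I, D, z, cmask)


class TestUpdateConfoundMap:
    def test_zero_psi_returns_control_ols(self, small_problem):
        I, D, z, cmask = small_problem
        prob = _JointProblem(I, D, z, cmask)
        Phi0 = np.ones((3, 4))
        out = update_confound_map(prob, Phi0, 0.0, np.zeros(3), gamma=0.5)
        oracle = ols_phi(D[cmask], I[cmask])
        np.testing.assert_allclose(out, oracle, atol=1e-9)

    def test_gamma_to_one_returns_ols_regardless_of_psi(self, small_problem):
        I, D, z, cmask = small_problem
        prob = _JointProblem(I, D, z, cmask)
        psi = np.array([1.0, -2.0, 0.5])
        out = update_confound_map(prob, prob.ols_phi(), 0.2, psi, gamma=1 - 1e-9)
        oracle = ols_phi(D[cmask], I[cmask])
        np.testing.assert_allclose(out, oracle, atol=1e-6)

    def test_update_never_increases_objective(self, small_problem):
        I, D, z, cmask = small_problem
        prob = _JointProblem(I, D, z, cmask)
        rng = np.random.default_rng(3)
        for _ in range(5):
            Phi0 = rng.normal(size=(3, 4)) * 0.2
            psi = rng.normal(size=3)
            nu = float(rng.normal())
            gamma = float(rng.uniform(0.05, 0.9))
            before = joint_objective(Phi0, nu, psi, psi, gamma, 0.0, I, D, z, cmask)
            Phi1 = update_confound_map(prob, Phi0, nu, psi, gamma)
            after = joint_objective(Phi1, nu, psi, psi, gamma, 0.0, I, D, z, cmask)
            assert after <= before + 1e-9 * (1 + abs(before))


class TestUpdateClassifierContinuous:
    def test_large_rho_pins_psi_to_omega(self, small_problem):
        I, D, z, cmask = small_problem
        prob = _JointProblem(I, D, z, cmask)
        Phi = prob.ols_phi()
        omega = np.array([1.0, 0.0, -0.5])
        _, psi = update_classifier_continuous(
            prob, Phi, 0.0, np.zeros(3), omega, gamma=0.3, rho=1e9
        )
        np.testing.assert_allclose(psi, omega, atol=1e-4)

    def test_gamma_zero_rho_zero_is_unconstrained_logistic(self, small_problem):
        from sklearn.linear_model import LogisticRegression

        I, D, z, cmask = small_problem
        prob = _JointProblem(I, D, z, cmask)
        Phi = prob.ols_phi()
        nu, psi = update_classifier_continuous(
            prob, Phi, 0.0, np.zeros(3), np.zeros(3), gamma=0.0, rho=0.0
        )
        R = I - D @ Phi.T
        ref = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000, tol=1e-12)
        ref.fit(R, z)
        np.testing.assert_allclose(psi, ref.coef_[0], atol=1e-4)
        assert nu == pytest.approx(ref.intercept_[0], abs=1e-4)

    def test_strict_convexity_restart_agreement(self, small_problem):
        I, D, z, cmask = small_problem
        prob = _JointProblem(I, D, z, cmask)
        Phi = prob.ols_phi()
        omega = np.array([0.5, -1.0, 0.0])
        rng = np.random.default_rng(4)
        sols = []
        for _ in range(2):
            psi0 = rng.normal(size=3) * 3
            nu, psi = update_classifier_continuous(
                prob, Phi, float(rng.normal()), psi0, omega, gamma=0.3, rho=0.5
            )
            sols.append(np.append(psi, nu))
        np.testing.assert_allclose(sols[0], sols[1], atol=1e-5)


class TestFitJoint:
    def test_fig1_cohort_perfect_training_separation(self):
        table = make_fig1_cohort(seed=0)
        fitted = run_pipeline(table, "JOI", N_K=1, sigma=2.0)
        assert int((fitted.predict(table) != table.labels).sum()) == 0

    def test_fig1_raw_comparator_misclassifies(self):
        table = make_fig1_cohort(seed=0)
        fitted = run_pipeline(table, "NO_GAM", N_K=1)
        assert int((fitted.predict(table) != table.labels).sum()) >= 1

    def test_known_pattern_recovered_under_strong_effects(self):
        from joigam import GeneratorSpec, make_ncanda_like, recovery_report

        spec = GeneratorSpec(
            n_controls=200, n_cases=30, n_str=8, n_dti=12, pattern_size=3, delta=2.0
        )
        table, truth = make_ncanda_like(spec, seed=3)
        fitted = run_pipeline(table, "JOI", N_K=3, sigma=1.0)
        assert recovery_report(fitted.pattern, truth).jaccard == 1.0

    def test_joi_opt_equals_joi_with_gamma_zero(self, small_cohort):
        table, _ = small_cohort
        a = fit_joint(table, N_K=2, variant="JOI_OPT")
        b = fit_joint(table, N_K=2, sigma=1.0, gamma=0.0, variant="JOI")
        np.testing.assert_array_equal(a.omega, b.omega)
        np.testing.assert_array_equal(a.Phi, b.Phi)
        assert a.nu == b.nu

    def test_objective_trace_nonincreasing_within_rho(self, small_cohort):
        table, _ = small_cohort
        fit = fit_joint(table, N_K=2, sigma=1.0)
        trace = fit.objective_trace
        assert len(trace) >= 3
        for (r1, v1), (r2, v2) in zip(trace, trace[1:]):
            if r1 == r2:
                assert v2 <= v1 + 1e-7 * (1 + abs(v1))

    def test_gamma_limit_phi_matches_ols(self, small_cohort):
        table, _ = small_cohort
        fit = fit_joint(table, N_K=2, gamma=1 - 1e-9, variant="JOI", debias=False)
        scaler = noise_scaler(table.controls())
        D = table.design_matrix()
        cmask = table.controls_mask
        oracle = ols_phi(D[cmask], scaler.transform(table.metrics)[cmask])
        np.testing.assert_allclose(fit.Phi, oracle, atol=1e-6)

    def test_sparsity_and_convergence_invariants(self, small_cohort):
        table, _ = small_cohort
        fit = fit_joint(table, N_K=3, sigma=1.0)
        assert np.count_nonzero(fit.omega) <= 3
        assert np.max(np.abs(fit.omega - fit.psi)) < 1e-3
        assert fit.gamma == pytest.approx(gamma_from_sigma(1.0))

    def test_variant_validation(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError):
            fit_joint(table, N_K=2, variant="BOGUS")


class TestRunPipeline:
    def test_sequential_on_pure_confound_is_chance(self):
        from joigam import GeneratorSpec, make_ncanda_like
        from joigam.evaluation import confusion_metrics

        spec = GeneratorSpec(
            n_controls=120, n_cases=40, n_str=4, n_dti=4, pattern_size=2, delta=0.0
        )
        table, _ = make_ncanda_like(spec, seed=5)
        fitted = run_pipeline(table, "SEQ_OLS", N_K=2)
        _, _, nacc = confusion_metrics(fitted.predict(table), table.labels)
        assert nacc <= 60.0

    def test_modality_variants_restrict_patterns(self, small_cohort):
        table, _ = small_cohort
        fs = run_pipeline(table, "JOI_STR", N_K=2, sigma=1.0)
        fd = run_pipeline(table, "JOI_DTI", N_K=2, sigma=1.0)
        assert all(m.startswith("str_") for m in fs.pattern)
        assert all(m.startswith("dti_") for m in fd.pattern)
        # prediction on the full table works through internal modality selection
        assert fs.predict(table).shape == (table.n,)

    def test_seq_residuals_feed_classifier(self, small_cohort):
        table, truth = small_cohort
        fitted = run_pipeline(table, "SEQ_OLS", N_K=2)
        gam_direct = fit_gam(table.controls(), method="ols")
        np.testing.assert_allclose(fitted.gamfit.Phi, gam_direct.Phi, atol=1e-9)
        R = residualize(fitted.gamfit, table)
        scores = fitted.classifier.decision_scores(R.values)
        np.testing.assert_allclose(scores, fitted.decision_scores(table))

    def test_unknown_pipeline_rejected(self, small_cohort):
        table, _ = small_cohort
        with pytest.raises(ValueError):
            run_pipeline(table, "SVM", N_K=2)
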