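"""Likelihood, GLS profiling, optimizer, and parameter counting.

The key correctness anchor is the quadrature oracle: the closed-form
marginal deviance must match numerical integration of the hierarchical
model (conditional Gaussian times the random-effect prior) on a small
two-muscle instance.
"""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import approx_fprime

import emglmm as eg
from emglmm.covariance import AR1Params, RandomEffectsCov, n_cov_params
from emglmm.data import SeriesLayout
from emglmm.errors import SingularDesignError
from emglmm.estimation import _Evaluator, _default_start
from emglmm.simulate import default_truth


from oracles import quadrature_deviance


@pytest.fixture(scope="module")
def two_muscle_design(medium_spec, balanced_covariates):
    cfg = eg.SyntheticConfig(
        n_patients=2, max_elevation=30, design=medium_spec,
        covariates=balanced_covariates, seed=31,
    )
    tab = eg.simulate_study(cfg)
    sub = tab.frame[tab.frame["muscle"].isin(["PM", "UT"])].reset_index(drop=True)
    spec = eg.DesignSpec(main_effects=("intercept", "elevation"), affected_interactions=(),
                         affected_only=())
    des = eg.build_design(eg.ObservationTable(sub), spec)
    # absent muscles leave all-zero blocks; trim them so the design is full rank
    keep = np.flatnonzero(np.abs(des.X).sum(axis=0) > 0)
    return dataclasses.replace(
        des, X=des.X[:, keep], labels=[des.labels[j] for j in keep]
    )


class TestLikelihood:
    def test_marginal_deviance_matches_quadrature(self, two_muscle_design):
        ar1 = AR1Params(rho=[0.6, 0.7, 0.5, 0.5], sigma2=[0.4, 0.3, 1.0, 1.0])
        sd = np.array([0.5, 0.6, 0.4, 0.7])
        C = np.full((4, 4), 0.4) + 0.6 * np.eye(4)
        recov = RandomEffectsCov.full(C * np.outer(sd, sd))
        ev = _Evaluator(two_muscle_design)
        dev, beta, _, _ = ev.value(ar1, recov)
        dev_q = quadrature_deviance(two_muscle_design, beta, ar1, recov)
        assert np.isclose(dev, dev_q, rtol=1e-6)

    def test_single_point_series_deviance(self):
        """Four length-1 series per patient: deviance is the sum of scalar
        normal deviances log(2 pi sigma_k^2) + r^2/sigma_k^2 at the GLS mean."""
        import pandas as pd

        rows = []
        y = {"p1": [1.0, 2.0, 0.5, -0.3], "p2": [1.6, 1.0, 0.9, 0.7]}
        for pid in ("p1", "p2"):
            for k, m in enumerate(eg.MUSCLES):
                rows.append(
                    dict(patient_id=pid, muscle=m, side="affected", movement="up",
                         elevation_deg=10, log_emg=y[pid][k])
                )
        tab = eg.ObservationTable(pd.DataFrame(rows))
        spec = eg.DesignSpec(main_effects=("intercept",), affected_interactions=(), affected_only=())
        des = eg.build_design(tab, spec)
        sigma2 = np.array([0.5, 1.0, 2.0, 0.25])
        ar1 = AR1Params(rho=[0.0] * 4, sigma2=sigma2)
        dev = eg.neg2_loglik(ar1, RandomEffectsCov.none(), des)
        expected = 0.0
        for k in range(4):
            obs = np.array([y["p1"][k], y["p2"][k]])
            r = obs - obs.mean()
            expected += np.sum(np.log(2 * np.pi * sigma2[k]) + r ** 2 / sigma2[k])
        assert np.isclose(dev, expected, rtol=1e-12)

    def test_model6_with_diagonal_D_equals_model4(self, small_study, medium_spec):
        des = eg.build_design(small_study, medium_spec)
        ar1 = AR1Params(rho=[0.7] * 4, sigma2=[0.3, 0.4, 0.35, 0.3])
        d = np.array([0.3, 0.4, 0.25, 0.35])
        dev4 = eg.neg2_loglik(ar1, RandomEffectsCov.diagonal(d), des)
        dev6 = eg.neg2_loglik(ar1, RandomEffectsCov.full(np.diag(d)), des)
        dev3 = eg.neg2_loglik(ar1, RandomEffectsCov.none(), des)
        dev6_zero = eg.neg2_loglik(ar1, RandomEffectsCov.full(np.zeros((4, 4))), des)
        assert np.isclose(dev4, dev6, rtol=1e-12)
        assert np.isclose(dev3, dev6_zero, rtol=1e-12)

    @pytest.mark.parametrize("estimation", ["ML", "REML"])
    @pytest.mark.parametrize("variant", ["model3", "model4", "model6"])
    def test_analytic_gradient_matches_finite_differences(
        self, variant, estimation, small_study, medium_spec
    ):
        des = eg.build_design(small_study, medium_spec)
        ev = _Evaluator(des, estimation=estimation)
        n = n_cov_params(variant)
        theta = _default_start(des, variant) + 0.1 * np.linspace(-1, 1, n)
        _, g = ev.objective(theta, variant)
        fd = approx_fprime(theta, lambda t: ev.objective(t, variant, want_grad=False), 1e-6)
        # one-sided differences carry O(eps) truncation error themselves
        assert np.max(np.abs(g - fd) / (np.abs(fd) + 1.0)) < 5e-4


class TestProfileBeta:
    def test_identity_covariance_is_ols(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        beta, cov = eg.profile_beta([y[:15], y[15:]], [X[:15], X[15:]], [np.eye(15)] * 2)
        expected = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(beta, expected)
        assert np.allclose(cov, np.linalg.inv(X.T @ X))

    def test_noise_free_interpolation(self, medium_spec, balanced_covariates):
        truth = default_truth(medium_spec)
        noise_free = dataclasses.replace(
            truth, ar1=AR1Params(rho=[0.0] * 4, sigma2=[0.0] * 4), recov=RandomEffectsCov.none()
        )
        cfg = eg.SyntheticConfig(
            n_patients=8, max_elevation=40, design=medium_spec,
            covariates=balanced_covariates, truth=noise_free, seed=32,
        )
        tab = eg.simulate_study(cfg)
        des = eg.build_design(tab, medium_spec)
        ar1 = AR1Params(rho=[0.5] * 4, sigma2=[0.3] * 4)
        ys, Xs, Vs = [], [], []
        for pid, sl, sub in des.layout.patient_slices():
            sub = sub.reset_index(drop=True).copy()
            sub[["start", "stop"]] -= sl.start
            ys.append(des.y[sl])
            Xs.append(des.X[sl])
            Vs.append(eg.marginal_cov(SeriesLayout(sub), ar1, RandomEffectsCov.none()))
        beta, _ = eg.profile_beta(ys, Xs, Vs, labels=des.labels)
        assert np.allclose(beta, noise_free.beta, atol=1e-8)

    def test_two_patient_toy_matches_direct_gls(self):
        X1 = np.array([[1.0, 0.0], [1.0, 1.0]])
        X2 = np.array([[1.0, 2.0], [1.0, 3.0]])
        y1 = np.array([0.3, 1.2])
        y2 = np.array([2.1, 3.3])
        V1 = np.array([[1.0, 0.4], [0.4, 1.0]])
        V2 = np.array([[0.5, -0.1], [-0.1, 0.8]])
        beta, cov = eg.profile_beta([y1, y2], [X1, X2], [V1, V2])
        M = X1.T @ np.linalg.inv(V1) @ X1 + X2.T @ np.linalg.inv(V2) @ X2
        b = X1.T @ np.linalg.inv(V1) @ y1 + X2.T @ np.linalg.inv(V2) @ y2
        assert np.allclose(beta, np.linalg.solve(M, b))
        assert np.allclose(cov, np.linalg.inv(M))


class TestFit:
    def test_nested_deviances_are_monotone(self, small_fits):
        d3 = small_fits["model3"].deviance
        d4 = small_fits["model4"].deviance
        d6 = small_fits["model6"].deviance
        assert d6 <= d4 + 1e-6 <= d3 + 2e-6

    def test_patient_order_invariance(self, small_study, medium_spec):
        r1 = eg.fit(small_study, medium_spec, "model3")
        shuffled = eg.ObservationTable(small_study.frame.sample(frac=1.0, random_state=3))
        r2 = eg.fit(shuffled, medium_spec, "model3")
        assert np.isclose(r1.deviance, r2.deviance, rtol=1e-8)
        assert np.allclose(r1.params.beta, r2.params.beta, atol=1e-6)

    def test_model4_recovery_on_simulated_truth(self, medium_spec, balanced_covariates):
        rho = np.array([0.79, 0.85, 0.82, 0.80])
        sigma2 = np.array([0.31, 0.37, 0.33, 0.29])
        d = np.array([0.33, 0.38, 0.29, 0.35])
        truth = dataclasses.replace(
            default_truth(medium_spec),
            ar1=AR1Params(rho=rho, sigma2=sigma2),
            recov=RandomEffectsCov.diagonal(d),
        )
        cfg = eg.SyntheticConfig(
            n_patients=80, max_elevation=60, design=medium_spec,
            covariates=balanced_covariates, truth=truth, seed=33,
        )
        res = eg.fit(eg.simulate_study(cfg), medium_spec, "model4")
        assert res.converged
        # MC error: AR(1) at rho ~ 0.8 shrinks the effective sample size by
        # (1+rho^2)/(1-rho^2) ~ 4.6, so sd(sigma2_hat)/sigma2 ~ 7% here
        assert np.all(np.abs(res.params.ar1.rho - rho) < 0.06)
        assert np.all(np.abs(res.params.ar1.sigma2 / sigma2 - 1) < 0.21)
        assert np.all(np.abs(np.diag(res.params.recov.D) - d) < 0.17)

    def test_model6_off_diagonals_near_zero_under_model4_truth(
        self, medium_spec, balanced_covariates
    ):
        truth = dataclasses.replace(
            default_truth(medium_spec),
            recov=RandomEffectsCov.diagonal([0.33, 0.38, 0.29, 0.35]),
        )
        cfg = eg.SyntheticConfig(
            n_patients=80, max_elevation=60, design=medium_spec,
            covariates=balanced_covariates, truth=truth, seed=34,
        )
        tab = eg.simulate_study(cfg)
        r4 = eg.fit(tab, medium_spec, "model4")
        r6 = eg.fit(tab, medium_spec, "model6")
        D6 = r6.params.recov.D
        off = D6[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.15
        assert 0 <= r4.deviance - r6.deviance < 20.0

    def test_singular_design_names_columns(self, medium_spec):
        cfg = eg.SyntheticConfig(
            n_patients=10, max_elevation=30, design=medium_spec,
            covariates=eg.CovariateModel(p_chemo=1.0, p_exercise_now=0.5), seed=35,
        )
        tab = eg.simulate_study(cfg)
        with pytest.raises(SingularDesignError) as err:
            eg.fit(tab, medium_spec, "model3")
        assert any("chemo" in c or "intercept" in c for c in err.value.columns)

    def test_reml_and_ml_variances_approach_each_other(self, medium_spec, balanced_covariates):
        """The REML-ML gap in the random-intercept variances shrinks with N."""
        gaps = {}
        for n_pat, seed in ((15, 36), (90, 37)):
            cfg = eg.SyntheticConfig(
                n_patients=n_pat, max_elevation=40, design=medium_spec,
                covariates=balanced_covariates, seed=seed,
            )
            tab = eg.simulate_study(cfg)
            ml = eg.fit(tab, medium_spec, "model4", eg.FitOptions(estimation="ML"))
            reml = eg.fit(tab, medium_spec, "model4", eg.FitOptions(estimation="REML"))
            gaps[n_pat] = np.mean(
                np.abs(np.diag(ml.params.recov.D) - np.diag(reml.params.recov.D))
            )
        assert gaps[90] < gaps[15]


class TestGapMode:
    def test_gap_power_agrees_on_contiguous_grids(self, small_study, medium_spec):
        """With no skipped increments the elevation-gap exponent equals the
        positional one, so the two modes give identical deviances."""
        des = eg.build_design(small_study, medium_spec)
        ar1 = AR1Params(rho=[0.7] * 4, sigma2=[0.3] * 4)
        d0 = eg.neg2_loglik(ar1, RandomEffectsCov.none(), des)
        d1 = eg.neg2_loglik(ar1, RandomEffectsCov.none(), des, ar1_on_gaps=True)
        assert np.isclose(d0, d1, rtol=1e-12)

    def test_gap_power_differs_with_skipped_increments(self, small_study, medium_spec):
        frame = small_study.frame
        # drop every observation at 20 degrees: lag between 10 and 30 becomes 2
        gappy = eg.ObservationTable(frame[frame["elevation_deg"] != 20])
        des = eg.build_design(gappy, medium_spec)
        ar1 = AR1Params(rho=[0.7] * 4, sigma2=[0.3] * 4)
        d0 = eg.neg2_loglik(ar1, RandomEffectsCov.none(), des)
        d1 = eg.neg2_loglik(ar1, RandomEffectsCov.none(), des, ar1_on_gaps=True)
        assert not np.isclose(d0, d1, rtol=1e-6)


class TestCountParameters:
    def test_ladder_differences(self):
        spec = eg.default_design_spec()
        n3 = eg.count_parameters(spec, "model3")
        n4 = eg.count_parameters(spec, "model4")
        n6 = eg.count_parameters(spec, "model6")
        assert n3 == (80, 8)
        assert n4[1] - n3[1] == 4
        assert n6[1] - n4[1] == 6
        assert n6[1] - n3[1] == 10
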