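"""The study simulator: moments, determinism, and degenerate limits."""

import dataclasses

import numpy as np
import pytest

import emglmm as eg
from emglmm.covariance import AR1Params, ModelParams, RandomEffectsCov
from emglmm.errors import ParameterError


def _truth(spec, rho, sigma2, D_variant="none", d=None, beta=None):
    base = eg.default_truth(spec)
    if D_variant == "none":
        recov = RandomEffectsCov.none()
    elif D_variant == "diagonal":
        recov = RandomEffectsCov.diagonal(d)
    else:
        recov = RandomEffectsCov.full(d)
    return ModelParams(
        beta=base.beta if beta is None else beta,
        ar1=AR1Params(rho=np.asarray(rho, float), sigma2=np.asarray(sigma2, float)),
        recov=recov,
    )


class TestCovariates:
    def test_degenerate_bernoulli(self):
        cfg = eg.SyntheticConfig(n_patients=50, covariates=eg.CovariateModel(p_wle=1.0), seed=0)
        cov = eg.generate_covariates(cfg)
        assert (cov["wle"] == 1).all()

    def test_default_study_size(self):
        cov = eg.generate_covariates(eg.SyntheticConfig(seed=0))
        assert len(cov) == 202

    def test_binomial_proportion(self):
        cfg = eg.SyntheticConfig(n_patients=10000, seed=11)
        cov = eg.generate_covariates(cfg)
        p_hat = cov["chemo"].mean()
        assert abs(p_hat - 0.5) < 3 * np.sqrt(0.25 / 10000)

    def test_spadi_right_skewed_nonnegative(self):
        cov = eg.generate_covariates(eg.SyntheticConfig(n_patients=2000, seed=12))
        for col, cap in (("spadi_pain_mm", 500), ("spadi_disability_mm", 800)):
            x = cov[col]
            assert (x >= 0).all() and (x <= cap).all()
            assert x.mean() > x.median()  # right skew

    def test_invalid_probability_rejected(self):
        with pytest.raises(ParameterError):
            eg.CovariateModel(p_chemo=1.3)


class TestSimulateStudy:
    def test_noise_free_limit_equals_linear_predictor(self, medium_spec, balanced_covariates):
        truth = _truth(medium_spec, rho=[0.0] * 4, sigma2=[0.0] * 4)
        cfg = eg.SyntheticConfig(
            n_patients=5, max_elevation=30, design=medium_spec,
            covariates=balanced_covariates, truth=truth, seed=1,
        )
        tab = eg.simulate_study(cfg)
        X = eg.build_design(tab, medium_spec).X
        assert np.allclose(tab.frame["log_emg"], X @ truth.beta, atol=1e-12)

    def test_residual_variance_matches_sigma2(self, medium_spec, balanced_covariates):
        """rho = 0, D = 0: empirical residual variance ~ sigma2_k over 1e5 points."""
        sigma2 = np.array([0.31, 0.37, 0.33, 0.29])
        truth = _truth(medium_spec, rho=[0.0] * 4, sigma2=sigma2)
        cfg = eg.SyntheticConfig(
            n_patients=420, max_elevation=150, design=medium_spec,
            covariates=balanced_covariates, truth=truth, seed=2,
        )
        tab = eg.simulate_study(cfg)
        assert len(tab) >= 100_000
        des = eg.build_design(tab, medium_spec)
        resid = des.y - des.X @ truth.beta
        mr = np.repeat(tab.layout.frame["muscle_idx"].to_numpy(), tab.layout.frame["n_i"].to_numpy())
        for k in range(4):
            r = resid[mr == k]
            se = sigma2[k] * np.sqrt(2.0 / len(r))
            assert abs(r.var() - sigma2[k]) < 3 * se

    def test_lag_one_autocorrelation_matches_rho(self, medium_spec, balanced_covariates):
        rho = np.array([0.79, 0.85, 0.82, 0.80])
        truth = _truth(medium_spec, rho=rho, sigma2=[0.31, 0.37, 0.33, 0.29])
        cfg = eg.SyntheticConfig(
            n_patients=150, max_elevation=150, design=medium_spec,
            covariates=balanced_covariates, truth=truth, seed=3,
        )
        tab = eg.simulate_study(cfg)
        des = eg.build_design(tab, medium_spec)
        resid = des.y - des.X @ truth.beta
        lay = tab.layout.frame
        for k in range(4):
            pairs_a, pairs_b = [], []
            for _, s in lay[lay["muscle_idx"] == k].iterrows():
                r = resid[s["start"] : s["stop"]]
                pairs_a.append(r[:-1])
                pairs_b.append(r[1:])
            a, b = np.concatenate(pairs_a), np.concatenate(pairs_b)
            r_hat = np.corrcoef(a, b)[0, 1]
            assert abs(r_hat - rho[k]) < 0.02  # ~5e4 pairs per muscle

    def test_marginal_variance_adds_frailty(self, medium_spec, balanced_covariates):
        """Var(y) = d_kk + sigma2_k under the full model."""
        d = np.array([0.33, 0.38, 0.29, 0.35])
        sigma2 = np.array([0.31, 0.37, 0.33, 0.29])
        truth = _truth(medium_spec, rho=[0.5] * 4, sigma2=sigma2, D_variant="diagonal", d=d)
        cfg = eg.SyntheticConfig(
            n_patients=600, max_elevation=60, design=medium_spec,
            covariates=balanced_covariates, truth=truth, seed=4,
        )
        tab = eg.simulate_study(cfg)
        des = eg.build_design(tab, medium_spec)
        resid = des.y - des.X @ truth.beta
        mr = np.repeat(tab.layout.frame["muscle_idx"].to_numpy(), tab.layout.frame["n_i"].to_numpy())
        for k in range(4):
            target = d[k] + sigma2[k]
            # effective sample size ~ n_patients (frailty shared within patient)
            assert abs(resid[mr == k].var() - target) < 4 * target * np.sqrt(2.0 / 600)

    def test_frailty_covariance_converges_to_D(self, medium_spec, balanced_covariates):
        """Per-patient muscle-mean residuals estimate nu_i; their covariance ~ D."""
        base = eg.default_truth(medium_spec)
        D = base.recov.D
        truth = _truth(
            medium_spec, rho=[0.2] * 4, sigma2=[0.01] * 4, D_variant="full", d=D
        )
        cfg = eg.SyntheticConfig(
            n_patients=800, max_elevation=40, design=medium_spec,
            covariates=balanced_covariates, truth=truth, seed=5,
        )
        tab = eg.simulate_study(cfg)
        des = eg.build_design(tab, medium_spec)
        resid = des.y - des.X @ truth.beta
        lay = tab.layout.frame
        mr = np.repeat(lay["muscle_idx"].to_numpy(), lay["n_i"].to_numpy())
        pid = np.repeat(lay["patient_id"].to_numpy(), lay["n_i"].to_numpy())
        import pandas as pd

        df = pd.DataFrame({"pid": pid, "k": mr, "r": resid})
        nu_hat = df.groupby(["pid", "k"])["r"].mean().unstack()
        D_hat = np.cov(nu_hat.to_numpy().T)
        # entrywise MC error ~ sqrt((d_jj d_kk + d_jk^2)/800) ~ 0.017; allow ~4 sigma
        assert np.max(np.abs(D_hat - D)) < 0.08

    def test_bit_identical_given_seed_and_stable_under_extension(self, medium_spec, balanced_covariates):
        cfg = eg.SyntheticConfig(
            n_patients=6, max_elevation=40, design=medium_spec,
            covariates=balanced_covariates, seed=9,
        )
        t1 = eg.simulate_study(cfg)
        t2 = eg.simulate_study(cfg)
        assert t1.frame.equals(t2.frame)
        bigger = eg.simulate_study(dataclasses.replace(cfg, n_patients=9))
        first = bigger.frame[bigger.frame["patient_id"].isin(t1.patients)]
        assert np.array_equal(first["log_emg"].to_numpy(), t1.frame["log_emg"].to_numpy())

    def test_invalid_truth_rejected(self, medium_spec):
        with pytest.raises(ParameterError):
            _truth(medium_spec, rho=[1.2, 0, 0, 0], sigma2=[1] * 4)
        with pytest.raises(ParameterError):
            RandomEffectsCov.full(np.diag([1.0, 1, 1, -0.5]))

    def test_config_yaml_roundtrip(self, tmp_path, medium_spec):
        cfg = eg.SyntheticConfig(n_patients=7, max_elevation=(50, 70), design=medium_spec, seed=4)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = eg.SyntheticConfig.from_yaml(path)
        assert back.n_patients == 7 and tuple(back.max_elevation) == (50, 70)
        assert back.design.terms == medium_spec.terms
        t1, t2 = cfg.resolved_truth(), back.resolved_truth()
        assert np.allclose(t1.beta, t2.beta) and np.allclose(t1.recov.D, t2.recov.D)
        assert eg.simulate_study(back).frame.equals(eg.simulate_study(cfg).frame)
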