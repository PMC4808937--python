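"""Maximum-likelihood estimation of the multivariate linear mixed model.

The marginal model per patient is ``y_i ~ N(X_i beta, V_i)`` with
``V_i = Z_i D Z_i' + blockdiag_series(AR1)``.  For fixed covariance
parameters the fixed effects have the closed-form GLS solution, so the
optimizer works on the profiled deviance over the unconstrained covariance
parameterization (log variances, arctanh autocorrelations, log-Cholesky D).

Two implementation choices matter for speed and are worth knowing about:

* patients sharing the same series layout share the same ``V_i``; they are
  grouped and factorized once, with all right-hand sides solved in one
  batched triangular solve;
* the gradient of the profiled deviance is analytic.  Because the profiled
  beta is the GLS minimizer, the quadratic form's beta-dependence drops out
  (envelope theorem) and each component is
  ``sum(G * dV/dtheta)`` with ``G = m V^{-1} - sum_i u_i u_i'``,
  ``u_i = V^{-1} r_i`` (REML subtracts the information-matrix correction).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import minimize

from .covariance import (
    _TRIL_IJ,
    AR1Params,
    ModelParams,
    N_MUSCLES,
    RandomEffectsCov,
    n_cov_params,
    unpack_cov_params,
)
from .data import MUSCLES, ObservationTable
from .design import DesignSpec, StackedDesign, build_design, default_design_spec
from .errors import ParameterError, SingularDesignError

_LOG2PI = float(np.log(2.0 * np.pi))
_FAIL_VALUE = 1e12


def count_parameters(spec: DesignSpec, variant: str):
    """(n_fixed, n_cov): 4 coefficients per covariate; 8 AR(1) parameters
    plus 0 / 4 / 10 random-effect parameters for model3 / model4 / model6."""
    return len(MUSCLES) * spec.p_per_muscle, n_cov_params(variant)


# ---------------------------------------------------------------------------
# layout grouping
# ---------------------------------------------------------------------------

@dataclass
class _Group:
    """Patients sharing one series layout, stacked for batched linear algebra."""

    X: np.ndarray        # (m, n, P)
    y: np.ndarray        # (m, n)
    mr: np.ndarray       # (n,) muscle index per row
    mask: np.ndarray     # (n, n) same-series indicator
    lag: np.ndarray      # (n, n) AR(1) exponent (positional or elevation-gap)
    Zind: np.ndarray     # (n, 4) muscle indicator columns
    slices: list         # row slices into the original design, per patient

    @property
    def m(self):
        return self.X.shape[0]

    @property
    def n(self):
        return self.X.shape[1]


def _patient_struct(sub, design, ar1_on_gaps):
    """Row-structure arrays for one patient's layout block."""
    n = int(sub["n_i"].sum())
    mr = np.repeat(sub["muscle_idx"].to_numpy(), sub["n_i"].to_numpy())
    sid = np.repeat(np.arange(len(sub)), sub["n_i"].to_numpy())
    if ar1_on_gaps:
        start = int(sub["start"].iloc[0])
        elev = design.index_frame["elevation_deg"].to_numpy()[start : start + n]
        pos = elev / 10.0
    else:
        pos = np.concatenate([np.arange(k) for k in sub["n_i"].to_numpy()]).astype(float)
    mask = sid[:, None] == sid[None, :]
    lag = np.abs(pos[:, None] - pos[None, :]) * mask
    Zind = np.zeros((n, N_MUSCLES))
    Zind[np.arange(n), mr] = 1.0
    return mr, mask, lag, Zind


def _build_groups(design: StackedDesign, ar1_on_gaps: bool = False):
    groups = {}
    for pid, sl, sub in design.layout.patient_slices():
        sig = tuple(zip(sub["muscle_idx"], sub["n_i"]))
        if ar1_on_gaps:
            sig = sig + tuple(design.index_frame["elevation_deg"].to_numpy()[sl.start : sl.stop])
        groups.setdefault(sig, ([], sub))[0].append(sl)
    out = []
    for sig, (slices, sub0) in groups.items():
        mr, mask, lag, Zind = _patient_struct(sub0, design, ar1_on_gaps)
        X = np.stack([design.X[sl] for sl in slices])
        y = np.stack([design.y[sl] for sl in slices])
        out.append(_Group(X=X, y=y, mr=mr, mask=mask, lag=lag, Zind=Zind, slices=slices))
    return out


def _build_V(g: _Group, ar1: AR1Params, D: np.ndarray):
    """(V, ar_part) for one group; ar_part is reused by the gradient."""
    sig_r = ar1.sigma2[g.mr][:, None]
    rho_r = ar1.rho[g.mr][:, None]
    ar_part = np.where(g.mask, sig_r * rho_r ** g.lag, 0.0)
    V = D[np.ix_(g.mr, g.mr)] + ar_part
    return V, ar_part


# ---------------------------------------------------------------------------
# profiled deviance and gradient
# ---------------------------------------------------------------------------

class _Evaluator:
    """Profiled -2 log likelihood over a fixed grouping of the data."""

    def __init__(self, design: StackedDesign, estimation: str = "ML", ar1_on_gaps: bool = False):
        if estimation not in ("ML", "REML"):
            raise ValueError("estimation must be 'ML' or 'REML'")
        self.design = design
        self.estimation = estimation
        self.groups = _build_groups(design, ar1_on_gaps)
        self.P = design.n_columns
        self.n_obs = design.n_obs

    def _raise_singular(self, M):
        w, v = np.linalg.eigh(M)
        load = np.abs(v[:, 0])
        cols = [self.design.labels[j] for j in np.flatnonzero(load > 0.3 * load.max())]
        raise SingularDesignError(
            f"stacked design is (numerically) rank deficient; suspect columns: {cols}", cols
        )

    def value(self, ar1: AR1Params, recov: RandomEffectsCov, want_grad=False, L=None):
        """Returns (deviance, beta, beta_cov, grad_pieces or None).

        ``grad_pieces`` is a dict with the raw accumulators
        (per-muscle AR(1) sums, aggregated Z'GZ) that the caller chains
        through the unconstrained parameterization.
        """
        if np.any(ar1.sigma2 <= 0):
            raise ParameterError("estimation requires sigma2 > 0")
        P = self.P
        D = recov.D
        reml = self.estimation == "REML"

        caches = []
        M = np.zeros((P, P))
        bvec = np.zeros(P)
        yty = 0.0
        logdet_tot = 0.0
        for g in self.groups:
            m, n = g.m, g.n
            V, ar_part = _build_V(g, ar1, D)
            try:
                c = cho_factor(V, lower=True, check_finite=False)
            except LinAlgError:
                return None  # caller maps to a large penalty
            logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
            Xf = g.X.transpose(1, 0, 2).reshape(n, m * P)
            rhs = np.concatenate([Xf, g.y.T], axis=1)
            sol = cho_solve(c, rhs, check_finite=False)
            ViXf = sol[:, : m * P]
            Viy = sol[:, m * P :]          # (n, m)
            # patient-major 2-D views so the accumulation hits BLAS
            Xl = g.X.reshape(m * n, P)
            ViXl = np.ascontiguousarray(ViXf.reshape(n, m, P).transpose(1, 0, 2)).reshape(m * n, P)
            M += Xl.T @ ViXl
            bvec += Xl.T @ Viy.T.ravel()
            yty += float(g.y.ravel() @ Viy.T.ravel())
            logdet_tot += m * logdet
            caches.append((g, c, ar_part, ViXl))

        try:
            cM = cho_factor(M, lower=True, check_finite=False)
        except LinAlgError:
            self._raise_singular(M)
        beta = cho_solve(cM, bvec, check_finite=False)
        beta_cov = cho_solve(cM, np.eye(P), check_finite=False)
        quad = yty - float(beta @ bvec)
        dev = logdet_tot + quad + self.n_obs * _LOG2PI
        if reml:
            dev += 2.0 * np.sum(np.log(np.diag(cM[0]))) - P * _LOG2PI

        if not want_grad:
            return dev, beta, beta_cov, None

        g_logsig = np.zeros(N_MUSCLES)
        g_rho = np.zeros(N_MUSCLES)
        GZ = np.zeros((N_MUSCLES, N_MUSCLES))
        for g, c, ar_part, ViXl in caches:
            m, n = g.m, g.n
            Vinv = cho_solve(c, np.eye(n), check_finite=False)
            R = g.y - (g.X.reshape(m * n, P) @ beta).reshape(m, n)
            U = cho_solve(c, R.T, check_finite=False)        # (n, m)
            G = m * Vinv - U @ U.T
            if reml:
                T = ViXl @ beta_cov                          # (m*n, P)
                for i in range(m):
                    Wi = ViXl[i * n : (i + 1) * n]
                    G -= Wi @ T[i * n : (i + 1) * n].T
            GA = (G * ar_part).sum(axis=1)
            g_logsig += np.bincount(g.mr, weights=GA, minlength=N_MUSCLES)
            rho_r = ar1.rho[g.mr][:, None]
            d_ar = np.where(
                g.lag > 0,
                ar1.sigma2[g.mr][:, None] * g.lag * rho_r ** np.maximum(g.lag - 1.0, 0.0),
                0.0,
            ) * g.mask
            GD = (G * d_ar).sum(axis=1)
            g_rho += np.bincount(g.mr, weights=GD, minlength=N_MUSCLES)
            GZ += g.Zind.T @ G @ g.Zind
        pieces = {"g_logsig": g_logsig, "g_rho": g_rho, "GZ": GZ}
        return dev, beta, beta_cov, pieces

    def objective(self, theta: np.ndarray, variant: str, want_grad=True):
        """theta-space deviance and gradient for the optimizer."""
        ar1, recov, L = unpack_cov_params(theta, variant)
        res = self.value(ar1, recov, want_grad=want_grad, L=L)
        if res is None:
            return (_FAIL_VALUE, np.zeros_like(theta)) if want_grad else _FAIL_VALUE
        dev, beta, beta_cov, pieces = res
        if not want_grad:
            return dev
        grad = np.zeros(n_cov_params(variant))
        grad[:4] = pieces["g_logsig"]                       # dV/dlog sigma2_k = ar_part(k)
        grad[4:8] = pieces["g_rho"] * (1.0 - ar1.rho ** 2)  # chain arctanh
        GZ = pieces["GZ"]
        if variant == "model4":
            grad[8:12] = np.diag(GZ) * np.diag(recov.D)
        elif variant == "model6":
            GL = 2.0 * GZ @ L
            grad[8:12] = np.diag(GL) * np.diag(L)
            grad[12:18] = [GL[i, j] for i, j in _TRIL_IJ]
        return dev, grad


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def profile_beta(ys, Xs, Vs, labels=None):
    """Closed-form GLS fixed effects given per-patient covariance matrices.

    beta = (sum X_i' V_i^-1 X_i)^-1 sum X_i' V_i^-1 y_i, with
    beta_cov the inverted information matrix; computed with per-patient
    Cholesky solves, never explicit covariance inverses.
    """
    ys = [np.asarray(y, dtype=float) for y in ys]
    Xs = [np.asarray(X, dtype=float) for X in Xs]
    P = Xs[0].shape[1]
    M = np.zeros((P, P))
    b = np.zeros(P)
    for y, X, V in zip(ys, Xs, Vs):
        c = cho_factor(np.asarray(V, dtype=float), lower=True)
        ViX = cho_solve(c, X)
        M += X.T @ ViX
        b += ViX.T @ y
    try:
        cM = cho_factor(M, lower=True)
    except LinAlgError:
        w, v = np.linalg.eigh(M)
        load = np.abs(v[:, 0])
        idx = np.flatnonzero(load > 0.3 * load.max())
        cols = [labels[j] for j in idx] if labels else list(idx)
        raise SingularDesignError(f"rank-deficient design; suspect columns: {cols}", cols) from None
    beta = cho_solve(cM, b)
    beta_cov = cho_solve(cM, np.eye(P))
    return beta, beta_cov


def neg2_loglik(ar1: AR1Params, recov: RandomEffectsCov, design: StackedDesign,
                estimation: str = "ML", ar1_on_gaps: bool = False) -> float:
    """-2 log marginal likelihood at the profiled (GLS) fixed effects.

    ML:   sum_i [log det V_i + r_i' V_i^-1 r_i] + n log 2*pi.
    REML: adds log det(sum_i X_i' V_i^-1 X_i) and replaces n by n - p in
    the constant.
    """
    ev = _Evaluator(design, estimation=estimation, ar1_on_gaps=ar1_on_gaps)
    res = ev.value(ar1, recov)
    if res is None:
        raise ParameterError("covariance matrix not positive definite at these parameters")
    return res[0]


@dataclass
class FitOptions:
    estimation: str = "ML"
    ftol: float = 1e-8          # relative deviance tolerance
    gtol: float = 1e-5          # projected-gradient tolerance
    maxiter: int = 500
    multistart: int = 0         # extra perturbed starts
    seed: int = 0
    ar1_on_gaps: bool = False
    start: np.ndarray | None = None  # unconstrained covariance start, overrides defaults


@dataclass
class FitResult:
    """Everything a downstream test or report needs from one model fit."""

    variant: str
    params: ModelParams
    deviance: float
    beta_cov: np.ndarray
    labels: list
    n_params: tuple                 # (n_fixed, n_cov)
    converged: bool
    estimation: str
    spec: DesignSpec
    optimizer: dict = field(default_factory=dict)
    boundary_warnings: list = field(default_factory=list)
    design: StackedDesign | None = field(default=None, repr=False)

    @property
    def n_total_params(self) -> int:
        return self.n_params[0] + self.n_params[1]

    def coef_frame(self) -> pd.DataFrame:
        """Coefficients and standard errors as a term x muscle table."""
        terms = self.spec.terms
        p = len(terms)
        se = np.sqrt(np.diag(self.beta_cov))
        est = self.params.beta
        data = {}
        for k, m in enumerate(MUSCLES):
            data[m] = est[k * p : (k + 1) * p]
            data[f"{m}_se"] = se[k * p : (k + 1) * p]
        return pd.DataFrame(data, index=list(terms))

    def summary(self) -> str:
        lines = [
            f"variant: {self.variant}   estimation: {self.estimation}   "
            f"converged: {self.converged}",
            f"deviance (-2 log L): {self.deviance:.4f}",
            f"parameters: {self.n_params[0]} fixed + {self.n_params[1]} covariance",
            "",
            self.coef_frame().round(4).to_string(),
            "",
            "AR(1) rho:    " + "  ".join(f"{m}={r:.3f}" for m, r in zip(MUSCLES, self.params.ar1.rho)),
            "AR(1) sigma2: " + "  ".join(f"{m}={s:.3f}" for m, s in zip(MUSCLES, self.params.ar1.sigma2)),
        ]
        if self.variant != "model3":
            d = np.diag(self.params.recov.D)
            lines.append("RE variance:  " + "  ".join(f"{m}={v:.3f}" for m, v in zip(MUSCLES, d)))
        if self.boundary_warnings:
            lines.append("boundary warnings: " + "; ".join(self.boundary_warnings))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "estimation": self.estimation,
            "deviance": float(self.deviance),
            "converged": bool(self.converged),
            "n_params": {"fixed": self.n_params[0], "covariance": self.n_params[1]},
            "beta": {lab: float(b) for lab, b in zip(self.labels, self.params.beta)},
            "beta_se": {lab: float(s) for lab, s in zip(self.labels, np.sqrt(np.diag(self.beta_cov)))},
            "rho": dict(zip(MUSCLES, map(float, self.params.ar1.rho))),
            "sigma2": dict(zip(MUSCLES, map(float, self.params.ar1.sigma2))),
            "D": np.asarray(self.params.recov.D).tolist(),
            "optimizer": {k: (v if not isinstance(v, np.ndarray) else v.tolist()) for k, v in self.optimizer.items()},
            "boundary_warnings": list(self.boundary_warnings),
        }


def _default_start(design: StackedDesign, variant: str):
    X, y = design.X, design.y
    beta_ols, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # identify offending columns via the information matrix spectrum
        M = X.T @ X
        w, v = np.linalg.eigh(M)
        load = np.abs(v[:, 0])
        cols = [design.labels[j] for j in np.flatnonzero(load > 0.3 * load.max())]
        raise SingularDesignError(f"design not full column rank; suspect columns: {cols}", cols)
    resid = y - X @ beta_ols
    mr = np.repeat(
        design.layout.frame["muscle_idx"].to_numpy(), design.layout.frame["n_i"].to_numpy()
    )
    sig2 = np.array([max(np.var(resid[mr == k]), 1e-4) for k in range(N_MUSCLES)])
    theta = [np.log(sig2 / 2.0), np.full(4, np.arctanh(0.5))]
    if variant == "model4":
        theta.append(np.full(4, np.log(0.1)))
    elif variant == "model6":
        theta.append(np.full(4, np.log(np.sqrt(0.1))))  # L = sqrt(0.1) I
        theta.append(np.zeros(6))
    return np.concatenate(theta)


def _bounds(variant: str):
    b = [(-20.0, 20.0)] * 4 + [(-7.0, 7.0)] * 4
    if variant == "model4":
        b += [(-20.0, 20.0)] * 4
    elif variant == "model6":
        b += [(-10.0, 10.0)] * 4 + [(-100.0, 100.0)] * 6
    return b


def fit(data, spec: DesignSpec | None = None, variant: str = "model6",
        options: FitOptions | None = None) -> FitResult:
    """Fit one rung of the model ladder by (RE)ML.

    Parameters
    ----------
    data : ObservationTable or StackedDesign
        When a table is given the design is built from ``spec`` (default:
        the full specification).
    variant : {'model3', 'model4', 'model6'}
        No random effects / independent muscle intercepts / correlated
        muscle intercepts.
    options : FitOptions
        Estimation mode (ML default), tolerances, optional seeded
        multistart.
    """
    options = options or FitOptions()
    if isinstance(data, StackedDesign):
        design = data
        spec = design.spec
    else:
        spec = spec or default_design_spec()
        design = build_design(data, spec)
    if design.layout.n_patients < 2:
        raise ValueError("fitting requires at least 2 patients")
    if variant not in ("model3", "model4", "model6"):
        raise ParameterError(f"unknown model variant {variant!r}")

    ev = _Evaluator(design, estimation=options.estimation, ar1_on_gaps=options.ar1_on_gaps)
    theta0 = options.start if options.start is not None else _default_start(design, variant)
    theta0 = np.asarray(theta0, dtype=float)
    if theta0.shape != (n_cov_params(variant),):
        raise ParameterError(f"start vector must have {n_cov_params(variant)} entries")

    rng = np.random.default_rng(options.seed)
    starts = [theta0] + [
        theta0 + rng.normal(scale=0.3, size=theta0.shape) for _ in range(options.multistart)
    ]
    best = None
    for s in starts:
        res = minimize(
            ev.objective,
            s,
            args=(variant,),
            jac=True,
            method="L-BFGS-B",
            bounds=_bounds(variant),
            options={"ftol": options.ftol, "gtol": options.gtol, "maxiter": options.maxiter},
        )
        if best is None or res.fun < best.fun:
            best = res
    res = best

    ar1, recov, _ = unpack_cov_params(res.x, variant)
    dev, beta, beta_cov, _ = ev.value(ar1, recov)
    converged = bool(res.success) and np.isfinite(dev)

    boundary = []
    if np.any(ar1.sigma2 < 1e-6):
        boundary.append("residual variance near zero")
    if np.any(np.abs(ar1.rho) > 0.999):
        boundary.append("autocorrelation near +/-1")
    if variant != "model3" and np.any(np.diag(recov.D) < 1e-6):
        boundary.append("random-effect variance near zero")
    for w in boundary:
        warnings.warn(f"fit({variant}): {w}", UserWarning, stacklevel=2)

    return FitResult(
        variant=variant,
        params=ModelParams(beta=beta, ar1=ar1, recov=recov),
        deviance=float(dev),
        beta_cov=beta_cov,
        labels=list(design.labels),
        n_params=count_parameters(spec, variant),
        converged=converged,
        estimation=options.estimation,
        spec=spec,
        optimizer={
            "nit": int(res.nit),
            "nfev": int(res.nfev),
            "message": str(res.message),
            "grad_inf_norm": float(np.max(np.abs(res.jac))),
            "n_starts": len(starts),
        },
        boundary_warnings=boundary,
        design=design,
    )
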