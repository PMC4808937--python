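"""Residual diagnostics: standardized and leave-one-observation-out residuals.

Standardized residuals whiten each patient's residual vector with the
Cholesky factor of the fitted marginal covariance, ``L_i^{-1}(y_i - X_i b)``;
under a correctly specified model they are iid standard normal, so about
4.55% should exceed 2 in absolute value.  A marginal variant
(raw residual over the marginal standard deviation) is available.

Deletion residuals compare each observation with its prediction from fixed
effects re-estimated without that observation, holding the covariance
parameters at the full-fit values.  The fast path downdates the GLS normal
equations with the Schur-complement / Sherman-Morrison identities; the
brute path refits the fixed effects per deletion and exists as an oracle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .covariance import marginal_cov
from .data import ObservationTable, SeriesLayout
from .errors import ParameterError
from .estimation import FitResult


def _design_of(fit_result: FitResult, data: ObservationTable | None):
    if data is not None:
        from .design import build_design

        return build_design(data, fit_result.spec)
    if fit_result.design is None:
        raise ValueError("fit carries no design; pass the observation table explicitly")
    return fit_result.design


def _patient_covariances(fit_result: FitResult, design):
    """Yield (slice, V_i) per patient at the fitted covariance parameters."""
    ar1 = fit_result.params.ar1
    recov = fit_result.params.recov
    for pid, sl, sub in design.layout.patient_slices():
        sub = sub.reset_index(drop=True).copy()
        sub[["start", "stop"]] -= sl.start  # rebase to the patient block
        yield pid, sl, marginal_cov(SeriesLayout(sub), ar1, recov)


def standardized_residuals(
    fit_result: FitResult,
    data: ObservationTable | None = None,
    standardization: str = "cholesky",
) -> pd.DataFrame:
    """Residual table with raw and standardized residuals per observation.

    standardization 'cholesky' (default) whitens within patients; under the
    fitted model the result is exactly iid N(0, 1).  'marginal' divides the
    raw residual by its marginal standard deviation (correlated but
    scale-free).
    """
    if standardization not in ("cholesky", "marginal"):
        raise ValueError("standardization must be 'cholesky' or 'marginal'")
    design = _design_of(fit_result, data)
    raw = design.y - design.X @ fit_result.params.beta
    std = np.empty_like(raw)
    for pid, sl, V in _patient_covariances(fit_result, design):
        if standardization == "cholesky":
            try:
                L = np.linalg.cholesky(V)
            except np.linalg.LinAlgError:
                raise ParameterError(f"fitted covariance for patient {pid!r} is not PD") from None
            std[sl] = solve_triangular(L, raw[sl], lower=True)
        else:
            std[sl] = raw[sl] / np.sqrt(np.diag(V))
    out = design.index_frame.copy()
    out["raw_residual"] = raw
    out["standardized_residual"] = std
    return out


def exceedance_summary(residuals: pd.DataFrame, threshold: float = 2.0,
                       column: str = "standardized_residual") -> dict:
    """Fraction of residuals beyond +/- threshold, with the standard-normal
    reference (4.55% for threshold 2, i.e. the "about 5%" rule of thumb)."""
    from scipy import stats

    r = residuals[column].to_numpy()
    r = r[np.isfinite(r)]
    expected = 2.0 * stats.norm.sf(threshold)
    frac = float(np.mean(np.abs(r) > threshold))
    return {
        "threshold": threshold,
        "n": int(r.size),
        "observed_fraction": frac,
        "expected_fraction": float(expected),
    }


def deletion_residuals(
    fit_result: FitResult,
    data: ObservationTable | None = None,
    mode: str = "fast",
) -> pd.DataFrame:
    """Leave-one-observation-out residuals at fixed covariance parameters.

    For observation j the fixed effects are re-estimated from all data
    except j; the residual is ``(y_j - x_j' b_(-j)) / sd_j`` with
    ``sd_j^2 = V_jj + x_j' M_(-j)^{-1} x_j`` (marginal variance plus the
    estimation variance of the deleted-data prediction).  'fast' uses exact
    rank-one downdates of the normal equations; 'brute' refits per deletion
    (identical values, used as the correctness oracle).  A deletion that
    makes the design rank deficient yields NaN for that row.
    """
    if mode not in ("fast", "brute"):
        raise ValueError("mode must be 'fast' or 'brute'")
    design = _design_of(fit_result, data)
    X, y = design.X, design.y
    P = X.shape[1]

    patients = list(_patient_covariances(fit_result, design))
    M = np.zeros((P, P))
    b = np.zeros(P)
    per_patient = []
    for pid, sl, V in patients:
        c = cho_factor(V, lower=True)
        Pm = cho_solve(c, np.eye(V.shape[0]))      # V_i^{-1}
        W = Pm @ X[sl]                             # V^{-1} X
        cvec = Pm @ y[sl]                          # V^{-1} y
        M += X[sl].T @ W
        b += X[sl].T @ cvec
        per_patient.append((sl, V, Pm, W, cvec))
    Minv = np.linalg.inv(M)

    deletion = np.full(len(y), np.nan)
    for sl, V, Pm, W, cvec in per_patient:
        Xi, yi = X[sl], y[sl]
        for j in range(V.shape[0]):
            gj = sl.start + j
            pjj = Pm[j, j]
            w = W[j]                               # X' V^{-1} e_j
            if mode == "fast":
                bj = b - w * (cvec[j] / pjj)
                Mw = Minv @ w
                denom = pjj - float(w @ Mw)
                if denom <= 1e-12 * pjj:
                    continue                       # deletion breaks identifiability
                Minv_j = Minv + np.outer(Mw, Mw) / denom
                beta_j = Minv_j @ bj
            else:
                # genuinely refit: drop row j from this patient and redo GLS
                keep = np.ones(V.shape[0], dtype=bool)
                keep[j] = False
                Vk = V[np.ix_(keep, keep)]
                ck = cho_factor(Vk, lower=True)
                ViXk = cho_solve(ck, Xi[keep])
                Mj = M - Xi.T @ W + Xi[keep].T @ ViXk
                bj = b - Xi.T @ cvec + ViXk.T @ yi[keep]
                try:
                    cj = cho_factor(Mj, lower=True)
                except np.linalg.LinAlgError:
                    continue
                Minv_j = cho_solve(cj, np.eye(P))
                beta_j = Minv_j @ bj
            pred = float(Xi[j] @ beta_j)
            var = float(V[j, j] + Xi[j] @ Minv_j @ Xi[j])
            deletion[gj] = (yi[j] - pred) / np.sqrt(var)

    out = standardized_residuals(fit_result, data, standardization="marginal")
    out = out.rename(columns={"standardized_residual": "marginal_standardized_residual"})
    out["deletion_residual"] = deletion
    return out
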