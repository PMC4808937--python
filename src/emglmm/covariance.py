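"""Covariance structures of the model ladder.

Within one (patient, muscle, side, movement) series the residual covariance
is stationary AR(1): entry (a, b) is ``sigma2_k * rho_k ** |a-b|``, shared
by all four side-by-movement series of muscle ``k``.  On top of the
block-diagonal AR(1) part, each patient carries a 4-vector of
muscle-specific random intercepts ``nu_i ~ N(0, D)``; its loading matrix
``Z_i`` has one column per muscle.  The three model variants differ only in
``D``: absent (model3), diagonal (model4), or full symmetric PSD (model6).

Optimization uses an unconstrained parameterization: ``log sigma2_k``,
``arctanh rho_k``, and for D either ``log d_kk`` (diagonal) or a
log-Cholesky factor (full; logs on the diagonal of L, free off-diagonals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import MUSCLES, SeriesLayout
from .errors import ParameterError

N_MUSCLES = len(MUSCLES)

VARIANTS = ("model3", "model4", "model6")

# lower-triangle off-diagonal order used by the log-Cholesky packing
_TRIL_IJ = [(1, 0), (2, 0), (2, 1), (3, 0), (3, 1), (3, 2)]


@dataclass(frozen=True)
class AR1Params:
    """Per-muscle AR(1) residual parameters (rho_k, sigma2_k), k = PM, UT, SA, RH.

    ``sigma2`` is the marginal residual variance in (ln mV)^2.  A zero
    variance is tolerated here only so degenerate noise-free simulations can
    be expressed; every covariance-building and fitting routine requires
    strictly positive variances.
    """

    rho: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rho", np.asarray(self.rho, dtype=float))
        object.__setattr__(self, "sigma2", np.asarray(self.sigma2, dtype=float))
        if self.rho.shape != (N_MUSCLES,) or self.sigma2.shape != (N_MUSCLES,):
            raise ParameterError(f"rho and sigma2 must each have {N_MUSCLES} entries")
        if np.any(np.abs(self.rho) >= 1):
            raise ParameterError("autocorrelation rho must satisfy |rho| < 1")
        if np.any(self.sigma2 < 0):
            raise ParameterError("residual variance sigma2 must be non-negative")


@dataclass(frozen=True)
class RandomEffectsCov:
    """Covariance D of the muscle-specific random intercepts.

    variant 'none' encodes model3 (D = 0), 'diagonal' model4 (independent
    intercepts), 'full' model6 (correlated intercepts, D symmetric PSD).
    """

    variant: str
    D: np.ndarray

    def __post_init__(self):
        if self.variant not in ("none", "diagonal", "full"):
            raise ParameterError(f"unknown random-effects variant {self.variant!r}")
        D = np.asarray(self.D, dtype=float)
        object.__setattr__(self, "D", D)
        if D.shape != (N_MUSCLES, N_MUSCLES):
            raise ParameterError("D must be 4x4")
        if not np.allclose(D, D.T, atol=1e-12):
            raise ParameterError("D must be symmetric")
        if self.variant == "none" and np.any(D != 0):
            raise ParameterError("variant 'none' requires D = 0")
        if self.variant == "diagonal" and np.any(D - np.diag(np.diag(D)) != 0):
            raise ParameterError("variant 'diagonal' requires zero off-diagonals")
        if np.any(np.diag(D) < 0):
            raise ParameterError("D must have non-negative diagonal")
        if self.variant == "full":
            w = np.linalg.eigvalsh(D)
            if w.min() < -1e-10 * max(1.0, w.max()):
                raise ParameterError("D must be positive semidefinite")

    @classmethod
    def none(cls) -> "RandomEffectsCov":
        return cls("none", np.zeros((N_MUSCLES, N_MUSCLES)))

    @classmethod
    def diagonal(cls, d) -> "RandomEffectsCov":
        return cls("diagonal", np.diag(np.asarray(d, dtype=float)))

    @classmethod
    def full(cls, D) -> "RandomEffectsCov":
        return cls("full", np.asarray(D, dtype=float))


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set: stacked fixed effects plus covariance components."""

    beta: np.ndarray
    ar1: AR1Params
    recov: RandomEffectsCov

    def __post_init__(self):
        object.__setattr__(self, "beta", np.asarray(self.beta, dtype=float))


def ar1_block(n: int, rho: float, sigma2: float) -> np.ndarray:
    """The n x n stationary AR(1) covariance sigma2 * rho**|a-b|.

    Symmetric positive definite for |rho| < 1, sigma2 > 0; its determinant
    is sigma2**n * (1 - rho**2)**(n-1) and its inverse is tridiagonal.
    """
    if n < 1:
        raise ParameterError("AR(1) block length must be >= 1")
    if not abs(rho) < 1:
        raise ParameterError(f"|rho| must be < 1, got {rho}")
    if not sigma2 > 0:
        raise ParameterError(f"sigma2 must be > 0, got {sigma2}")
    idx = np.arange(n)
    return sigma2 * rho ** np.abs(idx[:, None] - idx[None, :])


def random_effect_loading(layout: SeriesLayout) -> np.ndarray:
    """Loading matrix Z_i for one patient: one column per muscle.

    Entry (row, k) is 1 iff the observation belongs to muscle k — the
    intercept nu_ik is shared across that muscle's sides, movements and
    elevations.  The layout must describe a single patient.
    """
    f = layout.frame
    if f["patient_id"].nunique() > 1:
        raise ValueError("random_effect_loading expects a single patient's layout")
    n = layout.n_obs
    offset = int(f["start"].iloc[0]) if len(f) else 0
    Z = np.zeros((n, N_MUSCLES))
    for _, row in f.iterrows():
        Z[row["start"] - offset : row["stop"] - offset, row["muscle_idx"]] = 1.0
    return Z


def marginal_cov(layout: SeriesLayout, ar1: AR1Params, recov: RandomEffectsCov) -> np.ndarray:
    """Per-patient marginal covariance V_i = Z_i D Z_i' + blockdiag(AR(1) blocks).

    All four side-by-movement series of muscle k share (rho_k, sigma2_k).
    """
    f = layout.frame
    if len(f) and f["patient_id"].nunique() > 1:
        raise ValueError("marginal_cov expects a single patient's layout")
    Z = random_effect_loading(layout)
    V = Z @ recov.D @ Z.T
    offset = int(f["start"].iloc[0]) if len(f) else 0
    for _, row in f.iterrows():
        k = row["muscle_idx"]
        sl = slice(row["start"] - offset, row["stop"] - offset)
        V[sl, sl] += ar1_block(row["n_i"], ar1.rho[k], ar1.sigma2[k])
    return V


# ---------------------------------------------------------------------------
# unconstrained packing for the optimizer
# ---------------------------------------------------------------------------

def n_cov_params(variant: str) -> int:
    """Free covariance parameters: 8 AR(1) plus {0, 4, 10} for D."""
    try:
        extra = {"model3": 0, "model4": 4, "model6": 10}[variant]
    except KeyError:
        raise ParameterError(f"unknown model variant {variant!r}") from None
    return 2 * N_MUSCLES + extra


def pack_cov_params(ar1: AR1Params, recov: RandomEffectsCov, variant: str) -> np.ndarray:
    """Map (AR1Params, RandomEffectsCov) to the unconstrained vector."""
    if np.any(ar1.sigma2 <= 0):
        raise ParameterError("packing requires sigma2 > 0")
    theta = [np.log(ar1.sigma2), np.arctanh(ar1.rho)]
    if variant == "model4":
        d = np.diag(recov.D)
        if np.any(d <= 0):
            raise ParameterError("model4 packing requires positive diagonal of D")
        theta.append(np.log(d))
    elif variant == "model6":
        L = np.linalg.cholesky(recov.D + 1e-12 * np.eye(N_MUSCLES))
        theta.append(np.log(np.diag(L)))
        theta.append(np.array([L[i, j] for i, j in _TRIL_IJ]))
    return np.concatenate(theta)


def unpack_cov_params(theta: np.ndarray, variant: str):
    """Inverse of :func:`pack_cov_params`.

    Returns (AR1Params, RandomEffectsCov, L) where L is the Cholesky factor
    of D (zeros for model3) — the gradient code needs L.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_cov_params(variant),):
        raise ParameterError(f"expected {n_cov_params(variant)} parameters for {variant}")
    sigma2 = np.exp(theta[:4])
    rho = np.tanh(theta[4:8])
    L = np.zeros((N_MUSCLES, N_MUSCLES))
    if variant == "model3":
        recov = RandomEffectsCov.none()
    elif variant == "model4":
        L[np.diag_indices(4)] = np.exp(0.5 * theta[8:12])  # L = sqrt(d_kk) on the diagonal
        recov = RandomEffectsCov.diagonal(np.exp(theta[8:12]))
    else:
        L[np.diag_indices(4)] = np.exp(theta[8:12])
        for t, (i, j) in zip(theta[12:18], _TRIL_IJ):
            L[i, j] = t
        recov = RandomEffectsCov.full(L @ L.T)
    return AR1Params(rho=rho, sigma2=sigma2), recov, L
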