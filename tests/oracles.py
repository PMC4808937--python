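"""Independent oracles used by the test suite.

These deliberately avoid the package's marginal-covariance likelihood path:
the hierarchical deviance integrates the conditional Gaussian model over
the random effects with tensor-product Gauss-Hermite quadrature.
"""

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import logsumexp

import emglmm as eg
from emglmm.covariance import RandomEffectsCov
from emglmm.data import SeriesLayout


def quadrature_deviance(design, beta, ar1, recov, n_nodes=60):
    """-2 log likelihood of the hierarchical model by numerical integration.

    For each patient, integrates N(y; X beta + Z nu, A) against the
    N(0, D) prior of nu over the muscles present, where A is the
    block-diagonal AR(1) residual covariance.
    """
    from numpy.polynomial.hermite import hermgauss

    x, w = hermgauss(n_nodes)
    total = 0.0
    for pid, sl, sub in design.layout.patient_slices():
        sub = sub.reset_index(drop=True).copy()
        sub[["start", "stop"]] -= sl.start
        lay = SeriesLayout(sub)
        A = eg.marginal_cov(lay, ar1, RandomEffectsCov.none())  # AR(1) part only
        Z = eg.random_effect_loading(lay)
        present = np.flatnonzero(Z.sum(axis=0) > 0)
        d = len(present)
        Dsub = recov.D[np.ix_(present, present)]
        Lp = np.linalg.cholesky(Dsub + 1e-14 * np.eye(d))
        La = np.linalg.cholesky(A)
        resid = design.y[sl] - design.X[sl] @ beta
        rw = solve_triangular(La, resid, lower=True)
        Zw = solve_triangular(La, Z[:, present], lower=True)
        n = len(resid)
        const = -0.5 * (n * np.log(2 * np.pi) + 2 * np.sum(np.log(np.diag(La))))
        grids = np.meshgrid(*([x] * d), indexing="ij")
        pts = np.stack([g.ravel() for g in grids])  # (d, n_nodes**d)
        wgrids = np.meshgrid(*([np.log(w)] * d), indexing="ij")
        logw = np.sum([g.ravel() for g in wgrids], axis=0)
        nu = Lp @ (np.sqrt(2.0) * pts)
        E = rw[:, None] - Zw @ nu
        ll = const - 0.5 * np.sum(E * E, axis=0)
        total += logsumexp(ll + logw) - 0.5 * d * np.log(np.pi)
    return -2.0 * total
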