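"""Profiled maximum-likelihood fitting of small linear mixed models.

The per-biomarker variants need only a subject random intercept or an
intercept plus age slope, so the random-effects covariance has 1 or 3 free
parameters.  Writing the covariance as sigma^2 * Psi with Psi = L L'
(L lower-triangular), the fixed effects beta and the residual variance
sigma^2 have closed-form GLS/ML solutions given Psi, leaving a 1-3
dimensional profiled log-likelihood that is optimized directly.  Group
(subject) blocks of equal size are batched, so each likelihood evaluation is
a handful of stacked small-matrix solves.

The boundary Psi -> 0 is an ordinary interior point of the L
parameterization (L = 0), so variance components estimated at zero are
handled without special casing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass
class LMMFit:
    beta: np.ndarray
    cov_re: np.ndarray  # random-effects covariance, natural units
    sigma2: float  # residual variance
    llf: float
    converged: bool
    n_iter: int
    history: list[float]


def _group_blocks(groups: np.ndarray):
    """Row-index blocks per group, batched by group size."""
    order = np.argsort(groups, kind="stable")
    sorted_groups = np.asarray(groups)[order]
    boundaries = np.flatnonzero(
        np.r_[True, sorted_groups[1:] != sorted_groups[:-1], True]
    )
    blocks = [order[a:b] for a, b in zip(boundaries[:-1], boundaries[1:])]
    by_size: dict[int, list[np.ndarray]] = {}
    for blk in blocks:
        by_size.setdefault(len(blk), []).append(blk)
    return {m: np.stack(idx) for m, idx in by_size.items()}


def _theta_to_L(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = theta
    return L


def profile_ml(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    groups: np.ndarray,
    tol: float = 1e-8,
    maxiter: int = 200,
) -> LMMFit:
    """ML fit of y = X beta + Z_g b_g + e, b_g ~ N(0, sigma^2 Psi).

    ``Z`` holds the random-effects design columns (q = 1 or 2).  Convergence
    is declared when the relative profiled log-likelihood change over a
    simplex iteration falls below ``tol``; non-convergence raises with the
    log-likelihood trajectory attached.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Z = np.asarray(Z, float)
    n, p = X.shape
    q = Z.shape[1]
    batches = _group_blocks(np.asarray(groups))
    pre = {
        m: (y[idx], X[idx], Z[idx], np.eye(m)) for m, idx in batches.items()
    }

    def nll_and_fit(theta: np.ndarray):
        L = _theta_to_L(theta, q)
        psi = L @ L.T
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        logdet = 0.0
        solves = {}
        for m, (Y, Xg, Zg, Im) in pre.items():
            V = Zg @ psi @ Zg.transpose(0, 2, 1) + Im
            C = np.linalg.cholesky(V)
            logdet += 2.0 * np.log(np.diagonal(C, axis1=1, axis2=2)).sum()
            ViX = np.linalg.solve(V, Xg)
            Viy = np.linalg.solve(V, Y[..., None])[..., 0]
            XtVX += np.einsum("gmp,gmq->pq", Xg, ViX)
            XtVy += np.einsum("gmp,gm->p", Xg, Viy)
            solves[m] = V
        beta = np.linalg.solve(XtVX, XtVy)
        quad = 0.0
        for m, (Y, Xg, _, _) in pre.items():
            r = Y - Xg @ beta
            quad += np.einsum("gm,gm->", r, np.linalg.solve(solves[m], r[..., None])[..., 0])
        sigma2 = max(quad / n, 1e-300)
        ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
        return -ll, beta, sigma2, psi

    def nll(theta):
        return nll_and_fit(theta)[0]

    n_free = q * (q + 1) // 2
    starts = [np.full(n_free, 0.0), np.full(n_free, 0.3)]
    if q == 2:
        starts.append(np.array([0.3, 0.0, 0.02]))
    best = None
    history: list[float] = []
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0,
            method="Nelder-Mead",
            options={
                "maxiter": maxiter * max(n_free, 1),
                "fatol": tol * max(1.0, abs(nll(x0))),
                "xatol": 1e-8,
            },
        )
        history.append(-res.fun)
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError(
            f"mixed-model profiled likelihood diverged; trajectory: {history}"
        )
    if not best.success and best.nit >= maxiter * max(n_free, 1):
        raise RuntimeError(
            "mixed-model fit did not converge within "
            f"{maxiter} iterations; log-likelihood trajectory: {history}"
        )
    neg_ll, beta, sigma2, psi = nll_and_fit(best.x)
    return LMMFit(
        beta=beta,
        cov_re=sigma2 * psi,
        sigma2=sigma2,
        llf=-neg_ll,
        converged=bool(best.success),
        n_iter=int(best.nit),
        history=history,
    )
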