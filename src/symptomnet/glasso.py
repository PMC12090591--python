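"""L1-penalized sparse precision estimation (graphical lasso) with EBIC.

The solver is the standard block coordinate-descent formulation: cycle over
nodes, solve an L1-penalized regression of each node on the rest against the
current working covariance, and update the corresponding row/column.  The
objective maximized is

    log det K - trace(S K) - lambda * sum_{i != j} |k_ij|

with the diagonal unpenalized.  Convergence is declared when the largest
absolute change in the working covariance W between full sweeps drops below
``tol``.  Inner coordinate descent maintains residuals incrementally, so a
sweep costs O(p^2) and whole-path fits with warm starts are cheap enough to
sit inside bootstrap loops.

Model selection uses the extended BIC: with E the number of nonzero
upper-triangle off-diagonals of K and L = (n/2)[log det K - trace(S K)],

    EBIC_gamma = -2 L + E log n + 4 E gamma log p.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit


class GlassoConvergenceError(RuntimeError):
    """Raised when coordinate descent fails to reach ``tol`` in ``max_iter`` sweeps."""

    def __init__(self, lam: float, residual: float, max_iter: int):
        self.lam = lam
        self.residual = residual
        super().__init__(
            f"graphical lasso did not converge at lambda={lam:.6g} after "
            f"{max_iter} sweeps (last max |dW| = {residual:.3g})"
        )


@njit(cache=False)
def _glasso_cd(S, lam, tol, max_iter, B):  # pragma: no cover - jitted
    """Block coordinate descent; returns (W, K, sweeps, last max |dW|).

    ``B`` is the (p, p) matrix of regression coefficients, column j holding
    node j's lasso coefficients (entry j unused, kept at 0); passing a
    previous solution warm-starts the fit and ``B`` is updated in place.
    """
    p = S.shape[0]
    W = S.copy()
    # rebuild W off-diagonals from the warm-start coefficients
    for j in range(p):
        for k in range(p):
            if k == j:
                continue
            val = 0.0
            for l in range(p):
                if l != j:
                    val += W[k, l] * B[l, j]
            W[k, j] = val
            W[j, k] = val
    inner_tol = tol * 0.1
    max_delta = 0.0
    sweeps = 0
    c = np.empty(p)
    for sweep in range(max_iter):
        sweeps = sweep + 1
        max_delta = 0.0
        for j in range(p):
            # residuals c_k = s_kj - sum_{l != j,k} W_kl B_lj
            for k in range(p):
                acc = S[k, j]
                for l in range(p):
                    if l != j and l != k:
                        acc -= W[k, l] * B[l, j]
                c[k] = acc
            for _ in range(1000):
                inner_delta = 0.0
                for k in range(p):
                    if k == j:
                        continue
                    r = c[k]
                    if r > lam:
                        bnew = (r - lam) / W[k, k]
                    elif r < -lam:
                        bnew = (r + lam) / W[k, k]
                    else:
                        bnew = 0.0
                    d = bnew - B[k, j]
                    if d != 0.0:
                        B[k, j] = bnew
                        for l in range(p):
                            if l != j and l != k:
                                c[l] -= W[l, k] * d
                        ad = abs(d)
                        if ad > inner_delta:
                            inner_delta = ad
                if inner_delta < inner_tol:
                    break
            # w12 = W11 @ beta
            for k in range(p):
                if k == j:
                    continue
                val = 0.0
                for l in range(p):
                    if l != j:
                        val += W[k, l] * B[l, j]
                d = abs(val - W[k, j])
                if d > max_delta:
                    max_delta = d
                W[k, j] = val
                W[j, k] = val
        if max_delta < tol:
            break
    # precision from the regression coefficients
    K = np.zeros((p, p))
    for j in range(p):
        s = 0.0
        for l in range(p):
            if l != j:
                s += W[l, j] * B[l, j]
        kjj = 1.0 / (W[j, j] - s)
        K[j, j] = kjj
        for k in range(p):
            if k != j:
                K[k, j] = -B[k, j] * kjj
    # symmetrize, preserving exact zeros in the common support
    for i in range(p):
        for j in range(i + 1, p):
            if K[i, j] == 0.0 and K[j, i] == 0.0:
                continue
            v = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = v
            K[j, i] = v
    return W, K, sweeps, max_delta


@dataclass
class GlassoFit:
    """One penalized fit: precision K, working covariance W, and diagnostics."""

    precision: np.ndarray
    covariance: np.ndarray
    lam: float
    loglik: float  # log det K - trace(S K), the unpenalized likelihood kernel
    iterations: int
    converged: bool
    ebic: float | None = None
    coefficients: np.ndarray | None = field(default=None, repr=False)

    @property
    def edge_count(self) -> int:
        p = self.precision.shape[0]
        iu = np.triu_indices(p, k=1)
        return int(np.count_nonzero(self.precision[iu]))


def glasso_fit(
    S: np.ndarray,
    lam: float,
    tol: float = 1e-7,
    max_iter: int = 10_000,
    warm_start: np.ndarray | None = None,
) -> GlassoFit:
    """Fit the graphical lasso at one penalty value.

    ``S`` is a correlation (or covariance) matrix, positive semidefinite
    after any repair; ``warm_start`` optionally carries the coefficient
    matrix of a previous fit (it is copied, not mutated).
    """
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("S must be square")
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    p = S.shape[0]
    B = np.zeros((p, p)) if warm_start is None else np.ascontiguousarray(warm_start, dtype=float).copy()
    W, K, sweeps, residual = _glasso_cd(np.ascontiguousarray(S), float(lam), float(tol), int(max_iter), B)
    converged = residual < tol or sweeps < max_iter
    if not converged:
        raise GlassoConvergenceError(lam, residual, max_iter)
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        raise GlassoConvergenceError(lam, residual, max_iter)
    loglik = float(logdet - np.trace(S @ K))
    return GlassoFit(K, W, float(lam), loglik, sweeps, True, coefficients=B)


def ebic_score(fit: GlassoFit, n: int, gamma: float = 0.5) -> float:
    """Extended BIC of a converged fit; lower is better."""
    if n < 2:
        raise ValueError("need n >= 2")
    if not fit.converged:
        raise ValueError("fit did not converge")
    sign, logdet = np.linalg.slogdet(fit.precision)
    if sign <= 0 or not np.isfinite(logdet):
        raise ValueError("singular precision estimate")
    E = fit.edge_count
    p = fit.precision.shape[0]
    score = -n * fit.loglik + E * np.log(n) + 4.0 * E * gamma * np.log(p)
    if not np.isfinite(score):
        raise ValueError("EBIC is not finite")
    return float(score)


def lambda_path(S: np.ndarray, n_lambda: int = 100, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced descending penalty path from lambda_max = max off-diag |s|."""
    if n_lambda < 2:
        raise ValueError("need at least two path points")
    if not (0 < min_ratio < 1):
        raise ValueError("min_ratio must lie in (0, 1)")
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    off = np.abs(S[np.triu_indices(p, k=1)])
    lam_max = float(off.max()) if off.size else 0.0
    if lam_max <= 0:
        raise ValueError("all off-diagonal correlations are zero; degenerate path")
    return np.geomspace(lam_max, min_ratio * lam_max, n_lambda)
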