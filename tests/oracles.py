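"""Independent slow oracles used by the test suite.

Everything here is deliberately written from first principles (exhaustive
enumeration, proximal gradient on the raw objective) and shares no code
with the package implementation it checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

TIE_EPS = 1e-9


def glasso_objective(K: np.ndarray, S: np.ndarray, lam: float) -> float:
    """Penalized log-likelihood: log det K - tr(SK) - lam * sum_offdiag |k_ij|."""
    sign, logdet = np.linalg.slogdet(K)
    if sign <= 0:
        return -np.inf
    offdiag = np.abs(K).sum() - np.abs(np.diag(K)).sum()
    return float(logdet - np.trace(S @ K) - lam * offdiag)


def slow_glasso(S: np.ndarray, lam: float, n_starts: int = 10, seed: int = 0,
                iters: int = 20000) -> tuple[np.ndarray, float]:
    """Proximal-gradient (ISTA) maximizer of the penalized likelihood.

    Dense, slow, and independent of the coordinate-descent implementation;
    returns the best (K, objective) over random symmetric PD starts.
    """
    p = S.shape[0]
    rng = np.random.default_rng(seed)
    best_obj, best_K = -np.inf, None
    for start in range(n_starts):
        if start == 0:
            K = np.eye(p)
        else:
            A = rng.normal(size=(p, p)) * 0.3
            K = np.eye(p) + 0.5 * (A + A.T)
            w = np.linalg.eigvalsh(K)
            if w.min() < 0.1:
                K += (0.1 - w.min()) * np.eye(p)
        t = 0.1
        obj = glasso_objective(K, S, lam)
        for _ in range(iters):
            grad = np.linalg.inv(K) - S  # ascent direction of smooth part
            while True:
                step = K + t * grad
                new = np.sign(step) * np.maximum(np.abs(step) - t * lam, 0.0)
                ii = np.arange(p)
                new[ii, ii] = step[ii, ii]  # diagonal unpenalized
                new = 0.5 * (new + new.T)
                new_obj = glasso_objective(new, S, lam)
                if np.isfinite(new_obj):
                    break
                t *= 0.5
            if new_obj < obj - 1e-13:
                t *= 0.5
                if t < 1e-12:
                    break
                continue
            moved = np.abs(new - K).max()
            K, obj = new, new_obj
            if moved < 1e-12:
                break
        if obj > best_obj:
            best_obj, best_K = obj, K
    return best_K, best_obj


def two_node_glasso(s12: float, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form two-node solution: soft-threshold the off-diagonal of W."""
    w12 = np.sign(s12) * max(abs(s12) - lam, 0.0)
    W = np.array([[1.0, w12], [w12, 1.0]])
    K = np.linalg.inv(W)
    if w12 == 0.0:
        K = np.diag(np.diag(K))
    return W, K


def enumerate_simple_paths(weights: np.ndarray, s: int, t: int):
    """All simple s-t paths with their 1/|w| lengths (exhaustive)."""
    p = weights.shape[0]
    others = [v for v in range(p) if v not in (s, t)]
    with np.errstate(divide="ignore"):
        length = np.where(weights != 0, 1.0 / np.abs(weights), np.inf)
    for k in range(len(others) + 1):
        for mid in permutations(others, k):
            path = (s, *mid, t)
            L = sum(length[path[i], path[i + 1]] for i in range(len(path) - 1))
            if np.isfinite(L):
                yield path, L


def brute_distances(weights: np.ndarray) -> np.ndarray:
    p = weights.shape[0]
    d = np.zeros((p, p))
    for s in range(p):
        for t in range(s + 1, p):
            best = np.inf
            for _, L in enumerate_simple_paths(weights, s, t):
                best = min(best, L)
            d[s, t] = d[t, s] = best
    return d


def brute_closeness(weights: np.ndarray) -> np.ndarray:
    d = brute_distances(weights)
    p = weights.shape[0]
    out = np.zeros(p)
    for i in range(p):
        tot = sum(d[i, j] for j in range(p) if j != i)
        if np.isfinite(tot) and tot > 0:
            out[i] = 1.0 / tot
    return out


def brute_betweenness(weights: np.ndarray) -> np.ndarray:
    """Fractional-credit betweenness over unordered pairs, by enumeration."""
    p = weights.shape[0]
    out = np.zeros(p)
    for s in range(p):
        for t in range(s + 1, p):
            paths = list(enumerate_simple_paths(weights, s, t))
            if not paths:
                continue
            best = min(L for _, L in paths)
            shortest = [path for path, L in paths if L <= best + TIE_EPS]
            if not np.isfinite(best):
                continue
            for v in range(p):
                if v in (s, t):
                    continue
                through = sum(1 for path in shortest if v in path)
                out[v] += through / len(shortest)
    return out
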