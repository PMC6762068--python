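"""Independent reference implementations used only as test oracles.

These deliberately avoid the package's own code paths: the dual QP is
solved by a generic constrained optimizer (SLSQP) with an
equality-constrained Newton polish, the sinusoid frequency by a dense grid
search with per-frequency linear least squares, and the rank-sum p-value by
complete enumeration of rank assignments.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist


def qp_dual_solution(X: np.ndarray, nu: float, gamma: float) -> tuple[np.ndarray, float]:
    """Solve min 1/2 a'Ka  s.t.  0 <= a <= 1/(nu l), sum a = 1 generically.

    SLSQP provides the active set; a KKT linear solve on the free
    coordinates then polishes the solution to machine precision.
    Returns (alpha, objective).
    """
    X = np.asarray(X, dtype=float)
    l = X.shape[0]
    C = 1.0 / (nu * l)
    K = np.exp(-gamma * cdist(X, X, "sqeuclidean"))

    def objective(a):
        return 0.5 * a @ K @ a

    def gradient(a):
        return K @ a

    a0 = np.full(l, 1.0 / l)
    result = minimize(
        objective,
        a0,
        jac=gradient,
        method="SLSQP",
        bounds=[(0.0, C)] * l,
        constraints=[{"type": "eq", "fun": lambda a: np.sum(a) - 1.0,
                      "jac": lambda a: np.ones(l)}],
        options={"maxiter": 2000, "ftol": 1e-14},
    )
    alpha = np.clip(result.x, 0.0, C)

    # polish: fix coordinates at their bounds, solve the equality-constrained
    # QP exactly on the free set via its KKT system
    for _ in range(50):
        band = 1e-7 * C
        free = (alpha > band) & (alpha < C - band)
        if not np.any(free):
            break
        at_c = alpha >= C - band
        nf = int(np.sum(free))
        rhs_lin = -(K[np.ix_(free, at_c)] @ np.full(int(np.sum(at_c)), C)) if np.any(at_c) else np.zeros(nf)
        kkt = np.zeros((nf + 1, nf + 1))
        kkt[:nf, :nf] = K[np.ix_(free, free)]
        kkt[:nf, nf] = 1.0
        kkt[nf, :nf] = 1.0
        rhs = np.concatenate([rhs_lin, [1.0 - C * np.sum(at_c)]])
        try:
            sol = np.linalg.solve(kkt, rhs)
        except np.linalg.LinAlgError:
            sol = np.linalg.lstsq(kkt, rhs, rcond=None)[0]
        new_free = np.clip(sol[:nf], 0.0, C)
        new_alpha = alpha.copy()
        new_alpha[free] = new_free
        if objective(new_alpha) <= objective(alpha) + 1e-15:
            if np.allclose(new_alpha, alpha, atol=1e-14):
                alpha = new_alpha
                break
            alpha = new_alpha
        else:
            break
    # renormalize the residual constraint drift onto the free set
    drift = 1.0 - np.sum(alpha)
    free = (alpha > 1e-7 * C) & (alpha < C * (1 - 1e-7))
    if np.any(free) and abs(drift) > 0:
        alpha[free] += drift / np.sum(free)
        alpha = np.clip(alpha, 0.0, C)
    return alpha, float(objective(alpha))


def grid_search_frequency(
    times: np.ndarray,
    values: np.ndarray,
    f_lo: float,
    f_hi: float,
    n_grid: int = 20001,
) -> float:
    """Best-fit frequency by dense search with linear LSQ for (A, phi, b).

    For each f the model a sin(2 pi f t) + c cos(2 pi f t) + b is linear.
    """
    best_f, best_sse = None, math.inf
    for f in np.linspace(f_lo, f_hi, n_grid):
        w = 2.0 * math.pi * f
        design = np.column_stack([np.sin(w * times), np.cos(w * times), np.ones_like(times)])
        coef, *_ = np.linalg.lstsq(design, values, rcond=None)
        sse = float(np.sum((design @ coef - values) ** 2))
        if sse < best_sse:
            best_f, best_sse = float(f), sse
    return best_f


def exact_rank_sum_p_greater(x, y) -> float:
    """One-sided rank-sum p-value P(W >= w_obs) by complete enumeration.

    Assumes no ties.  W is the rank sum of sample x within the pooled
    ranking; all C(n+m, n) assignments are equally likely under the null.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    assert np.unique(pooled).size == pooled.size, "oracle requires no ties"
    ranks = np.argsort(np.argsort(pooled)) + 1
    w_obs = float(np.sum(ranks[: x.size]))
    n_total = pooled.size
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, n_total + 1), x.size):
        total += 1
        if sum(combo) >= w_obs - 1e-9:
            count += 1
    return count / total
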