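"""One-class support vector machine, implemented from the dual formulation.

Training solves

    min_alpha  1/2 sum_ij alpha_i alpha_j k(x_i, x_j)
    s.t.       0 <= alpha_i <= 1/(nu l),   sum_i alpha_i = 1

with a Gaussian RBF kernel ``k(x, y) = exp(-gamma ||x - y||^2)`` by
pairwise coordinate ascent (SMO with a working set of size two, as
required by the equality constraint), selecting the maximally
KKT-violating pair each iteration.  The decision function is

    f(x) = sum_i alpha_i k(x_i, x) - rho

with the bias ``rho`` taken as the mean of ``(K alpha)_i`` over margin
support vectors (those strictly inside the box).  A decision value of zero
counts as inlier; because margin support vectors sit at exactly zero up to
roundoff, the inlier rule uses a small guard (``BOUNDARY_TOL``) so that
re-evaluating the kernel expansion cannot flip them to outliers.

No ML library is involved; correctness is cross-checked in the test suite
against a generic quadratic-programming solver on the same dual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .errors import InputError, ParameterError, TrainingError
from .preprocess import SLICING_ANCHOR, FeatureMatrix, Scaler

#: Floor for the on-boundary inlier guard; the effective guard is the
#: model's training tolerance (margin SVs sit within ~tol of zero).
BOUNDARY_TOL = 1e-9


def rbf_kernel(x, y, gamma: float) -> float:
    """``exp(-gamma ||x - y||^2)`` for two feature rows."""
    if gamma <= 0:
        raise ParameterError("gamma must be > 0")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise InputError(f"dimension mismatch: {x.shape} vs {y.shape}")
    d2 = float(np.dot(x - y, x - y))
    return math.exp(-gamma * d2)


def kernel_matrix(X, Y, gamma: float) -> np.ndarray:
    """Dense RBF Gram matrix between row sets X (n x d) and Y (m x d)."""
    if gamma <= 0:
        raise ParameterError("gamma must be > 0")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != Y.shape[1]:
        raise InputError(
            f"dimension mismatch: {X.shape[1]} vs {Y.shape[1]} features"
        )
    return np.exp(-gamma * cdist(X, Y, "sqeuclidean"))


@dataclass
class OneClassSvmModel:
    """Trained boundary: support vectors, dual coefficients and bias."""

    support_vectors: np.ndarray  # (n_sv, d)
    alphas: np.ndarray  # (n_sv,) dual coefficients, each in (0, 1/(nu l)]
    rho: float
    gamma: float
    nu: float
    l: int  # training-set size
    training_score: float = math.nan
    dual_objective: float = math.nan
    n_iterations: int = 0
    kkt_violation: float = math.nan
    boundary_tol: float = 1e-6  # inlier guard width, set from training tol
    scaler: Scaler | None = None
    columns: tuple[str, ...] | None = None
    slicing_anchor: str = SLICING_ANCHOR

    @property
    def n_support_vectors(self) -> int:
        return int(self.alphas.size)

    @property
    def n_features(self) -> int:
        return int(self.support_vectors.shape[1])

    def decision_function(self, X) -> np.ndarray | float:
        return decision_function(self, X)

    def predict(self, X) -> np.ndarray | int:
        return predict(self, X)

    def score(self, features) -> float:
        return score(self, features)


def _as_rows(features) -> np.ndarray:
    if isinstance(features, FeatureMatrix):
        return features.Z
    return np.asarray(features, dtype=float)


def train(
    features,
    nu: float,
    gamma: float,
    tol: float = 1e-6,
    max_iterations: int | None = None,
) -> OneClassSvmModel:
    """Train on standardized feature rows (``FeatureMatrix`` or array).

    ``nu`` bounds the training outlier fraction from above and the
    support-vector fraction from below; ``gamma`` is the RBF width.
    Convergence: maximal first-order KKT violation below ``tol``.
    """
    X = _as_rows(features)
    if X.ndim != 2 or X.shape[0] == 0:
        raise InputError("training features must be a non-empty 2-D row matrix")
    l = X.shape[0]
    if not 0 < nu <= 1:
        raise ParameterError(f"nu must be in (0, 1], got {nu}")
    if gamma <= 0:
        raise ParameterError(f"gamma must be > 0, got {gamma}")
    if l < math.ceil(1.0 / nu):
        raise ParameterError(
            f"infeasible: need at least ceil(1/nu) = {math.ceil(1.0 / nu)} "
            f"training rows for nu={nu}, got {l}"
        )
    if max_iterations is None:
        max_iterations = max(20_000, 200 * l)

    C = 1.0 / (nu * l)
    K = kernel_matrix(X, X, gamma)

    # feasible start: fill the box from the front, remainder on the next slot
    alpha = np.zeros(l)
    n_full = int(nu * l)
    alpha[:n_full] = C
    if n_full < l:
        alpha[n_full] = 1.0 - n_full * C
    g = K @ alpha  # gradient of the dual objective

    violation = math.inf
    it = 0
    for it in range(1, max_iterations + 1):
        up = alpha < C * (1.0 - 1e-12)  # can grow
        down = alpha > C * 1e-12  # can shrink
        gi_candidates = np.where(up, g, math.inf)
        gj_candidates = np.where(down, g, -math.inf)
        i = int(np.argmin(gi_candidates))
        j = int(np.argmax(gj_candidates))
        violation = g[j] - g[i]
        if violation < tol:
            break
        eta = K[i, i] + K[j, j] - 2.0 * K[i, j]
        if eta > 1e-15:
            delta = violation / eta
        else:
            delta = C  # flat direction: move to a bound
        delta = min(delta, C - alpha[i], alpha[j])
        alpha[i] += delta
        alpha[j] -= delta
        g += delta * (K[:, i] - K[:, j])
    else:
        raise TrainingError(
            f"SMO did not converge in {max_iterations} iterations "
            f"(last KKT violation {violation:.3g})",
            n_iterations=max_iterations,
        )

    sv_threshold = C * 1e-8
    sv_mask = alpha > sv_threshold
    guard = max(tol, C * 1e-6)
    margin_mask = (alpha > guard) & (alpha < C - guard)
    if np.any(margin_mask):
        rho = float(np.mean(g[margin_mask]))
    else:
        # KKT interval: [max g over alpha at the box, min g over alpha at 0]
        lower = g[alpha >= C - guard]
        upper = g[alpha <= guard]
        lo = float(np.max(lower)) if lower.size else float(np.min(g))
        hi = float(np.min(upper)) if upper.size else float(np.max(g))
        rho = 0.5 * (lo + hi)

    model = OneClassSvmModel(
        support_vectors=X[sv_mask].copy(),
        alphas=alpha[sv_mask].copy(),
        rho=rho,
        gamma=gamma,
        nu=nu,
        l=l,
        dual_objective=0.5 * float(alpha @ g),
        n_iterations=it,
        kkt_violation=float(max(violation, 0.0)),
        boundary_tol=max(BOUNDARY_TOL, tol),
    )
    if isinstance(features, FeatureMatrix):
        model.scaler = features.scaler
        model.columns = features.columns
    model.training_score = score(model, X)
    return model


def decision_function(model: OneClassSvmModel, X) -> np.ndarray | float:
    """Pre-sign margin ``sum_i alpha_i k(x_i, x) - rho``; positive = inlier."""
    rows = _as_rows(X)
    single = rows.ndim == 1
    rows = np.atleast_2d(rows)
    if rows.shape[1] != model.n_features:
        raise InputError(
            f"dimension mismatch: model has {model.n_features} features, "
            f"input has {rows.shape[1]}"
        )
    values = kernel_matrix(rows, model.support_vectors, model.gamma) @ model.alphas - model.rho
    return float(values[0]) if single else values


def predict(model: OneClassSvmModel, X) -> np.ndarray | int:
    """+1 inlier / -1 outlier.

    Zero margin counts as inlier; the boundary is widened by the roundoff
    guard ``BOUNDARY_TOL`` so margin support vectors classify as inliers
    deterministically.
    """
    guard = model.boundary_tol
    values = decision_function(model, X)
    if np.isscalar(values):
        return 1 if values >= -guard else -1
    return np.where(values >= -guard, 1, -1)


def score(model: OneClassSvmModel, features) -> float:
    """Fraction of rows predicted inlier, in [0, 1]."""
    rows = _as_rows(features)
    rows = np.atleast_2d(rows)
    if rows.shape[0] == 0:
        raise InputError("cannot score an empty feature set")
    values = decision_function(model, rows)
    return float(np.mean(values >= -model.boundary_tol))
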