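"""Model Compliance Index (MCI) diagnostics.

MCI = N_inliers / N_samples for one recording scored against the baseline
model; 1 means full agreement with the healthy-valve baseline.  This module
also summarizes scenarios (median / IQR), runs the (nu, gamma) grid search
whose objective is the baseline-vs-regurgitation MCI separation, compares
scenarios with a one-sided Wilcoxon rank-sum test, and tracks MCI over time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import ocsvm
from .errors import InputError, ParameterError
from .ocsvm import OneClassSvmModel
from .preprocess import FeatureMatrix, pool_features


def compute_mci(model: OneClassSvmModel, features) -> float:
    """Fraction of the recording's samples inside the decision boundary.

    Identical to the classifier score on the same rows by construction.
    """
    rows = features.Z if isinstance(features, FeatureMatrix) else np.asarray(features, dtype=float)
    rows = np.atleast_2d(rows)
    if rows.shape[0] == 0:
        raise InputError("cannot compute MCI for an empty feature set")
    n_inliers = int(np.sum(ocsvm.decision_function(model, rows) >= -model.boundary_tol))
    mci = n_inliers / rows.shape[0]
    assert mci == ocsvm.score(model, rows)
    return mci


@dataclass
class MciReport:
    """Per-recording MCI values for one scenario, with summary statistics."""

    scenario: str
    per_recording_mci: list[float]
    median: float
    iqr: float
    n_inliers: list[int] = field(default_factory=list)
    n_samples: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "per_recording_mci": list(self.per_recording_mci),
            "median": self.median,
            "iqr": self.iqr,
            "n_inliers": list(self.n_inliers),
            "n_samples": list(self.n_samples),
        }


def summarize_scenario(
    mcis,
    scenario: str = "",
    n_inliers=None,
    n_samples=None,
) -> MciReport:
    """Median (linear-interpolated percentile) and IQR (75th - 25th)."""
    values = [float(v) for v in mcis]
    if not values:
        raise InputError("need at least one MCI value")
    arr = np.asarray(values)
    q25, q50, q75 = np.percentile(arr, [25.0, 50.0, 75.0], method="linear")
    return MciReport(
        scenario=scenario,
        per_recording_mci=values,
        median=float(q50),
        iqr=float(q75 - q25),
        n_inliers=list(n_inliers) if n_inliers is not None else [],
        n_samples=list(n_samples) if n_samples is not None else [],
    )


def score_scenario(
    model: OneClassSvmModel,
    feature_sets: list[FeatureMatrix],
    scenario: str = "",
) -> MciReport:
    """Score each recording's features against the model and summarize."""
    if not feature_sets:
        raise InputError("need at least one recording")
    mcis, inliers, totals = [], [], []
    for fm in feature_sets:
        n = len(fm)
        mci = compute_mci(model, fm)
        mcis.append(mci)
        inliers.append(round(mci * n))
        totals.append(n)
    return summarize_scenario(mcis, scenario, n_inliers=inliers, n_samples=totals)


@dataclass
class GridSearchResult:
    nu_grid: list[float]
    gamma_grid: list[float]
    sensitivity: np.ndarray  # |nu_grid| x |gamma_grid|
    best_nu: float
    best_gamma: float
    best_sensitivity: float


#: Grids spanning the hard/soft-margin and regularization regimes around the
#: operating point (nu=0.05, gamma=7).
DEFAULT_NU_GRID = (0.01, 0.05, 0.1, 0.2)
DEFAULT_GAMMA_GRID = (0.1, 1.0, 7.0, 20.0, 100.0)


def grid_search(
    baseline_features: list[FeatureMatrix],
    ar_features: list[FeatureMatrix],
    nu_grid=DEFAULT_NU_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    tol: float = 1e-6,
) -> GridSearchResult:
    """Sensitivity of the MCI to regurgitant flow over a (nu, gamma) grid.

    For each cell the model is trained on the pooled baseline rows;
    sensitivity is the mean baseline MCI minus the mean regurgitation MCI
    (higher = better separation).  Deterministic for fixed inputs.
    """
    nu_grid = [float(v) for v in nu_grid]
    gamma_grid = [float(v) for v in gamma_grid]
    if not nu_grid or not gamma_grid:
        raise ParameterError("nu_grid and gamma_grid must be non-empty")
    if len(baseline_features) < 2:
        raise InputError("need at least two baseline recordings")
    if len(ar_features) < 1:
        raise InputError("need at least one regurgitation recording")

    pooled = pool_features(baseline_features)
    sens = np.empty((len(nu_grid), len(gamma_grid)))
    for a, nu in enumerate(nu_grid):
        for b, gamma in enumerate(gamma_grid):
            model = ocsvm.train(pooled, nu=nu, gamma=gamma, tol=tol)
            base = np.mean([compute_mci(model, fm) for fm in baseline_features])
            ar = np.mean([compute_mci(model, fm) for fm in ar_features])
            sens[a, b] = base - ar
    a_best, b_best = np.unravel_index(int(np.argmax(sens)), sens.shape)
    return GridSearchResult(
        nu_grid=nu_grid,
        gamma_grid=gamma_grid,
        sensitivity=sens,
        best_nu=nu_grid[a_best],
        best_gamma=gamma_grid[b_best],
        best_sensitivity=float(sens[a_best, b_best]),
    )


@dataclass
class ComparisonResult:
    statistic: float
    p_value: float
    significant: bool
    alpha: float
    method: str  # "exact" or "asymptotic"


def compare_scenarios(a, b, alpha: float = 0.01) -> ComparisonResult:
    """One-sided Wilcoxon rank-sum (Mann-Whitney) test: alternative a > b.

    Exact null distribution when the combined sample is small (<= 20) and
    tie-free; tie-corrected normal approximation otherwise.
    """
    x = np.asarray(a.per_recording_mci if isinstance(a, MciReport) else a, dtype=float)
    y = np.asarray(b.per_recording_mci if isinstance(b, MciReport) else b, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InputError("need at least three recordings per scenario")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    method = "exact" if (not has_ties and combined.size <= 20) else "asymptotic"
    result = stats.mannwhitneyu(
        x, y, alternative="greater", method=method, use_continuity=True
    )
    p = float(result.pvalue)
    return ComparisonResult(
        statistic=float(result.statistic),
        p_value=p,
        significant=bool(p < alpha),
        alpha=alpha,
        method=method,
    )


@dataclass
class MonitorResult:
    timestamps: list[float]
    mci: list[float]
    slope: float  # MCI per unit timestamp, least-squares linear trend


def monitor(
    model: OneClassSvmModel,
    feature_sets: list[FeatureMatrix],
    timestamps=None,
) -> MonitorResult:
    """MCI time series over an ordered sequence of recordings."""
    if not feature_sets:
        raise InputError("need at least one recording to monitor")
    if timestamps is None:
        timestamps = list(range(len(feature_sets)))
    timestamps = [float(t) for t in timestamps]
    if len(timestamps) != len(feature_sets):
        raise InputError("timestamps and recordings must align")
    mcis = [compute_mci(model, fm) for fm in feature_sets]
    if len(mcis) >= 2 and np.ptp(timestamps) > 0:
        slope = float(np.polyfit(timestamps, mcis, 1)[0])
    else:
        slope = 0.0
    return MonitorResult(timestamps=timestamps, mci=mcis, slope=slope)
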