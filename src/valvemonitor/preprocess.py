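"""Condense a multi-beat recording into a standardized phase/flow cloud.

Pipeline: first-harmonic sinusoid fit (Levenberg-Marquardt) -> slice at the
fitted sinusoid's minima and wrap every sample onto one cycle via
``tau = (t - t0) mod T`` -> z-score standardization of the feature axes.

The slicing anchor is always the sinusoid *minimum* (cycle starts near the
flow minimum at end-diastole).  Training and scoring must share this
convention; it is recorded in serialized models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, InputError, StandardizationError
from .recording import FlowRecording

SLICING_ANCHOR = "minimum"

#: Feature column labels in fixed order.
COLUMNS_2D = ("Z1_phase", "Z2_flow")
COLUMNS_3D = ("Z1_phase", "Z2_flow", "Z3_heart_rate")


@dataclass
class SinusoidModel:
    """First harmonic ``A sin(2 pi f t + phi) + b`` in canonical form
    (A >= 0, phi in [0, 2 pi))."""

    amplitude: float
    frequency: float
    phase: float
    offset: float
    residual_norm: float = math.nan
    n_evaluations: int = 0
    converged: bool = True

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def evaluate(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.sin(
            2.0 * math.pi * self.frequency * t + self.phase
        ) + self.offset

    def first_minimum_after(self, t_start: float) -> float:
        """Time of the first sinusoid minimum at or after ``t_start``.

        Minima sit at ``2 pi f t + phi = 3 pi / 2 + 2 pi k``.
        """
        w = 2.0 * math.pi * self.frequency
        k = math.ceil((w * t_start + self.phase - 1.5 * math.pi) / (2.0 * math.pi) - 1e-12)
        return (1.5 * math.pi - self.phase + 2.0 * math.pi * k) / w


@dataclass
class CondensedCycle:
    """All samples of a recording wrapped onto a single cardiac cycle."""

    tau: np.ndarray  # per-sample phase, seconds in [0, T)
    flow: np.ndarray  # signal units, order preserved from the recording
    period: float  # seconds

    @property
    def heart_rate(self) -> float:
        return 60.0 / self.period


@dataclass
class Scaler:
    """Per-axis mean and standard deviation used for standardization."""

    mean: np.ndarray
    sd: np.ndarray
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.sd


@dataclass
class FeatureMatrix:
    """Standardized per-sample feature rows plus the scaler that made them."""

    Z: np.ndarray  # (n_samples, n_features)
    scaler: Scaler
    columns: tuple[str, ...] = COLUMNS_2D

    @property
    def n_features(self) -> int:
        return int(self.Z.shape[1])

    def __len__(self) -> int:
        return int(self.Z.shape[0])


def _spectral_peak_frequency(recording: FlowRecording) -> float:
    """Dominant nonzero-frequency bin of the recording's spectrum."""
    y = recording.values - np.mean(recording.values)
    spectrum = np.abs(np.fft.rfft(y))
    spectrum[0] = 0.0
    k = int(np.argmax(spectrum))
    if k == 0 or spectrum[k] == 0.0:
        raise FitError("no nonzero spectral peak: signal appears constant")
    return k * recording.sample_rate / recording.n_samples


def _canonicalize(params: np.ndarray) -> tuple[float, float, float, float]:
    a, f, phi, b = (float(v) for v in params)
    if f < 0:
        f, phi = -f, -phi  # sin(-x) = -sin(x): fold into amplitude sign
        a = -a
    if a < 0:
        a, phi = -a, phi + math.pi
    phi = phi % (2.0 * math.pi)
    return a, f, phi, b


def fit_sinusoid(
    recording: FlowRecording,
    initial_frequency: float | None = None,
    max_iterations: int = 2000,
) -> SinusoidModel:
    """Least-squares fit of ``A sin(2 pi f t + phi) + b``.

    Levenberg-Marquardt with restarts at four initial phases
    (0, pi/2, pi, 3pi/2) to escape the phase local minima of sinusoid
    fitting; the lowest-residual solution wins.  The initial frequency
    comes from the dominant spectral peak unless given.

    Raises
    ------
    FitError
        For a (near-)constant recording or non-convergence.
    InputError
        If the recording is shorter than two estimated periods.
    """
    t = recording.times
    y = recording.values
    sd = float(np.std(y))
    scale = max(1.0, float(np.max(np.abs(y))))
    if sd < 1e-12 * scale:
        raise FitError(
            "degenerate input: recording is constant (amplitude would be 0, "
            "phase undefined)",
            last_params=(0.0, math.nan, math.nan, float(np.mean(y))),
        )

    f0 = initial_frequency if initial_frequency is not None else _spectral_peak_frequency(recording)
    if f0 <= 0:
        raise FitError("initial frequency must be positive")
    if recording.duration < 2.0 / f0:
        raise InputError(
            f"recording spans {recording.duration:.3g} s, shorter than two "
            f"estimated periods at f0={f0:.3g} Hz"
        )

    a0 = math.sqrt(2.0) * sd
    b0 = float(np.mean(y))

    def residual(p):
        a, f, phi, b = p
        return a * np.sin(2.0 * math.pi * f * t + phi) + b - y

    best = None
    total_nfev = 0
    for phi0 in (0.0, 0.5 * math.pi, math.pi, 1.5 * math.pi):
        result = least_squares(
            residual,
            x0=[a0, f0, phi0, b0],
            method="lm",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=max_iterations,
        )
        total_nfev += result.nfev
        if best is None or result.cost < best.cost:
            best = result

    if best is None or not best.success:
        raise FitError(
            "sinusoid fit did not converge",
            last_params=tuple(best.x) if best is not None else None,
        )

    a, f, phi, b = _canonicalize(best.x)
    return SinusoidModel(
        amplitude=a,
        frequency=f,
        phase=phi,
        offset=b,
        residual_norm=float(np.linalg.norm(best.fun)),
        n_evaluations=total_nfev,
        converged=bool(best.success),
    )


def condense(recording: FlowRecording, fit: SinusoidModel) -> CondensedCycle:
    """Wrap every sample onto one cycle: ``tau = (t - t0) mod T``.

    ``t0`` is the first minimum of the fitted sinusoid at or after the
    recording start; the mod maps samples on both sides of ``t0``
    correctly, so no samples are dropped.
    """
    period = fit.period
    if recording.duration < 2.0 * period:
        raise InputError(
            f"recording spans {recording.duration:.3g} s, "
            f"shorter than two fitted periods ({period:.3g} s each)"
        )
    t0 = fit.first_minimum_after(float(recording.times[0]))
    tau = np.mod(recording.times - t0, period)
    return CondensedCycle(tau=tau, flow=recording.values.copy(), period=period)


def compute_scaler(X: np.ndarray, columns: tuple[str, ...]) -> Scaler:
    """Own-statistics scaler; errors on any zero-variance axis."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    scale = np.maximum(1.0, np.abs(mean))
    for j, s in enumerate(sd):
        if s < 1e-12 * scale[j]:
            raise StandardizationError(
                f"axis {columns[j]!r} has zero variance; cannot standardize"
            )
    return Scaler(mean=mean, sd=sd, columns=columns)


def standardize(
    cycle: CondensedCycle,
    scaler: Scaler | None = None,
    n_features: int = 2,
) -> FeatureMatrix:
    """Z-score the (phase, flow[, heart-rate]) axes.

    With ``scaler=None`` each axis is standardized by the recording's own
    statistics.  The three-feature variant needs an external scaler: heart
    rate is constant within one recording, so its statistics only exist
    across a set of recordings (see :func:`pooled_scaler`).
    """
    if n_features == 2:
        columns = COLUMNS_2D
        X = np.column_stack([cycle.tau, cycle.flow])
    elif n_features == 3:
        columns = COLUMNS_3D
        X = np.column_stack(
            [cycle.tau, cycle.flow, np.full_like(cycle.tau, cycle.heart_rate)]
        )
        if scaler is None:
            raise StandardizationError(
                "axis 'Z3_heart_rate' is constant within a recording; "
                "3-feature standardization needs an external scaler "
                "computed across recordings"
            )
    else:
        raise InputError(f"n_features must be 2 or 3, got {n_features}")

    if scaler is None:
        scaler = compute_scaler(X, columns)
    else:
        if len(scaler.mean) != X.shape[1]:
            raise InputError(
                f"external scaler has {len(scaler.mean)} axes, features have "
                f"{X.shape[1]}"
            )
        if np.any(scaler.sd <= 0):
            raise StandardizationError("external scaler has a non-positive sd axis")
    return FeatureMatrix(Z=scaler.transform(X), scaler=scaler, columns=columns)


def pooled_scaler(cycles: list[CondensedCycle], n_features: int = 3) -> Scaler:
    """Scaler computed over the pooled samples of several recordings.

    This is how the heart-rate axis obtains nonzero variance when pump rate
    differs between recordings.
    """
    if not cycles:
        raise InputError("need at least one condensed cycle")
    if n_features == 2:
        columns = COLUMNS_2D
        X = np.vstack([np.column_stack([c.tau, c.flow]) for c in cycles])
    else:
        columns = COLUMNS_3D
        X = np.vstack(
            [
                np.column_stack(
                    [c.tau, c.flow, np.full_like(c.tau, c.heart_rate)]
                )
                for c in cycles
            ]
        )
    return compute_scaler(X, columns)


def preprocess_recording(
    recording: FlowRecording,
    scaler: Scaler | None = None,
    n_features: int = 2,
    initial_frequency: float | None = None,
) -> FeatureMatrix:
    """Full per-recording chain: fit -> condense -> standardize."""
    fit = fit_sinusoid(recording, initial_frequency=initial_frequency)
    cycle = condense(recording, fit)
    return standardize(cycle, scaler=scaler, n_features=n_features)


def pool_features(feature_sets: list[FeatureMatrix]) -> FeatureMatrix:
    """Stack per-recording feature matrices into one training matrix.

    The pooled matrix keeps the first set's scaler for bookkeeping only;
    each constituent was standardized by its own recording.
    """
    if not feature_sets:
        raise InputError("need at least one feature matrix")
    cols = feature_sets[0].columns
    for fm in feature_sets[1:]:
        if fm.columns != cols:
            raise InputError("feature matrices have mismatching columns")
    Z = np.vstack([fm.Z for fm in feature_sets])
    return FeatureMatrix(Z=Z, scaler=feature_sets[0].scaler, columns=cols)
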