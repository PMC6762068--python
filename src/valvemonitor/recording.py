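"""The core time-series container shared by the simulator and the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Relative tolerance on sample spacing uniformity (fraction of the nominal dt).
UNIFORMITY_RTOL = 1e-3


@dataclass
class FlowRecording:
    """One uniformly sampled multi-beat flow-rate time series.

    Parameters
    ----------
    times
        Sample times in seconds, strictly increasing on a uniform grid.
    values
        Flow signal in ``units`` (ml/s or raw ADC counts).
    sample_rate
        Sampling frequency in Hz.
    units
        Label for the value axis.
    scenario
        Optional scenario label (e.g. ``"baseline"``, ``"severe-ar"``).
    meta
        Free-form metadata (simulator config, source path, ...).
    """

    times: np.ndarray
    values: np.ndarray
    sample_rate: float
    units: str = "ml/s"
    scenario: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValidationError("times and values must be one-dimensional")
        if self.times.size != self.values.size:
            raise ValidationError(
                f"times ({self.times.size}) and values ({self.values.size}) "
                "must have equal length"
            )
        if self.times.size < 2:
            raise ValidationError("a recording needs at least two samples")
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValidationError("times must be strictly increasing")
        nominal = 1.0 / self.sample_rate
        if np.max(np.abs(dt - nominal)) > UNIFORMITY_RTOL * nominal:
            raise ValidationError(
                "non-uniform sampling: spacing deviates from "
                f"1/sample_rate = {nominal:.6g} s by more than "
                f"{UNIFORMITY_RTOL:.0e} relative tolerance"
            )

    @property
    def n_samples(self) -> int:
        return int(self.values.size)

    @property
    def duration(self) -> float:
        """Span from first to last sample plus one sample period, seconds."""
        return float(self.times[-1] - self.times[0]) + 1.0 / self.sample_rate

    @classmethod
    def from_values(
        cls,
        values,
        sample_rate: float,
        t_start: float = 0.0,
        **kwargs,
    ) -> "FlowRecording":
        """Build a recording from values alone, reconstructing times as i/fs."""
        values = np.asarray(values, dtype=float)
        times = t_start + np.arange(values.size) / float(sample_rate)
        return cls(times=times, values=values, sample_rate=sample_rate, **kwargs)
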