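"""Synthetic pulsatile-flow generator.

Emulates an in-vitro aortic flow loop: each cardiac cycle consists of a
half-sine systolic ejection, a brief negative closure-reflux dip, and --
when a leak orifice is configured -- a constant diastolic regurgitant flow
given by the orifice equation

    Q_leak = C_d * A * sqrt(2 * dP / rho_blood)

with blood density 1060 kg/m^3.  Gaussian noise and optional ADC
quantization are applied last.  The systolic amplitude is normalized so
that a no-leak cycle has a time-average flow equal to the configured
cardiac output.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .recording import FlowRecording

BLOOD_DENSITY_KG_M3 = 1060.0
MMHG_TO_PA = 133.322387415

#: Leak areas (mm^2) used for the mild / moderate / severe regurgitation
#: scenarios, mirroring the tube-insert cross sections of the rig.
SCENARIO_LEAK_AREAS = {
    "baseline": 0.0,
    "mild": 10.0,
    "moderate": 31.4,
    "severe": 99.4,
}


def orifice_leak_flow(
    leak_area_mm2: float,
    pressure_mmhg: float,
    discharge_coefficient: float = 0.6,
) -> float:
    """Magnitude of the regurgitant orifice flow in ml/s.

    Standard sharp-edged orifice equation with blood density 1060 kg/m^3;
    a zero area gives exactly zero flow.
    """
    if leak_area_mm2 == 0.0:
        return 0.0
    area_m2 = leak_area_mm2 * 1e-6
    dp_pa = pressure_mmhg * MMHG_TO_PA
    v = math.sqrt(2.0 * dp_pa / BLOOD_DENSITY_KG_M3)
    return discharge_coefficient * area_m2 * v * 1e6  # m^3/s -> ml/s


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic flow recording.

    Defaults reproduce the resting physiological operating point of the
    flow rig: 5 l/min cardiac output, 60 BPM, 80 mmHg diastolic pressure,
    recordings of 1000 samples at 60 Hz.
    """

    heart_rate: float = 60.0  # beats/min
    cardiac_output: float = 5.0  # l/min
    systolic_fraction: float = 0.35
    leak_area: float = 0.0  # mm^2
    diastolic_pressure: float = 80.0  # mmHg
    discharge_coefficient: float = 0.6
    closure_reflux_volume: float = 3.0  # ml per beat
    closure_fraction: float = 0.08  # fraction of cycle taken by the dip
    noise_sd: float = 2.5  # signal units (ml/s)
    period_jitter_sd: float = 0.0  # s
    sample_rate: float = 60.0  # Hz
    n_samples: int = 1000
    adc_bits: int | None = None
    adc_gain: float | None = None  # counts per ml/s; auto when None
    adc_offset: float | None = None  # counts; auto (midscale) when None
    seed: int | None = None
    scenario: str | None = None

    def validate(self) -> None:
        if not self.heart_rate > 0:
            raise ConfigurationError("heart_rate must be > 0")
        if not self.cardiac_output > 0:
            raise ConfigurationError("cardiac_output must be > 0")
        if not 0 < self.systolic_fraction < 1 - self.closure_fraction:
            raise ConfigurationError(
                "systolic_fraction must lie in (0, 1 - closure_fraction)"
            )
        if self.leak_area < 0:
            raise ConfigurationError("leak_area must be >= 0")
        if self.diastolic_pressure < 0:
            raise ConfigurationError("diastolic_pressure must be >= 0")
        if not 0 < self.discharge_coefficient <= 1.5:
            raise ConfigurationError("discharge_coefficient must be in (0, 1.5]")
        if self.closure_reflux_volume < 0:
            raise ConfigurationError("closure_reflux_volume must be >= 0")
        if not 0 < self.closure_fraction < 0.5:
            raise ConfigurationError("closure_fraction must be in (0, 0.5)")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.period_jitter_sd < 0:
            raise ConfigurationError("period_jitter_sd must be >= 0")
        if not self.sample_rate > 0:
            raise ConfigurationError("sample_rate must be > 0")
        min_samples = 2 * self.sample_rate * 60.0 / self.heart_rate
        if self.n_samples < min_samples:
            raise ConfigurationError(
                f"n_samples must cover at least two cycles "
                f"(>= {math.ceil(min_samples)} at heart_rate={self.heart_rate})"
            )
        if self.adc_bits is not None and not 2 <= self.adc_bits <= 32:
            raise ConfigurationError("adc_bits must be in [2, 32] or None")

    # -- derived quantities -------------------------------------------------

    @property
    def period(self) -> float:
        """Nominal cardiac period in seconds."""
        return 60.0 / self.heart_rate

    @property
    def mean_flow(self) -> float:
        """Target no-leak cycle-average flow, ml/s."""
        return self.cardiac_output * 1000.0 / 60.0

    @property
    def systolic_amplitude(self) -> float:
        """Half-sine ejection peak, ml/s, normalized so the no-leak cycle
        mean (ejection minus closure reflux) equals the cardiac output."""
        t_sys = self.systolic_fraction * self.period
        ejected = self.mean_flow * self.period + self.closure_reflux_volume
        return ejected * math.pi / (2.0 * t_sys)

    @property
    def leak_flow(self) -> float:
        """Magnitude of the constant diastolic leak, ml/s."""
        return orifice_leak_flow(
            self.leak_area, self.diastolic_pressure, self.discharge_coefficient
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _cycle_waveform(tau: np.ndarray, period: float, config: SimulationConfig) -> np.ndarray:
    """Noise-free flow at in-cycle times ``tau`` (0 <= tau < period), ml/s."""
    t_sys = config.systolic_fraction * period
    t_clo = config.closure_fraction * period
    q = np.zeros_like(tau)

    systole = tau < t_sys
    q[systole] = config.systolic_amplitude * np.sin(np.pi * tau[systole] / t_sys)

    closing = (tau >= t_sys) & (tau < t_sys + t_clo)
    if config.closure_reflux_volume > 0:
        dip_amp = config.closure_reflux_volume * math.pi / (2.0 * t_clo)
        q[closing] -= dip_amp * np.sin(np.pi * (tau[closing] - t_sys) / t_clo)

    # leak acts whenever the valve should be closed
    q[~systole] -= config.leak_flow
    return q


def generate_recording(config: SimulationConfig) -> FlowRecording:
    """Generate one synthetic multi-beat recording.

    Deterministic for a fixed config (including ``seed``): two calls with
    the same arguments return bit-identical values.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    fs = config.sample_rate
    n = config.n_samples
    times = np.arange(n) / fs
    duration = n / fs
    t_nominal = config.period

    # cycle boundaries; jitter drawn per cycle, floor keeps periods sane
    starts = [0.0]
    periods = []
    while starts[-1] < duration:
        if config.period_jitter_sd > 0:
            p = t_nominal + rng.normal(0.0, config.period_jitter_sd)
            p = max(p, 0.5 * t_nominal)
        else:
            p = t_nominal
        periods.append(p)
        starts.append(starts[-1] + p)
    starts_arr = np.asarray(starts[:-1])
    periods_arr = np.asarray(periods)

    idx = np.searchsorted(starts_arr, times, side="right") - 1
    tau = times - starts_arr[idx]

    values = np.empty(n)
    for k in np.unique(idx):
        sel = idx == k
        values[sel] = _cycle_waveform(tau[sel], periods_arr[k], config)

    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, size=n)

    units = "ml/s"
    if config.adc_bits is not None:
        full_scale = 2**config.adc_bits - 1
        gain = config.adc_gain
        if gain is None:
            # auto gain: +/- 1.2x systolic peak spans the full range
            gain = full_scale / (2.4 * config.systolic_amplitude)
        offset = config.adc_offset
        if offset is None:
            offset = 0.5 * full_scale
        values = np.clip(np.rint(gain * values + offset), 0, full_scale)
        units = "counts"

    return FlowRecording(
        times=times,
        values=values,
        sample_rate=fs,
        units=units,
        scenario=config.scenario,
        meta={"config": config.to_dict()},
    )


def generate_batch(
    config: SimulationConfig, n_recordings: int, seed: int | None = None
) -> list[FlowRecording]:
    """Generate ``n_recordings`` independent recordings from one config.

    Per-recording seeds are spawned from ``seed`` (falling back to
    ``config.seed``) so the batch is reproducible as a whole.
    """
    if n_recordings < 1:
        raise ConfigurationError("n_recordings must be >= 1")
    root = seed if seed is not None else config.seed
    children = np.random.SeedSequence(root).spawn(n_recordings)
    out = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0])
        cfg = dataclasses.replace(config, seed=sub_seed)
        rec = generate_recording(cfg)
        rec.meta["recording_index"] = i
        out.append(rec)
    return out
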