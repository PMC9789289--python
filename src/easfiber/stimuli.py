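"""Electric pulse waveforms and acoustic stimulus descriptors.

Electric stimuli are sampled current traces in mA on a fixed time grid.
By convention cathodic current is represented by **negative** sample
values; with the polarity weighting of the two-neuron model this makes a
cathodic pulse depolarize the peripheral neuron, as observed
physiologically.

The acoustic side is deliberately only a descriptor (broadband-noise
level, onset, duration): it parameterizes the synaptic-release front end
in :mod:`easfiber.as_surrogate` rather than an audio signal path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ElectricWaveform",
    "AcousticStimulusSpec",
    "monophasic_pulse",
    "biphasic_pulse_train",
    "split_polarity",
]

DEFAULT_DT = 1e-6  # s; integration step of the electric model


@dataclass
class ElectricWaveform:
    """Sampled electric current trace.

    Attributes
    ----------
    dt : sample step (s)
    samples : current (mA); cathodic negative
    t0 : time of the first sample (s)
    pulse_onsets : onset times of the constituent pulses (s), kept for
        post-pulse latency analysis
    """

    dt: float
    samples: np.ndarray
    t0: float = 0.0
    pulse_onsets: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")

    @property
    def duration(self) -> float:
        return len(self.samples) * self.dt

    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.samples))

    def to_csv(self, path) -> None:
        """Write a two-column (time_s, current_mA) CSV."""
        np.savetxt(path, np.column_stack([self.times(), self.samples]),
                   delimiter=",", header="time_s,current_mA", comments="")


@dataclass(frozen=True)
class AcousticStimulusSpec:
    """Broadband-noise acoustic stimulus descriptor.

    Attributes
    ----------
    level : sound pressure level (dB SPL)
    onset : stimulus onset time (s)
    duration : stimulus duration (s)
    kind : only ``"broadband-noise"`` is supported
    """

    level: float
    onset: float = 0.0
    duration: float = 0.0
    kind: str = "broadband-noise"

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.kind != "broadband-noise":
            raise ValueError("only broadband-noise stimuli are supported")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


def _width_in_samples(phase_width: float, dt: float) -> int:
    n = phase_width / dt
    n_round = int(round(n))
    if abs(n - n_round) > 1e-9 * max(1.0, n):
        warnings.warn(
            f"phase width {phase_width} s is not an integer multiple of "
            f"dt={dt} s; rounded to {n_round} samples", stacklevel=3)
    if n_round < 1:
        raise ValueError("phase width must be at least one sample")
    return n_round


def monophasic_pulse(amplitude: float, phase_width: float,
                     polarity: str = "cathodic", dt: float = DEFAULT_DT,
                     total_duration: float | None = None) -> ElectricWaveform:
    """Rectangular monophasic pulse starting at t = 0.

    Parameters
    ----------
    amplitude : pulse amplitude (mA), > 0
    phase_width : pulse duration (s)
    polarity : "cathodic" (negative samples) or "anodic"
    dt : sample step (s)
    total_duration : total waveform length (s); defaults to
        ``phase_width + 3.5 ms`` so the standard analysis window fits
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if phase_width <= 0:
        raise ValueError("phase width must be positive")
    if polarity not in ("cathodic", "anodic"):
        raise ValueError("polarity must be 'cathodic' or 'anodic'")
    if total_duration is None:
        total_duration = phase_width + 3.5e-3
    n_phase = _width_in_samples(phase_width, dt)
    n_total = max(n_phase, int(round(total_duration / dt)))
    samples = np.zeros(n_total)
    sign = -1.0 if polarity == "cathodic" else 1.0
    samples[:n_phase] = sign * amplitude
    return ElectricWaveform(dt=dt, samples=samples,
                            pulse_onsets=np.zeros(1))


def biphasic_pulse_train(amplitude: float, phase_width: float,
                         leading: str = "cathodic", rate: float = 250.0,
                         train_duration: float = 0.3,
                         dt: float = DEFAULT_DT,
                         total_duration: float | None = None,
                         ) -> ElectricWaveform:
    """Charge-balanced symmetric biphasic pulse train.

    Pulses (two back-to-back rectangular phases of opposite polarity, no
    interphase gap) are placed at ``rate`` pulses per second starting at
    t = 0 for ``train_duration`` seconds.

    Parameters
    ----------
    amplitude : phase amplitude (mA), > 0
    phase_width : duration of each phase (s)
    leading : polarity of the first phase
    rate : pulse rate (pulses/s)
    train_duration : duration of the pulse train (s)
    total_duration : optional waveform length beyond the train (s)
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    if leading not in ("cathodic", "anodic"):
        raise ValueError("leading must be 'cathodic' or 'anodic'")
    if 2.0 * phase_width > 1.0 / rate:
        raise ValueError("pulses overlap: 2*phase_width exceeds 1/rate")
    n_pulses = int(np.floor(train_duration * rate + 1e-9))
    if n_pulses < 1:
        raise ValueError("train must contain at least one pulse")
    n_phase = _width_in_samples(phase_width, dt)
    if total_duration is None:
        total_duration = train_duration
    n_total = int(round(total_duration / dt))
    onsets = np.arange(n_pulses) / rate
    samples = np.zeros(n_total)
    sign = -1.0 if leading == "cathodic" else 1.0
    for onset in onsets:
        i0 = int(round(onset / dt))
        samples[i0:i0 + n_phase] = sign * amplitude
        samples[i0 + n_phase:i0 + 2 * n_phase] = -sign * amplitude
    return ElectricWaveform(dt=dt, samples=samples, pulse_onsets=onsets)


def split_polarity(w: ElectricWaveform) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample decomposition into cathodic and anodic parts.

    Returns ``(I_minus, I_plus)`` with ``I_minus = min(samples, 0)`` and
    ``I_plus = max(samples, 0)``; their sum reconstructs the waveform
    exactly.
    """
    return np.minimum(w.samples, 0.0), np.maximum(w.samples, 0.0)
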