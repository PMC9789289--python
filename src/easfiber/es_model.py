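"""Two-point-neuron adaptive integrate-and-fire model for electric stimulation.

The electric-stimulation (ES) model represents the peripheral and the
central process of an auditory nerve fiber by two structurally identical
adaptive exponential integrate-and-fire point neurons.  Cathodic current
depolarizes the peripheral neuron and hyperpolarizes the central one
(scaled by the compression factor ``beta``); anodic current acts the
other way round.  Each neuron carries a subthreshold and a suprathreshold
adaptation current and an intrinsic 1/f^alpha noise current.  A spike is
emitted when either membrane reaches the detection potential; both
neurons are then reset, the suprathreshold adaptation currents jump by
``b`` (relative refractoriness) and external drive is gated off for the
dead time ``t_dead`` (absolute refractoriness).

Integration is forward Euler at a default step of 1 µs, well below the
shortest time constant of the system (``tau_sub`` = 250 µs); a step-size
convergence check is part of the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft

from . import _kernel
from .population import CENTRAL, PERIPHERAL, FiberParams
from .spikes import SpikeTrain
from .stimuli import DEFAULT_DT, ElectricWaveform, split_polarity

__all__ = [
    "ESState",
    "make_noise_current",
    "integrate_fiber",
    "burn_in",
    "run_es_alone",
    "electric_drive",
    "DEFAULT_BURN_IN",
]

#: Default per-trial burn-in (s): >= 8 membrane time constants and
#: >= 4 suprathreshold adaptation time constants for every fiber.
DEFAULT_BURN_IN = 20e-3


@dataclass
class ESState:
    """Membrane state of the two point neurons.

    ``V`` (mV), ``I_sub`` and ``I_supra`` (µA) per neuron, plus the
    shared absolute-refractory bookkeeping.
    """

    V_per: float = PERIPHERAL.E_L
    V_cen: float = CENTRAL.E_L
    I_sub_per: float = 0.0
    I_sub_cen: float = 0.0
    I_supra_per: float = 0.0
    I_supra_cen: float = 0.0
    refractory_until: float = -np.inf
    t: float = 0.0

    def as_vector(self) -> np.ndarray:
        return np.array([self.V_per, self.V_cen, self.I_sub_per,
                         self.I_sub_cen, self.I_supra_per, self.I_supra_cen])

    @classmethod
    def from_vector(cls, v: np.ndarray, t: float = 0.0,
                    refractory_until: float = -np.inf) -> "ESState":
        return cls(V_per=float(v[0]), V_cen=float(v[1]),
                   I_sub_per=float(v[2]), I_sub_cen=float(v[3]),
                   I_supra_per=float(v[4]), I_supra_cen=float(v[5]),
                   refractory_until=refractory_until, t=t)


def noise_batch(rng: np.random.Generator, n_trials: int, n_samples: int,
                dt: float, sigma_noise: float, alpha_noise: float,
                ) -> np.ndarray:
    """Batch of independent 1/f^alpha noise current realizations (µA).

    Synthesis is in the frequency domain: a complex Gaussian spectrum is
    shaped with ``|H(f)| ~ f**(-alpha/2)`` (DC bin zeroed) and transformed
    back; each trace is then rescaled so its sample variance equals
    ``sigma_noise**2`` exactly.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    if sigma_noise == 0.0:
        return np.zeros((n_trials, n_samples))
    # synthesize on the next 5-smooth length (much faster FFT) and slice;
    # a window cut from a longer stationary realization is equally valid.
    # Single precision suffices for a noise source that is renormalized
    # to its target variance afterwards.
    n_fft = sp_fft.next_fast_len(n_samples, real=True)
    nf = n_fft // 2 + 1
    spec = rng.standard_normal((n_trials, 2 * nf),
                               dtype=np.float32).view(np.complex64)
    f = np.fft.rfftfreq(n_fft, dt)
    shape = np.zeros(nf, dtype=np.float32)
    shape[1:] = f[1:] ** (-alpha_noise / 2.0)
    x = sp_fft.irfft(spec * shape, n=n_fft, axis=1)[:, :n_samples]
    x = x.astype(np.float64)
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    return x * (sigma_noise / sd)


def make_noise_current(rng: np.random.Generator, n_samples: int, dt: float,
                       sigma_noise: float, alpha_noise: float = 0.80,
                       ) -> np.ndarray:
    """One realization of the 1/f^alpha membrane noise current (µA)."""
    return noise_batch(rng, 1, n_samples, dt, sigma_noise, alpha_noise)[0]


def electric_drive(w: ElectricWaveform, beta: float = PERIPHERAL.beta,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Polarity-weighted stimulating currents in µA.

    The cathodic part ``I-`` (negative samples) and anodic part ``I+``
    are weighted into the two neurons as

    * peripheral: ``-(I- + beta * I+)`` — cathodic depolarizes,
    * central:    ``beta * I- + I+``   — anodic depolarizes,

    converting the waveform from mA to µA.
    """
    i_minus, i_plus = split_polarity(w)
    drive_per = -(i_minus + beta * i_plus) * 1e3
    drive_cen = (beta * i_minus + i_plus) * 1e3
    return drive_per, drive_cen


def _run_batch(fiber: FiberParams, drive_per: np.ndarray,
               drive_cen: np.ndarray, n_trials: int,
               rng: np.random.Generator, dt: float,
               syn_per: np.ndarray | None = None,
               rel_idx_flat: np.ndarray | None = None,
               rel_offsets: np.ndarray | None = None,
               states: np.ndarray | None = None,
               noise: bool = True,
               ) -> tuple[list[np.ndarray], list[np.ndarray], np.ndarray]:
    """Integrate ``n_trials`` independent trials of one fiber.

    Returns (spike-time arrays, spike-source arrays, final states).
    Spike times are relative to the start of the drive arrays.
    """
    n = len(drive_per)
    if noise:
        noise_per = noise_batch(rng, n_trials, n, dt,
                                PERIPHERAL.sigma_noise, PERIPHERAL.alpha_noise)
        noise_cen = noise_batch(rng, n_trials, n, dt,
                                CENTRAL.sigma_noise, CENTRAL.alpha_noise)
    else:
        noise_per = np.zeros((n_trials, n))
        noise_cen = noise_per
    p = _kernel.make_param_vector(fiber, PERIPHERAL, CENTRAL, dt)
    if syn_per is None:
        syn_per = np.zeros((0, 0))
    if rel_idx_flat is None:
        rel_idx_flat = np.zeros(0, dtype=np.int64)
        rel_offsets = np.zeros(0, dtype=np.int64)
        rrp_draws = np.zeros((1, 1))
    else:
        # generous pool of relative-refractory draws, one consumed per spike
        n_draw = max(8, int(n * dt / fiber.t_abs) + 8)
        rrp_draws = rng.exponential(fiber.t_rel, (n_trials, n_draw)) / dt
    if states is None:
        states = np.tile(ESState().as_vector(), (n_trials, 1))
    max_spikes = n // max(1, int(round(fiber.t_dead / dt))) + 16
    if rel_idx_flat.size:
        max_spikes += int(np.max(np.diff(rel_offsets))) if len(rel_offsets) > 1 else 0
    out_t = np.zeros((n_trials, max_spikes))
    out_w = np.zeros((n_trials, max_spikes), dtype=np.int64)
    out_n = np.zeros(n_trials, dtype=np.int64)
    _kernel.integrate_batch(p, drive_per, drive_cen, syn_per,
                            noise_per, noise_cen,
                            rel_idx_flat, rel_offsets, rrp_draws,
                            states, out_t, out_w, out_n)
    times = [out_t[k, :out_n[k]] for k in range(n_trials)]
    which = [out_w[k, :out_n[k]] for k in range(n_trials)]
    return times, which, states


def integrate_fiber(fiber: FiberParams, drive_per: np.ndarray,
                    drive_cen: np.ndarray, state: ESState,
                    rng: np.random.Generator, dt: float = DEFAULT_DT,
                    return_attribution: bool = False):
    """Integrate one trial from an explicit initial state.

    ``drive_per`` / ``drive_cen`` are the already polarity-weighted
    stimulating currents (µA) on the integration grid.  Returns a
    :class:`~easfiber.spikes.SpikeTrain` (spike times relative to the
    start of the drive arrays); with ``return_attribution=True`` also the
    per-spike source neuron (0 peripheral, 1 central).
    """
    states = state.as_vector()[None, :].copy()
    times, which, _ = _run_batch(fiber, np.asarray(drive_per, float),
                                 np.asarray(drive_cen, float), 1, rng, dt,
                                 states=states)
    train = SpikeTrain(times[0], source_label="ES")
    if return_attribution:
        return train, which[0]
    return train


def burn_in(fiber: FiberParams, state: ESState | None = None,
            duration: float = DEFAULT_BURN_IN,
            rng: np.random.Generator | None = None,
            dt: float = DEFAULT_DT) -> ESState:
    """Evolve the membrane with noise only to draw a random initial state."""
    if duration <= 0:
        raise ValueError("burn-in duration must be positive")
    if rng is None:
        rng = np.random.default_rng()
    if state is None:
        state = ESState()
    n = int(round(duration / dt))
    zeros = np.zeros(n)
    states = state.as_vector()[None, :].copy()
    _run_batch(fiber, zeros, zeros, 1, rng, dt, states=states)
    return ESState.from_vector(states[0], t=state.t + duration)


def run_es_alone(fiber: FiberParams, waveform: ElectricWaveform,
                 n_reps: int = 1, rng: np.random.Generator | None = None,
                 burn_in_duration: float = DEFAULT_BURN_IN,
                 fiber_id: int = 0) -> list[SpikeTrain]:
    """Simulate electric-only stimulation of an acoustically insensitive fiber.

    Each repetition starts from a fresh noise-generated membrane state
    (burn-in is prepended to the stimulus on the same grid) and uses an
    independent noise realization.  Spike times are reported relative to
    the waveform time axis; burn-in spikes, if any, have negative times.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    dt = waveform.dt
    n_burn = int(round(burn_in_duration / dt))
    drive_per, drive_cen = electric_drive(waveform)
    drive_per = np.concatenate([np.zeros(n_burn), drive_per])
    drive_cen = np.concatenate([np.zeros(n_burn), drive_cen])
    times, _, _ = _run_batch(fiber, drive_per, drive_cen, n_reps, rng, dt)
    t0 = waveform.t0 - n_burn * dt
    return [SpikeTrain(t + t0, fiber_id=fiber_id, trial_id=k,
                       source_label="ES")
            for k, t in enumerate(times)]
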