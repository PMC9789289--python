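"""Surrogate synaptic-release front end for acoustic stimulation.

The acoustic pathway of a real auditory periphery model (middle-ear
filter, basilar-membrane tuning, hair-cell transduction, power-law
synapse) is replaced here by a compact surrogate: an inhomogeneous
Poisson process of neurotransmitter-release events whose instantaneous
rate follows a level-dependent profile with onset adaptation and
post-offset suppression of spontaneous activity.  A classic spike
generator converts release events to spikes, discarding events that fall
into a random refractory period ``t_abs + Exp(mean t_rel)`` after each
spike.

The surrogate reproduces the features the coupling experiments depend on
— spontaneous rate, saturating driven rates, onset emphasis, transient
off-suppression, refractoriness — but not cochlear tuning, phase locking
to stimulus fine structure, or power-law adaptation.  Any object
implementing ``release_times(fiber, stimulus, window, rng)`` can replace
it (see :class:`SurrogateReleaseGenerator` for the contract), so a full
periphery model can be plugged in without touching the coupling code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .population import FiberParams
from .spikes import SpikeTrain
from .stimuli import AcousticStimulusSpec

__all__ = [
    "ReleaseTrain",
    "RateProfileParams",
    "SurrogateReleaseGenerator",
    "calibrate_spontaneous_rate",
    "spike_rate_for_release_rate",
    "release_rate_for_spike_rate",
    "release_rate_profile",
    "generate_releases",
    "releases_to_spikes",
    "run_as_alone",
    "driven_spike_rate",
    "RELEASE_GRID",
]

#: Time resolution of the release-event grid (s).
RELEASE_GRID = 10e-6


@dataclass
class ReleaseTrain:
    """Sorted neurotransmitter-release event times on a 10 µs grid."""

    event_times: np.ndarray

    def __post_init__(self) -> None:
        self.event_times = np.asarray(self.event_times, dtype=float)
        if np.any(np.diff(self.event_times) <= 0):
            raise ValueError("release times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.event_times)


@dataclass(frozen=True)
class RateProfileParams:
    """Tunable parameters of the surrogate release-rate profile.

    Attributes
    ----------
    r_max : saturated sustained *driven* release rate (events/s); if
        ``None`` it is derived per fiber so that the saturated driven
        spike rate equals ``driven_spike_max``
    driven_spike_max : saturated acoustically driven spike rate
        (spikes/s) used to derive ``r_max``
    L50 : level of half-maximal driven rate (dB SPL, for a normal ear)
    slope : logistic rate-level slope (dB)
    onset_factor : peak/sustained ratio of the onset response
    tau_adapt : onset adaptation time constant (s)
    tau_rec : recovery time constant of spontaneous activity after the
        stimulus offset (s)
    suppression_depth : fraction of spontaneous rate suppressed at the
        stimulus offset (0..1)
    hearing_loss : flat acoustic threshold shift (dB); effective level is
        ``level - hearing_loss``
    """

    r_max: float | None = None
    driven_spike_max: float = 150.0
    L50: float = 55.0
    slope: float = 6.0
    onset_factor: float = 2.5
    tau_adapt: float = 10e-3
    tau_rec: float = 80e-3
    suppression_depth: float = 1.0
    hearing_loss: float = 26.0

    def __post_init__(self) -> None:
        if self.tau_adapt <= 0 or self.tau_rec <= 0:
            raise ValueError("time constants must be positive")
        if not 0.0 <= self.suppression_depth <= 1.0:
            raise ValueError("suppression_depth must be in [0, 1]")


def spike_rate_for_release_rate(r0: float, t_abs: float, t_rel: float,
                                ) -> float:
    """Steady-state output spike rate of the spike generator.

    For homogeneous Poisson releases at rate ``r0`` thinned by a random
    refractory period ``t_abs + Exp(mean t_rel)``, the mean inter-spike
    interval is ``t_abs + t_rel + 1/r0``.
    """
    if r0 <= 0:
        return 0.0
    return r0 / (1.0 + r0 * (t_abs + t_rel))


def release_rate_for_spike_rate(sr: float, t_abs: float, t_rel: float,
                                ) -> float:
    """Inverse of :func:`spike_rate_for_release_rate` (dead-time correction)."""
    if sr < 0:
        raise ValueError("spike rate must be non-negative")
    occupancy = sr * (t_abs + t_rel)
    if occupancy >= 1.0:
        raise ValueError(
            f"spike rate {sr}/s unreachable with refractoriness "
            f"t_abs+t_rel={t_abs + t_rel:g} s")
    return sr / (1.0 - occupancy)


def calibrate_spontaneous_rate(sr: float, t_abs: float, t_rel: float,
                               refine: bool = False,
                               rng: np.random.Generator | None = None,
                               sim_duration: float = 50.0) -> float:
    """Release rate r0 whose refractory-thinned spike output equals ``sr``.

    The closed-form dead-time correction
    ``r0 = sr / (1 - sr * (t_abs + t_rel))`` is exact for the memoryless
    refractory rule used here, so the optional simulation-based bisection
    (``refine=True``) only compensates for the residual discretization of
    the 10 µs release grid and is off by default.
    """
    r0 = release_rate_for_spike_rate(sr, t_abs, t_rel)
    if not refine or sr == 0:
        return r0
    if rng is None:
        rng = np.random.default_rng()

    def simulated_rate(r: float) -> float:
        rel = generate_releases(rng, lambda t: np.full_like(t, r),
                                (0.0, sim_duration))
        sp = releases_to_spikes(rel, t_abs, t_rel, rng)
        return len(sp) / sim_duration

    lo, hi = 0.5 * r0, 2.0 * r0
    for _ in range(20):
        mid = 0.5 * (lo + hi)
        if simulated_rate(mid) < sr:
            lo = mid
        else:
            hi = mid
        if hi - lo < 0.005 * r0:
            break
    return 0.5 * (lo + hi)


def _driven_release_rate(level: float, fiber: FiberParams,
                         params: RateProfileParams) -> float:
    """Sustained driven release rate (events/s) at the given level."""
    if params.r_max is not None:
        r_max = params.r_max
    else:
        # saturate the driven *spike* rate at driven_spike_max
        r_total = release_rate_for_spike_rate(
            min(fiber.sr + params.driven_spike_max,
                0.99 / (fiber.t_abs + fiber.t_rel)),
            fiber.t_abs, fiber.t_rel)
        r_spont = release_rate_for_spike_rate(fiber.sr, fiber.t_abs,
                                              fiber.t_rel)
        r_max = max(r_total - r_spont, 0.0)
    hl = fiber.hearing_loss if fiber is not None else params.hearing_loss
    x = (level - hl - params.L50) / params.slope
    return r_max / (1.0 + math.exp(-x))


def release_rate_profile(spec: AcousticStimulusSpec | None,
                         fiber: FiberParams,
                         params: RateProfileParams | None = None,
                         ) -> Callable[[np.ndarray], np.ndarray]:
    """Instantaneous release-rate function r(t) in events/s.

    Before the stimulus the rate is the calibrated spontaneous release
    rate; during the stimulus a level-dependent driven rate with an
    exponentially decaying onset emphasis is added; after the offset the
    spontaneous rate is transiently suppressed and recovers with
    ``tau_rec``.
    """
    if params is None:
        params = RateProfileParams(hearing_loss=fiber.hearing_loss)
    r_spont = release_rate_for_spike_rate(fiber.sr, fiber.t_abs, fiber.t_rel)
    if spec is None or spec.duration == 0:
        def profile(t: np.ndarray) -> np.ndarray:
            return np.full_like(np.asarray(t, dtype=float), r_spont)
        return profile
    r_drv = _driven_release_rate(spec.level, fiber, params)
    onset, offset = spec.onset, spec.offset
    of, ta, tr = params.onset_factor, params.tau_adapt, params.tau_rec
    depth = params.suppression_depth

    def profile(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r = np.full_like(t, r_spont)
        during = (t >= onset) & (t < offset)
        r[during] += r_drv * (1.0 + (of - 1.0)
                              * np.exp(-(t[during] - onset) / ta))
        after = t >= offset
        r[after] = r_spont * (1.0 - depth * np.exp(-(t[after] - offset) / tr))
        return r

    return profile


def generate_releases(rng: np.random.Generator,
                      profile: Callable[[np.ndarray], np.ndarray],
                      window: tuple[float, float],
                      grid: float = RELEASE_GRID) -> ReleaseTrain:
    """Inhomogeneous Poisson release events via thinning.

    Candidate events are drawn as a homogeneous Poisson process at the
    peak rate of the profile over the window and thinned by the rate
    ratio; surviving events are snapped to the release grid with at most
    one event per grid cell.
    """
    t0, t1 = window
    if t1 <= t0:
        return ReleaseTrain(np.zeros(0))
    tt = np.arange(t0, t1, grid)
    rates = np.asarray(profile(tt), dtype=float)
    r_bound = float(rates.max(initial=0.0))
    if r_bound <= 0:
        return ReleaseTrain(np.zeros(0))
    n_cand = rng.poisson(r_bound * (t1 - t0))
    if n_cand == 0:
        return ReleaseTrain(np.zeros(0))
    cand = rng.uniform(t0, t1, n_cand)
    accept = rng.uniform(0.0, r_bound, n_cand) < np.asarray(
        profile(cand), dtype=float)
    events = cand[accept]
    cells = np.unique(np.floor((events - t0) / grid).astype(np.int64))
    return ReleaseTrain(t0 + cells * grid)


def releases_to_spikes(releases: ReleaseTrain, t_abs: float, t_rel: float,
                       rng: np.random.Generator) -> SpikeTrain:
    """Convert release events to spikes with random refractoriness.

    After each emitted spike a refractory duration ``t_abs + X`` with
    ``X ~ Exp(mean t_rel)`` is drawn; releases inside it are discarded.
    """
    spikes = []
    blocked_until = -np.inf
    for t in releases.event_times:
        if t >= blocked_until:
            spikes.append(t)
            blocked_until = t + t_abs + rng.exponential(t_rel) \
                if (t_abs or t_rel) else t
    return SpikeTrain(np.asarray(spikes), source_label="AS")


@runtime_checkable
class ReleaseGenerator(Protocol):
    """Plug-in contract for an acoustic front end."""

    def release_times(self, fiber: FiberParams,
                      stimulus: AcousticStimulusSpec | None,
                      window: tuple[float, float],
                      rng: np.random.Generator) -> ReleaseTrain: ...


@dataclass(frozen=True)
class SurrogateReleaseGenerator:
    """Default release generator built on the surrogate rate profile."""

    params: RateProfileParams | None = None

    def release_times(self, fiber: FiberParams,
                      stimulus: AcousticStimulusSpec | None,
                      window: tuple[float, float],
                      rng: np.random.Generator) -> ReleaseTrain:
        params = self.params
        if params is None:
            params = RateProfileParams(hearing_loss=fiber.hearing_loss)
        profile = release_rate_profile(stimulus, fiber, params)
        return generate_releases(rng, profile, window)


def run_as_alone(fiber: FiberParams, spec: AcousticStimulusSpec | None,
                 window: tuple[float, float], rng: np.random.Generator,
                 release_model: ReleaseGenerator | None = None,
                 fiber_id: int = 0, trial_id: int = 0) -> SpikeTrain:
    """Acoustic-only (or spontaneous-only) spiking of one fiber."""
    if release_model is None:
        release_model = SurrogateReleaseGenerator()
    releases = release_model.release_times(fiber, spec, window, rng)
    train = releases_to_spikes(releases, fiber.t_abs, fiber.t_rel, rng)
    train.fiber_id = fiber_id
    train.trial_id = trial_id
    return train


def driven_spike_rate(level: float, fiber: FiberParams,
                      params: RateProfileParams | None = None) -> float:
    """Expected sustained SR-corrected driven spike rate at ``level`` dB SPL."""
    if params is None:
        params = RateProfileParams(hearing_loss=fiber.hearing_loss)
    r_spont = release_rate_for_spike_rate(fiber.sr, fiber.t_abs, fiber.t_rel)
    r_total = r_spont + _driven_release_rate(level, fiber, params)
    return (spike_rate_for_release_rate(r_total, fiber.t_abs, fiber.t_rel)
            - fiber.sr)
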