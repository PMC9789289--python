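"""Coupling variants for combined electric-acoustic stimulation.

Three single-fiber model variants combine the electric membrane model
with the acoustic release front end:

* **uncoupled** — electric-only and acoustic-only spike trains are merged
  without any interaction; the baseline for quantifying interaction.
* **coupled** — the acoustic spike generator is removed: every
  neurotransmitter release injects a brief, strongly suprathreshold
  rectangular current (40 µs, 3.0 mA) into the peripheral neuron of the
  electric model, which then enforces a common refractoriness across
  modalities.  All output spikes come from the membrane model.
* **alternative** — both models keep their own spike generation, but
  exchange spike occurrences at run time: any spike puts *both* systems
  into their absolute and relative refractory states.

The coupled and alternative variants implement mutual suppression that
is restricted to the suprathreshold regime by construction.
"""

from __future__ import annotations

import numpy as np

from . import es_model
from .as_surrogate import (ReleaseGenerator, ReleaseTrain,
                           SurrogateReleaseGenerator)
from .population import FiberParams
from .spikes import SpikeTrain
from .stimuli import AcousticStimulusSpec, ElectricWaveform

__all__ = [
    "run_uncoupled",
    "release_current",
    "run_coupled",
    "run_alternative",
    "T_NEURO",
    "I_NEURO",
]

#: Duration (s) and amplitude (mA) of the per-release synaptic current.
T_NEURO = 40e-6
I_NEURO = 3.0


def run_uncoupled(fiber: FiberParams, elec: ElectricWaveform | None,
                  spec: AcousticStimulusSpec | None,
                  rng: np.random.Generator,
                  release_model: ReleaseGenerator | None = None,
                  burn_in_duration: float = es_model.DEFAULT_BURN_IN,
                  fiber_id: int = 0, trial_id: int = 0) -> SpikeTrain:
    """Merged, non-interacting electric + acoustic spike train.

    The electric and the acoustic pathway are simulated independently and
    their spike times merged (no deduplication, no cross-source
    refractoriness).  The acoustic pathway covers the electric waveform's
    time span (or the acoustic stimulus, whichever is longer).
    """
    es_times = np.zeros(0)
    t_end = 0.0
    if elec is not None:
        es_train = es_model.run_es_alone(fiber, elec, 1, rng,
                                         burn_in_duration)[0]
        es_times = es_train.spike_times
        es_times = es_times[es_times >= 0.0]  # drop burn-in spikes
        t_end = elec.duration
    if spec is not None:
        t_end = max(t_end, spec.offset + 0.1)
    as_train = run_as_alone_window(fiber, spec, (0.0, t_end), rng,
                                   release_model)
    merged = np.sort(np.concatenate([es_times, as_train.spike_times]))
    return SpikeTrain(merged, fiber_id=fiber_id, trial_id=trial_id,
                      source_label="EAS-uncoupled")


def run_as_alone_window(fiber, spec, window, rng, release_model=None):
    from .as_surrogate import run_as_alone
    return run_as_alone(fiber, spec, window, rng, release_model)


def release_current(releases: ReleaseTrain, dt: float,
                    t_neuro: float = T_NEURO, I_neuro: float = I_NEURO,
                    t0: float = 0.0, total_duration: float | None = None,
                    ) -> ElectricWaveform:
    """Rectangular synaptic currents, one per release event.

    Returns a cathodic-sign (negative-sample) current waveform in mA on
    the integration grid, starting at ``t0``.  Each event contributes a
    ``t_neuro``-long pulse of amplitude ``I_neuro``; overlapping
    injections sum.
    """
    if total_duration is None:
        t_last = releases.event_times[-1] if len(releases) else t0
        total_duration = (t_last - t0) + t_neuro
    n = int(round(total_duration / dt))
    samples = np.zeros(n)
    n_pulse = max(1, int(round(t_neuro / dt)))
    for t in releases.event_times:
        i0 = int(round((t - t0) / dt))
        if i0 >= n:
            continue
        samples[max(i0, 0):min(i0 + n_pulse, n)] += -I_neuro
    return ElectricWaveform(dt=dt, samples=samples, t0=t0)


def _release_batch(fiber, spec, window, rng, release_model, n_reps):
    if release_model is None:
        release_model = SurrogateReleaseGenerator()
    return [release_model.release_times(fiber, spec, window, rng)
            for _ in range(n_reps)]


def run_coupled_batch(fiber: FiberParams, elec: ElectricWaveform | None,
                      spec: AcousticStimulusSpec | None,
                      rng: np.random.Generator, n_reps: int = 1,
                      release_model: ReleaseGenerator | None = None,
                      burn_in_duration: float = es_model.DEFAULT_BURN_IN,
                      fiber_id: int = 0) -> list[SpikeTrain]:
    """Coupled-model repetitions sharing the electric waveform.

    Releases are generated over burn-in plus the stimulus window so the
    membrane carries realistic spontaneous-activity history when the
    electric stimulus starts.  The synaptic current is gated off during
    the dead time exactly like the electric drive.
    """
    if elec is None:
        if spec is not None:
            dur = spec.offset + 0.1
        else:
            dur = 0.1
        elec = ElectricWaveform(dt=1e-6, samples=np.zeros(int(round(dur / 1e-6))))
    dt = elec.dt
    n_burn = int(round(burn_in_duration / dt))
    drive_per, drive_cen = es_model.electric_drive(elec)
    drive_per = np.concatenate([np.zeros(n_burn), drive_per])
    drive_cen = np.concatenate([np.zeros(n_burn), drive_cen])
    n = len(drive_per)
    window = (-n_burn * dt, elec.duration)
    amp_ua = I_NEURO * 1e3
    n_pulse = max(1, int(round(T_NEURO / dt)))
    syn = np.zeros((n_reps, n))
    releases = _release_batch(fiber, spec, window, rng, release_model, n_reps)
    for k, rel in enumerate(releases):
        for t in rel.event_times:
            i0 = int(round((t - window[0]) / dt))
            if 0 <= i0 < n:
                syn[k, i0:i0 + n_pulse] += amp_ua
    times, _, _ = es_model._run_batch(fiber, drive_per, drive_cen, n_reps,
                                      rng, dt, syn_per=syn)
    t0 = elec.t0 - n_burn * dt
    return [SpikeTrain(t + t0, fiber_id=fiber_id, trial_id=k,
                       source_label="EAS-coupled")
            for k, t in enumerate(times)]


def run_coupled(fiber: FiberParams, elec: ElectricWaveform | None,
                spec: AcousticStimulusSpec | None,
                rng: np.random.Generator,
                release_model: ReleaseGenerator | None = None,
                burn_in_duration: float = es_model.DEFAULT_BURN_IN,
                fiber_id: int = 0) -> SpikeTrain:
    """One trial of the coupled EAS model (release-to-current coupling)."""
    return run_coupled_batch(fiber, elec, spec, rng, 1, release_model,
                             burn_in_duration, fiber_id)[0]


def run_alternative_batch(fiber: FiberParams, elec: ElectricWaveform | None,
                          spec: AcousticStimulusSpec | None,
                          rng: np.random.Generator, n_reps: int = 1,
                          release_model: ReleaseGenerator | None = None,
                          burn_in_duration: float = es_model.DEFAULT_BURN_IN,
                          fiber_id: int = 0) -> list[SpikeTrain]:
    """Alternative (spike-exchange) coupling repetitions."""
    if elec is None:
        dur = (spec.offset + 0.1) if spec is not None else 0.1
        elec = ElectricWaveform(dt=1e-6, samples=np.zeros(int(round(dur / 1e-6))))
    dt = elec.dt
    n_burn = int(round(burn_in_duration / dt))
    drive_per, drive_cen = es_model.electric_drive(elec)
    drive_per = np.concatenate([np.zeros(n_burn), drive_per])
    drive_cen = np.concatenate([np.zeros(n_burn), drive_cen])
    n = len(drive_per)
    window = (-n_burn * dt, elec.duration)
    releases = _release_batch(fiber, spec, window, rng, release_model, n_reps)
    rel_idx = []
    offsets = [0]
    for rel in releases:
        idx = np.round((rel.event_times - window[0]) / dt).astype(np.int64)
        idx = idx[(idx >= 0) & (idx < n)]
        rel_idx.append(idx)
        offsets.append(offsets[-1] + len(idx))
    rel_idx_flat = (np.concatenate(rel_idx) if rel_idx
                    else np.zeros(0, dtype=np.int64))
    rel_offsets = np.asarray(offsets, dtype=np.int64)
    times, _, _ = es_model._run_batch(fiber, drive_per, drive_cen, n_reps,
                                      rng, dt, rel_idx_flat=rel_idx_flat,
                                      rel_offsets=rel_offsets)
    t0 = elec.t0 - n_burn * dt
    out = []
    for k, t in enumerate(times):
        # collapse duplicates emitted in the same integration step
        t = np.unique(np.round(t / dt).astype(np.int64)) * dt + t0
        out.append(SpikeTrain(t, fiber_id=fiber_id, trial_id=k,
                              source_label="EAS-alt"))
    return out


def run_alternative(fiber: FiberParams, elec: ElectricWaveform | None,
                    spec: AcousticStimulusSpec | None,
                    rng: np.random.Generator,
                    release_model: ReleaseGenerator | None = None,
                    burn_in_duration: float = es_model.DEFAULT_BURN_IN,
                    fiber_id: int = 0) -> SpikeTrain:
    """One trial of the alternative (spike-exchange) EAS model."""
    return run_alternative_batch(fiber, elec, spec, rng, 1, release_model,
                                 burn_in_duration, fiber_id)[0]
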