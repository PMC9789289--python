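import dataclasses

import numpy as np
import pytest

from easfiber.as_surrogate import ReleaseTrain
from easfiber.eas_coupling import (release_current, run_alternative_batch,
                                   run_coupled_batch, run_uncoupled)
from easfiber.population import sample_population
from easfiber.stimuli import ElectricWaveform, biphasic_pulse_train, monophasic_pulse


def _zero_sr(fiber):
    return dataclasses.replace(fiber, sr=0.0)


def test_uncoupled_empty_when_silent(mean_fiber, rng):
    """Subthreshold electric + zero SR gives an empty merged train."""
    elec = monophasic_pulse(0.05, 26e-6, "cathodic")
    tr = run_uncoupled(_zero_sr(mean_fiber), elec, None, rng)
    assert len(tr) == 0
    assert tr.source_label == "EAS-uncoupled"


def test_uncoupled_is_union(hsr_fiber, rng):
    """The merged train length equals |ES| + |AS| (no dedup)."""
    import easfiber.es_model as esm
    import easfiber.as_surrogate as asur
    elec = monophasic_pulse(3.0, 26e-6, "cathodic",
                            total_duration=50e-3)
    # reproduce the exact sub-streams with a matched generator
    rng1 = np.random.default_rng(42)
    tr = run_uncoupled(hsr_fiber, elec, None, rng1)
    rng2 = np.random.default_rng(42)
    es = esm.run_es_alone(hsr_fiber, elec, 1, rng2)[0]
    as_ = asur.run_as_alone(hsr_fiber, None, (0.0, elec.duration), rng2)
    n_es = np.sum(es.spike_times >= 0.0)
    assert len(tr) == n_es + len(as_)


def test_release_current_shape():
    assert len(release_current(ReleaseTrain(np.zeros(0)), 1e-6,
                               total_duration=1e-3).samples.nonzero()[0]) == 0
    w = release_current(ReleaseTrain(np.array([1e-3])), 1e-6,
                        total_duration=2e-3)
    nz = np.nonzero(w.samples)[0]
    assert len(nz) == 40                      # exactly 40 us of drive
    assert np.all(w.samples[nz] == -3.0)      # cathodic sign, 3 mA
    # overlapping injections sum
    w2 = release_current(ReleaseTrain(np.array([1e-3, 1.02e-3])), 1e-6,
                         total_duration=2e-3)
    assert w2.samples.min() == -6.0


def test_every_release_spikes_across_population(rng):
    """A single release fires the peripheral neuron for every fiber in a
    population sample, unless refractory."""
    fibers = sample_population(np.random.default_rng(0), 2, 2, 4)
    elec = ElectricWaveform(dt=1e-6, samples=np.zeros(10_000))
    for fiber in fibers:
        fiber = dataclasses.replace(fiber, sr=0.0)

        class OneRelease:
            def release_times(self, fiber, stimulus, window, rng):
                return ReleaseTrain(np.array([5e-3]))

        tr = run_coupled_batch(fiber, elec, None, rng, 1,
                               release_model=OneRelease())[0]
        assert len(tr) == 1
        assert abs(tr.spike_times[0] - 5e-3) < 0.2e-3


def test_release_in_dead_time_is_silent(mean_fiber, rng):
    """A release arriving inside the dead time of an electric spike does
    not produce an additional spike."""
    elec = monophasic_pulse(3.0, 26e-6, "cathodic", total_duration=10e-3)

    class LateRelease:
        def release_times(self, fiber, stimulus, window, rng):
            return ReleaseTrain(np.array([150e-6]))  # ~100 us after spike

    tr = run_coupled_batch(dataclasses.replace(mean_fiber, sr=0.0), elec,
                           None, rng, 1, release_model=LateRelease())[0]
    assert len(tr) == 1


def test_coupled_spontaneous_rate_matches_sr(hsr_fiber):
    """With no electric stimulus the membrane-enforced refractoriness
    reproduces the fiber's spontaneous rate within ~5 %."""
    rng = np.random.default_rng(31)
    elec = ElectricWaveform(dt=1e-6, samples=np.zeros(1_000_000))
    trains = run_coupled_batch(hsr_fiber, elec, None, rng, n_reps=20)
    rate = np.mean([np.sum(t.spike_times >= 0.0) for t in trains])
    assert rate == pytest.approx(70.0, rel=0.08)


def test_coupled_equals_uncoupled_without_acoustic_input(mean_fiber, rng):
    """With SR = 0 and no acoustic stimulus there are no releases, so the
    coupled model reduces to the electric-only pathway."""
    fiber = _zero_sr(mean_fiber)
    elec = monophasic_pulse(3.0, 26e-6, "cathodic")
    tr_c = run_coupled_batch(fiber, elec, None,
                             np.random.default_rng(5), 1)[0]
    import easfiber.es_model as esm
    tr_e = esm.run_es_alone(fiber, elec, 1, np.random.default_rng(5))[0]
    assert np.allclose(tr_c.spike_times, tr_e.spike_times)


def test_alternative_empty_and_min_isi(mean_fiber, hsr_fiber, rng):
    elec = monophasic_pulse(0.05, 26e-6, "cathodic")
    tr = run_alternative_batch(_zero_sr(mean_fiber), elec, None, rng, 1)[0]
    assert len(tr) == 0
    # mutual refractoriness: min ISI >= t_abs even for merged sources
    elec = biphasic_pulse_train(2.0, 40e-6, "cathodic", 250.0, 0.2)
    for tr in run_alternative_batch(hsr_fiber, elec, None, rng, 3):
        if len(tr) > 1:
            assert np.diff(tr.spike_times).min() >= hsr_fiber.t_abs - 1e-9


def test_alternative_spontaneous_rate(hsr_fiber):
    rng = np.random.default_rng(32)
    elec = ElectricWaveform(dt=1e-6, samples=np.zeros(1_000_000))
    trains = run_alternative_batch(hsr_fiber, elec, None, rng, n_reps=20)
    rate = np.mean([np.sum(t.spike_times >= 0.0) for t in trains])
    assert rate == pytest.approx(70.0, rel=0.08)


def test_hsr_sublinear_addition(hsr_fiber):
    """Coupled EA spike rate stays below the sum of the E and A rates
    (suppression through shared refractoriness)."""
    from easfiber.stimuli import AcousticStimulusSpec
    rng = np.random.default_rng(33)
    spec = AcousticStimulusSpec(level=100.0, onset=0.0, duration=0.4)
    elec = biphasic_pulse_train(2.0, 40e-6, "cathodic", 250.0, 0.4)
    n = 4

    def mean_rate(trains):
        return np.mean([np.sum((t.spike_times >= 0.05)
                               & (t.spike_times < 0.4)) / 0.35
                        for t in trains])

    ea = mean_rate(run_coupled_batch(hsr_fiber, elec, spec, rng, n))
    e = mean_rate(run_coupled_batch(hsr_fiber, elec, None, rng, n))
    a = mean_rate(run_coupled_batch(
        hsr_fiber, ElectricWaveform(dt=1e-6, samples=np.zeros(400_000)),
        spec, rng, n))
    assert ea < e + a
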