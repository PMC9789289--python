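import numpy as np
import pytest
from scipy import stats

import easfiber.experiments as ex
from easfiber.es_model import (ESState, burn_in, electric_drive,
                               integrate_fiber, make_noise_current,
                               run_es_alone)
from easfiber.population import PERIPHERAL
from easfiber.response_stats import firing_efficiency
from easfiber.stimuli import monophasic_pulse


def test_noise_zero_sigma(rng):
    x = make_noise_current(rng, 1000, 1e-6, 0.0)
    assert np.all(x == 0.0)


def test_noise_variance_exact(rng):
    x = make_noise_current(rng, 5000, 1e-6, 8.70, 0.8)
    assert x.std() == pytest.approx(8.70, rel=1e-9)
    assert abs(x.mean()) < 1e-9


def test_noise_psd_slope(rng):
    """Averaged periodogram follows f^-alpha with alpha = 0.80."""
    n, dt = 4096, 1e-6
    psd = np.zeros(n // 2 + 1)
    for _ in range(200):
        x = make_noise_current(rng, n, dt, 10.0, 0.8)
        psd += np.abs(np.fft.rfft(x)) ** 2
    f = np.fft.rfftfreq(n, dt)
    sel = slice(1, n // 2)  # skip DC and Nyquist
    slope, *_ = stats.linregress(np.log(f[sel]), np.log(psd[sel]))
    assert slope == pytest.approx(-0.80, abs=0.05)


def test_quiescent_fixed_point(mean_fiber, rng):
    """With zero drive and zero noise the membrane settles at its
    quiescent point: within 1 mV of the resting potential (the
    exponential spiking term shifts it slightly above E_L) and
    stationary thereafter; no spikes are emitted."""
    from easfiber.es_model import _run_batch
    zeros = np.zeros(40_000)  # ~9 suprathreshold adaptation constants
    times, _, s1 = _run_batch(mean_fiber, zeros, zeros, 1, rng, 1e-6,
                              noise=False)
    assert len(times[0]) == 0
    assert abs(s1[0][0] + 80.0) < 1.0 and abs(s1[0][1] + 80.0) < 1.0
    # stationarity: a second integration from the settled state is inert
    _, _, s2 = _run_batch(mean_fiber, zeros, zeros, 1, rng, 1e-6,
                          states=s1.copy(), noise=False)
    assert np.allclose(s1, s2, atol=1e-3)


def test_single_pulse_single_spike(mean_fiber, rng):
    """A strongly suprathreshold pulse gives exactly one spike (dead time)."""
    w = monophasic_pulse(3.0, 26e-6, "cathodic")
    for tr in run_es_alone(mean_fiber, w, 10, rng):
        t = tr.spike_times[tr.spike_times >= 0]
        assert len(t) == 1


def test_min_isi_respects_dead_time(mean_fiber, rng):
    """No two spikes closer than t_dead, even under strong drive."""
    w = monophasic_pulse(5.0, 2e-3, "cathodic", total_duration=10e-3)
    for tr in run_es_alone(mean_fiber, w, 5, rng):
        if len(tr) > 1:
            assert np.diff(tr.spike_times).min() >= mean_fiber.t_dead - 1e-9


def test_large_b_suppresses_repeated_spiking(mean_fiber, rng):
    """Refractory suppression is monotone in the spike-triggered offset b."""
    w = monophasic_pulse(2.0, 26e-6, "cathodic", dt=1e-6,
                         total_duration=25e-3)
    # repeat the pulse every 2.5 ms by tiling
    s = np.tile(w.samples[:2500], 10)
    from easfiber.stimuli import ElectricWaveform
    train = ElectricWaveform(dt=1e-6, samples=s)
    base = sum(len(tr) for tr in run_es_alone(mean_fiber, train, 3, rng))
    with _patched_b(1e5):
        trains = run_es_alone(mean_fiber, train, 3, rng)
    few = sum(len(tr) for tr in trains)
    assert few <= base
    # with a huge offset no two spikes occur within 5 suprathreshold
    # adaptation time constants of each other (shorter, central constant)
    for tr in trains:
        if len(tr) > 1:
            assert np.diff(tr.spike_times).min() >= 5 * mean_fiber.tau_supra_cen


class _patched_b:
    """Temporarily replace the spike-triggered adaptation offset."""

    def __init__(self, b):
        self.b = b

    def __enter__(self):
        from easfiber.population import CENTRAL, PERIPHERAL
        self._orig = (PERIPHERAL, CENTRAL)
        object.__setattr__(PERIPHERAL, "b", self.b)
        object.__setattr__(CENTRAL, "b", self.b)

    def __exit__(self, *exc):
        object.__setattr__(self._orig[0], "b", 90.0)
        object.__setattr__(self._orig[1], "b", 90.0)


def test_burn_in_deterministic_rest(mean_fiber, rng, monkeypatch):
    """With zero noise the burn-in state converges to rest."""
    import easfiber.es_model as esm
    orig = esm.noise_batch
    monkeypatch.setattr(esm, "noise_batch",
                        lambda rng, k, n, dt, s, a: np.zeros((k, n)))
    start = ESState(V_per=-60.0, V_cen=-60.0,
                    I_supra_per=50.0, I_supra_cen=50.0)
    state = burn_in(mean_fiber, start, duration=40e-3, rng=rng)
    longer = burn_in(mean_fiber, start, duration=80e-3, rng=rng)
    # converged to the deterministic quiescent point near rest
    assert state.V_per == pytest.approx(longer.V_per, abs=1e-3)
    assert abs(state.V_per + 80.0) < 1.0
    assert abs(state.I_supra_per) < 5.0
    monkeypatch.setattr(esm, "noise_batch", orig)


def test_burn_in_stochastic_and_stationary(mean_fiber):
    """Independent noise gives distinct states; the V distribution is
    stationary between 20 ms and 40 ms of burn-in."""
    s1 = burn_in(mean_fiber, rng=np.random.default_rng(1))
    s2 = burn_in(mean_fiber, rng=np.random.default_rng(2))
    assert s1.V_per != s2.V_per
    rng = np.random.default_rng(3)
    v20 = [burn_in(mean_fiber, duration=20e-3, rng=rng).V_per
           for _ in range(120)]
    v40 = [burn_in(mean_fiber, duration=40e-3, rng=rng).V_per
           for _ in range(120)]
    assert stats.ks_2samp(v20, v40).pvalue > 0.01


def test_polarity_swap_switches_spiking_neuron(mean_fiber, rng):
    """Cathodic pulses fire the peripheral neuron, anodic the central."""
    for pol, neuron in (("cathodic", 0), ("anodic", 1)):
        w = monophasic_pulse(3.0, 26e-6, pol)
        d_per, d_cen = electric_drive(w)
        train, which = integrate_fiber(mean_fiber, d_per, d_cen, ESState(),
                                       rng, return_attribution=True)
        assert len(train) >= 1
        assert which[0] == neuron


def test_subthreshold_silent_without_noise(mean_fiber):
    """Far-subthreshold stimulation with zero noise never spikes."""
    from easfiber.es_model import _run_batch
    w = monophasic_pulse(0.1, 26e-6, "cathodic")
    d_per, d_cen = electric_drive(w)
    times, _, _ = _run_batch(mean_fiber, d_per, d_cen, 5,
                             np.random.default_rng(0), 1e-6, noise=False)
    assert all(len(t) == 0 for t in times)


@pytest.fixture(scope="module")
def cathodic_fit(mean_fiber):
    rng = np.random.default_rng(777)
    cfg = ex.ExperimentConfig()
    make = lambda a: monophasic_pulse(a, 26e-6, "cathodic")
    fit, curve = ex.fit_threshold(mean_fiber, make, "es-alone", rng, cfg)
    return fit


def test_threshold_within_published_band(cathodic_fit):
    """26 us cathodic threshold of the mean fiber falls inside the
    population band -1.06 +/- 2*3.92 dB re 1 mA."""
    thr_db = 20 * np.log10(cathodic_fit.mu)
    assert -1.06 - 2 * 3.92 < thr_db < -1.06 + 2 * 3.92
    # and close to the population mean for the mean-parameter fiber
    assert abs(thr_db + 1.06) < 1.5


def test_fe_at_threshold_is_half(mean_fiber, cathodic_fit, rng):
    """Stimulating at the fitted threshold yields FE ~ 0.5."""
    w = monophasic_pulse(cathodic_fit.mu, 26e-6, "cathodic")
    trains = run_es_alone(mean_fiber, w, 100, rng)
    fe = firing_efficiency([t.spike_times for t in trains], 0.0, 3.5e-3)
    # 99.9 % binomial interval at n=100, p=0.5 is ~0.5 +/- 0.165
    assert 0.30 <= fe <= 0.70


def test_anodic_threshold_above_cathodic(mean_fiber, cathodic_fit):
    rng = np.random.default_rng(778)
    cfg = ex.ExperimentConfig()
    make = lambda a: monophasic_pulse(a, 26e-6, "anodic")
    fit_an, _ = ex.fit_threshold(mean_fiber, make, "es-alone", rng, cfg)
    assert fit_an.mu > cathodic_fit.mu


def test_euler_step_size_convergence(mean_fiber, cathodic_fit):
    """Halving the step changes the fitted threshold by < 1 %."""
    rng = np.random.default_rng(779)
    cfg = ex.ExperimentConfig(dt=0.5e-6)
    make = lambda a: monophasic_pulse(a, 26e-6, "cathodic", dt=0.5e-6)
    fit_half, _ = ex.fit_threshold(mean_fiber, make, "es-alone", rng, cfg)
    assert fit_half.mu == pytest.approx(cathodic_fit.mu, rel=0.01)
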