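import numpy as np
import pytest
from scipy import stats

from easfiber.response_stats import (BracketingError, FECurve, ThresholdFit,
                                     analytic_jitter, analytic_latency,
                                     dynamic_range, firing_efficiency,
                                     fit_fe_curve, interval_stats,
                                     latency_jitter, vector_strength)


# --- firing efficiency ------------------------------------------------------

def test_firing_efficiency_direct():
    trains = [np.array([1e-3])] * 50 + [np.array([])] * 50
    assert firing_efficiency(trains, 0.0, 3.5e-3, sr=0.0) == 0.5
    assert firing_efficiency([np.array([])] * 10, 0.0, 3.5e-3) == 0.0
    # SR correction: N=85 over M=100 windows at sr=100/s, T=3.5 ms
    trains = [np.array([1e-3])] * 85 + [np.array([])] * 15
    fe = firing_efficiency(trains, 0.0, 3.5e-3, sr=100.0)
    assert fe == pytest.approx((85 - 0.35 * 100) / 100)


# --- integrated-Gaussian fit ------------------------------------------------

def test_fit_recovers_parameters(rng):
    """Synthetic binomial FE data: mu recovered within 1 %, RS within
    1 % absolute (averaged over repeated draws)."""
    mu_t, sigma_t, n = 1.0, 0.06, 100
    mus, rss = [], []
    for _ in range(40):
        levels = np.linspace(0.65, 1.35, 10)
        p = stats.norm.cdf((levels - mu_t) / sigma_t)
        fe = rng.binomial(n, p) / n
        fit = fit_fe_curve(FECurve(levels, fe, n))
        mus.append(fit.mu)
        rss.append(fit.rs)
    assert np.mean(mus) == pytest.approx(mu_t, rel=0.01)
    assert np.mean(rss) == pytest.approx(sigma_t / mu_t, abs=0.01)


def test_fit_requires_bracketing():
    with pytest.raises(BracketingError):
        fit_fe_curve(FECurve(np.array([1.0, 1.1, 1.2, 1.3]),
                             np.array([0.5, 0.5, 0.5, 0.5]), 100))
    with pytest.raises(BracketingError):
        fit_fe_curve(FECurve(np.array([1.0]), np.array([0.5]), 100))


# --- dynamic range ----------------------------------------------------------

def test_dynamic_range_closed_form():
    fit = ThresholdFit(mu=1.0, sigma=0.0404, rs=0.0404, dr_db=np.nan)
    assert dynamic_range(fit) == pytest.approx(0.90, abs=0.01)
    zero = ThresholdFit(mu=1.0, sigma=0.0, rs=0.0, dr_db=np.nan)
    assert dynamic_range(zero) == 0.0
    # monotone in RS at fixed mu
    drs = [dynamic_range(ThresholdFit(1.0, s, s, np.nan))
           for s in (0.02, 0.05, 0.1, 0.2)]
    assert np.all(np.diff(drs) > 0)
    with pytest.warns(UserWarning, match="undefined"):
        assert np.isnan(dynamic_range(ThresholdFit(1.0, 1.0, 1.0, np.nan)))


# --- latency / jitter -------------------------------------------------------

def test_latency_jitter_degenerate_and_uniform(rng):
    lat, jit = latency_jitter([np.array([10.3e-3])], [10e-3], 3.5e-3)
    assert lat == pytest.approx(0.3e-3)
    assert jit == 0.0
    u = rng.uniform(0.0, 3.5e-3, 200_000)
    lat, jit = latency_jitter([np.sort(u)], [0.0], 3.5e-3)
    assert lat == pytest.approx(1.75e-3, rel=0.01)
    assert jit == pytest.approx(3.5e-3 / np.sqrt(12), rel=0.01)
    with pytest.warns(UserWarning, match="no spikes"):
        lat, jit = latency_jitter([np.array([])], [0.0], 3.5e-3)
    assert np.isnan(lat)


# --- vector strength --------------------------------------------------------

def test_vector_strength_exact_cases(rng):
    assert vector_strength(np.arange(10) / 250.0, 250.0) == pytest.approx(1.0)
    # four spikes at quadrature phases cancel exactly
    t = np.array([0.0, 0.25, 0.5, 0.75]) / 250.0
    assert vector_strength(t, 250.0) == pytest.approx(0.0, abs=1e-12)
    with pytest.warns(UserWarning):
        assert np.isnan(vector_strength(np.array([]), 250.0))


def test_vector_strength_rayleigh_scale(rng):
    """Uniform phases give VS of order 1/sqrt(N) (Rayleigh statistics)."""
    n = 1000
    vs = [vector_strength(rng.uniform(0.0, 1.0 / 250.0, n), 250.0)
          for _ in range(200)]
    # E[VS] = sqrt(pi)/2 / sqrt(N) for uniform phases
    expected = np.sqrt(np.pi) / 2 / np.sqrt(n)
    assert np.mean(vs) == pytest.approx(expected, rel=0.15)
    assert vector_strength(rng.uniform(0, 4e-3, 50), 250.0) <= 1.0


# --- analytic latency / jitter ----------------------------------------------

def test_analytic_limits_exact():
    T = 3.5e-3
    assert analytic_latency(0.0, T, 0.5, 0.11e-3) == 0.11e-3
    assert analytic_jitter(0.0, T, 0.5, 0.11e-3, 0.06e-3) == 0.06e-3
    assert analytic_latency(100.0, T, 0.0, 0.0) == pytest.approx(T / 2)
    assert analytic_jitter(100.0, T, 0.0, 0.0, 0.0) == pytest.approx(
        T / np.sqrt(12))
    # direct evaluation at mixed rates
    assert analytic_latency(100.0, T, 0.5, 0.11e-3) == pytest.approx(
        (0.35 * 1.75e-3 + 0.5 * 0.11e-3) / 0.85)


def test_analytic_jitter_matches_mixture_simulation(rng):
    """Brute-force mixture draw reproduces the closed-form SD within 1 %."""
    T, sr, n_e, l_e, j_e = 3.5e-3, 120.0, 0.5, 0.11e-3, 0.06e-3
    n_s = sr * T
    n = 1_000_000
    from_spont = rng.uniform(0, 1, n) < n_s / (n_s + n_e)
    samples = np.where(from_spont, rng.uniform(0, T, n),
                       rng.normal(l_e, j_e, n))
    assert samples.std() == pytest.approx(
        analytic_jitter(sr, T, n_e, l_e, j_e), rel=0.01)
    assert samples.mean() == pytest.approx(
        analytic_latency(sr, T, n_e, l_e), rel=0.01)


# --- interval statistics ----------------------------------------------------

def test_interval_stats_sr_correction(rng):
    """A purely spontaneous train has ~zero SR-corrected rate in any
    interval."""
    sr = 100.0
    t = np.sort(rng.uniform(0.0, 10.0, int(sr * 10)))
    out = interval_stats([t], {"I1": (1.0, 9.0)}, sr, 250.0)
    assert out[0].interval_id == "I1"
    assert out[0].rate == pytest.approx(0.0, abs=3 * np.sqrt(sr * 8) / 8)
    assert 0.0 <= out[0].vs <= 1.0
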