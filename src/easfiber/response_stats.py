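"""Response statistics: firing efficiency, threshold fits, timing measures.

Conventions follow the single-fiber electric-stimulation literature:

* firing efficiency (FE) is the spontaneous-rate-corrected spike
  probability per stimulus presentation,
  ``FE = (N - SR * T * M) / M`` with ``N`` the spike count in the
  analysis windows of duration ``T`` and ``M`` the number of windows;
* threshold and relative spread (RS) come from an integrated-Gaussian
  (probit) fit of the FE-level curve: threshold = mean ``mu`` (FE = 50 %),
  RS = ``sigma / mu``;
* dynamic range (DR) is the dB span between the 10 % and 90 % FE levels
  of the fitted curve, ``DR = 20 log10(L90 / L10)``;
* latency / jitter are the mean / standard deviation of spike times
  relative to the pulse onset, pooling *all* spikes inside the analysis
  window (not only the first), which is the convention under which the
  analytic mixture estimates below are exact;
* vector strength (VS) measures phase locking to the pulse rate.

The analytic latency/jitter estimates treat the windowed spikes as a
mixture of uniformly timed spontaneous spikes and evoked spikes with
mean ``L_E`` and SD ``J_E``; they hold when the two processes do not
interact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .spikes import SpikeTrain

__all__ = [
    "FECurve",
    "ThresholdFit",
    "IntervalStats",
    "firing_efficiency",
    "fit_fe_curve",
    "dynamic_range",
    "latency_jitter",
    "vector_strength",
    "analytic_latency",
    "analytic_jitter",
    "interval_stats",
    "DEFAULT_WINDOW",
]

#: Standard post-pulse analysis window (s).
DEFAULT_WINDOW = 3.5e-3

_Z90 = float(stats.norm.ppf(0.9))  # 1.2816


@dataclass
class FECurve:
    """Firing efficiency as a function of stimulus level.

    ``levels`` (mA) strictly increasing; ``fe`` dimensionless (may leave
    [0, 1] slightly after the spontaneous-rate correction); ``n_trials``
    per level; ``T`` analysis-window duration (s).
    """

    levels: np.ndarray
    fe: np.ndarray
    n_trials: np.ndarray
    T: float = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.fe = np.asarray(self.fe, dtype=float)
        self.n_trials = np.broadcast_to(
            np.asarray(self.n_trials, dtype=float), self.levels.shape).copy()
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if not np.all(np.isfinite(self.fe)):
            raise ValueError("firing efficiencies must be finite")


@dataclass
class ThresholdFit:
    """Integrated-Gaussian fit of an FE-level curve.

    ``mu`` threshold (mA, FE = 50 %), ``sigma`` spread (mA),
    ``rs = sigma/mu`` relative spread, ``dr_db`` dynamic range (dB).
    """

    mu: float
    sigma: float
    rs: float
    dr_db: float


class BracketingError(ValueError):
    """Raised when FE data do not bracket the threshold transition."""


def firing_efficiency(spike_trains, window_start: float,
                      T: float = DEFAULT_WINDOW, sr: float = 0.0,
                      M: int | None = None) -> float:
    """Spontaneous-rate-corrected firing efficiency.

    ``N`` is the total spike count within ``[window_start,
    window_start + T)`` across the given trains (one analysis window per
    train).  ``M`` defaults to the number of trains; the expected count
    of spontaneous spikes ``SR * T`` is subtracted per window.
    """
    if T <= 0:
        raise ValueError("window duration must be positive")
    trains = list(spike_trains)
    if M is None:
        M = len(trains)
    if M < 1:
        raise ValueError("need at least one presentation")
    n = 0
    for tr in trains:
        t = tr.spike_times if isinstance(tr, SpikeTrain) else np.asarray(tr)
        n += int(np.count_nonzero((t >= window_start) & (t < window_start + T)))
    return (n - sr * T * len(trains)) / M


def _probit(levels: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return stats.norm.cdf((levels - mu) / sigma)


def fit_fe_curve(curve: FECurve, require_bracketing: bool = True,
                 ) -> ThresholdFit:
    """Weighted least-squares integrated-Gaussian fit ``FE(L) = Phi((L-mu)/sigma)``.

    Weights follow the binomial variance of the fitted curve
    (quasi-likelihood iteration with a small variance floor, so levels
    with FE at 0 or 1 neither dominate nor vanish).  Raises
    :class:`BracketingError` when the data do not span the transition
    (minimum FE above 0.2 or maximum below 0.8).
    """
    L, fe, n = curve.levels, curve.fe, curve.n_trials
    if len(L) < 4:
        raise BracketingError("need at least 4 levels to fit an FE curve")
    if require_bracketing and (fe.min() > 0.2 or fe.max() < 0.8):
        raise BracketingError(
            "FE data do not bracket the transition (need FE below 0.2 and "
            "above 0.8); widen the level sweep")
    # initial guess: interpolate the 50 % crossing, slope from 16-84 span
    order = np.argsort(L)
    mu0 = float(np.interp(0.5, np.clip(fe[order], 0.0, 1.0), L[order]))
    if not np.isfinite(mu0) or mu0 <= L.min() or mu0 >= L.max():
        mu0 = float(0.5 * (L.min() + L.max()))
    sigma0 = max(0.05 * mu0, 0.25 * (L.max() - L.min()) / 4.0)

    def residuals(theta):
        mu, log_sigma = theta
        sigma = np.exp(log_sigma)
        p = _probit(L, mu, sigma)
        var = np.maximum(p * (1.0 - p), 0.01) / n
        return (fe - p) / np.sqrt(var)

    sol = optimize.least_squares(residuals, [mu0, np.log(sigma0)],
                                 method="lm", max_nfev=2000)
    mu, sigma = float(sol.x[0]), float(np.exp(sol.x[1]))
    if mu <= 0:
        raise BracketingError("fitted threshold is non-positive; the level "
                              "sweep does not constrain the transition")
    fit = ThresholdFit(mu=mu, sigma=sigma, rs=sigma / mu, dr_db=np.nan)
    fit.dr_db = dynamic_range(fit)
    return fit


def dynamic_range(fit: ThresholdFit) -> float:
    """DR in dB between the 10 % and 90 % FE levels of the fitted curve."""
    l10 = fit.mu - _Z90 * fit.sigma
    l90 = fit.mu + _Z90 * fit.sigma
    if l10 <= 0:
        warnings.warn("10 % FE level is non-positive; dynamic range "
                      "undefined", stacklevel=2)
        return np.nan
    return 20.0 * np.log10(l90 / l10)


def _as_train_list(spike_trains) -> list:
    """Normalize input to a list of trains/arrays (handles a bare train)."""
    if isinstance(spike_trains, (SpikeTrain, np.ndarray)):
        return [spike_trains]
    return list(spike_trains)


def latency_jitter(spike_trains, pulse_onsets, T: float = DEFAULT_WINDOW,
                   ) -> tuple[float, float]:
    """Mean latency and jitter (SD) of all spikes in post-onset windows.

    Latencies of *all* spikes falling within ``T`` after each pulse onset
    are pooled across onsets and trains.  Returns ``(nan, nan)`` with a
    warning when no spikes fall into any window.
    """
    onsets = np.atleast_1d(np.asarray(pulse_onsets, dtype=float))
    lat = []
    for tr in _as_train_list(spike_trains):
        t = tr.spike_times if isinstance(tr, SpikeTrain) else np.asarray(tr)
        for onset in onsets:
            sel = t[(t >= onset) & (t < onset + T)]
            lat.append(sel - onset)
    lat = np.concatenate(lat) if lat else np.zeros(0)
    if len(lat) == 0:
        warnings.warn("no spikes in any analysis window; latency/jitter "
                      "undefined", stacklevel=2)
        return np.nan, np.nan
    return float(lat.mean()), float(lat.std())


def vector_strength(spike_times, pulse_rate: float) -> float:
    """Phase-locking index in [0, 1] relative to the pulse rate."""
    t = (spike_times.spike_times if isinstance(spike_times, SpikeTrain)
         else np.asarray(spike_times, dtype=float))
    if len(t) == 0:
        warnings.warn("vector strength undefined for empty spike train",
                      stacklevel=2)
        return np.nan
    phase = 2.0 * np.pi * pulse_rate * t
    return float(np.hypot(np.sin(phase).sum(), np.cos(phase).sum()) / len(t))


def analytic_latency(sr: float, T: float, N_E: float, L_E: float) -> float:
    """Expected mean latency of a non-interacting spontaneous + evoked mixture.

    ``N_S = sr * T`` spontaneous spikes are uniform on the window
    (mean ``T/2``); ``N_E`` evoked spikes have mean latency ``L_E``.
    """
    n_s = sr * T
    if n_s < 0 or N_E < 0:
        raise ValueError("spike counts must be non-negative")
    if n_s + N_E == 0:
        warnings.warn("no spikes expected; latency undefined", stacklevel=2)
        return np.nan
    return (n_s * (T / 2.0) + N_E * L_E) / (n_s + N_E)


def analytic_jitter(sr: float, T: float, N_E: float, L_E: float,
                    J_E: float) -> float:
    """Expected latency SD of the same mixture (law of total variance)."""
    n_s = sr * T
    if n_s + N_E == 0:
        warnings.warn("no spikes expected; jitter undefined", stacklevel=2)
        return np.nan
    w_s = n_s / (n_s + N_E)
    w_e = N_E / (n_s + N_E)
    var = (w_s * T**2 / 12.0 + w_e * J_E**2
           + w_s * w_e * (T / 2.0 - L_E) ** 2)
    return float(np.sqrt(var))


@dataclass
class IntervalStats:
    """Per-interval response statistics.

    ``rate`` is SR-corrected (spikes/s); ``latency`` / ``jitter`` are
    computed in post-pulse windows restricted to the interval; ``vs`` is
    the vector strength of in-interval spikes.
    """

    interval_id: str
    rate: float
    latency: float
    jitter: float
    vs: float


def interval_stats(spike_trains, intervals, sr: float, pulse_rate: float,
                   pulse_onsets=None, T: float = DEFAULT_WINDOW,
                   ) -> list[IntervalStats]:
    """Compute rate/latency/jitter/VS for each named analysis interval.

    ``intervals`` maps names to ``(start, stop)`` tuples (s).  Spikes are
    pooled across the given trains (repeated presentations); the rate is
    averaged per presentation and corrected for the spontaneous rate.
    ``pulse_onsets`` defaults to a regular grid at ``pulse_rate`` from
    t = 0.
    """
    trains = _as_train_list(spike_trains)
    all_t = [tr.spike_times if isinstance(tr, SpikeTrain) else np.asarray(tr)
             for tr in trains]
    t_max = max((t[-1] for t in all_t if len(t)),
                default=max(stop for _, stop in intervals.values()))
    t_max = max(t_max, max(stop for _, stop in intervals.values()))
    if pulse_onsets is None:
        pulse_onsets = np.arange(0.0, t_max, 1.0 / pulse_rate)
    pulse_onsets = np.asarray(pulse_onsets, dtype=float)
    out = []
    for name, (start, stop) in intervals.items():
        dur = stop - start
        n_spk = sum(int(np.count_nonzero((t >= start) & (t < stop)))
                    for t in all_t)
        rate = n_spk / (dur * len(trains)) - sr
        onsets = pulse_onsets[(pulse_onsets >= start)
                              & (pulse_onsets + T <= stop + T)]
        onsets = onsets[onsets < stop]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            lat, jit = latency_jitter(trains, onsets, T)
            in_int = np.concatenate([t[(t >= start) & (t < stop)]
                                     for t in all_t]) if all_t else np.zeros(0)
            vs = vector_strength(in_int, pulse_rate)
        out.append(IntervalStats(interval_id=name, rate=rate, latency=lat,
                                 jitter=jit, vs=vs))
    return out
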