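"""End-to-end experiment protocols and population sweeps.

Three standard experiments are provided:

1. **Monophasic single pulses** (electric-only, acoustically insensitive
   fibers): thresholds, relative spread, latency and jitter for 26 µs and
   39 µs cathodic/anodic pulses.
2. **Biphasic pulse trains, electric-only** (acoustically sensitive
   fibers): first-pulse thresholds and dynamic ranges for the ES-alone,
   uncoupled and coupled model variants; latency/jitter at threshold
   compared to the analytic non-interacting estimates; nonparametric
   tests split at SR = 50.
3. **Combined electric-acoustic stimulation**: 250 pps trains plus
   broadband noise; per-interval EA-E differences in rate, jitter and
   vector strength, and sustained-rate addition ratios.

All runners are deterministic functions of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import as_surrogate, eas_coupling, es_model, response_stats
from .population import FiberParams, sample_population
from .response_stats import (BracketingError, FECurve, ThresholdFit,
                             firing_efficiency, fit_fe_curve, latency_jitter)
from .stimuli import (AcousticStimulusSpec, ElectricWaveform,
                      biphasic_pulse_train, monophasic_pulse)

__all__ = [
    "ExperimentConfig",
    "estimate_fe_curve",
    "fit_threshold",
    "run_experiment1",
    "run_experiment2",
    "run_experiment3",
]

VARIANTS = ("es-alone", "as-alone", "uncoupled", "coupled", "alternative")


@dataclass
class ExperimentConfig:
    """Configuration of one experiment run; defaults follow the standard
    protocols (150 fibers, 100 trials per level, 250 pps trains, 26 dB
    hearing loss)."""

    experiment_id: int = 1
    n_lsr: int = 30
    n_msr: int = 30
    n_hsr: int = 90
    seed: int = 0
    dt: float = 1e-6
    burn_in: float = es_model.DEFAULT_BURN_IN
    hearing_loss: float = 26.0
    T: float = response_stats.DEFAULT_WINDOW
    # threshold-estimation protocol
    n_trials_fe: int = 100
    n_bracket_trials: int = 24
    n_levels: int = 10
    level_span: float = 0.35
    start_level: float = 1.0
    # experiment 1
    phase_widths: tuple = (26e-6, 39e-6)
    polarities: tuple = ("cathodic", "anodic")
    # experiment 2 / 3 pulse trains
    pulse_rate: float = 250.0
    train_phase_width: float = 40e-6
    train_duration: float = 0.3
    n_train_presentations: int = 20
    #: presentations per level for train FE curves (protocol: at least 15;
    #: 40 keeps the fitted sigma/DR estimator within a few % of truth)
    n_fe_presentations: int = 40
    variants: tuple = ("es-alone", "uncoupled", "coupled")
    # experiment 3
    as_durations: tuple = (0.1, 0.2, 0.3)
    as_level_range: tuple = (70.0, 100.0)
    as_level_step: float = 5.0
    as_rate_criterion: float = 2.5
    n_es_levels: int = 4
    n_reps_exp3: int = 2

    def population(self, rng: np.random.Generator) -> list[FiberParams]:
        return sample_population(rng, self.n_lsr, self.n_msr, self.n_hsr,
                                 self.hearing_loss)


# ---------------------------------------------------------------------------
# firing-efficiency evaluation per model variant


def _spont_spikes(fiber, window, rng):
    return as_surrogate.run_as_alone(fiber, None, window, rng).spike_times


def _fe_spike_arrays(fiber, wave, variant, n_reps, rng, burn_in):
    """Spike-time arrays (one per presentation) for an FE evaluation."""
    if variant == "es-alone":
        trains = es_model.run_es_alone(fiber, wave, n_reps, rng, burn_in)
        return [tr.spike_times for tr in trains]
    if variant == "uncoupled":
        trains = es_model.run_es_alone(fiber, wave, n_reps, rng, burn_in)
        out = []
        for tr in trains:
            spont = _spont_spikes(fiber, (0.0, wave.duration), rng)
            out.append(np.sort(np.concatenate(
                [tr.spike_times[tr.spike_times >= 0.0], spont])))
        return out
    if variant == "coupled":
        trains = eas_coupling.run_coupled_batch(fiber, wave, None, rng,
                                                n_reps,
                                                burn_in_duration=burn_in)
        return [tr.spike_times for tr in trains]
    if variant == "alternative":
        trains = eas_coupling.run_alternative_batch(fiber, wave, None, rng,
                                                    n_reps,
                                                    burn_in_duration=burn_in)
        return [tr.spike_times for tr in trains]
    raise ValueError(f"unknown variant {variant!r}")


def _fe_at_level(fiber, make_wave, level, variant, n_reps, rng, T, sr,
                 burn_in):
    arrays = _fe_spike_arrays(fiber, make_wave(level), variant, n_reps, rng,
                              burn_in)
    return firing_efficiency(arrays, 0.0, T, sr=sr)


def estimate_fe_curve(fiber, make_wave, variant, rng,
                      config: ExperimentConfig, span: float | None = None,
                      ) -> FECurve:
    """Adaptive FE-level curve measurement.

    A factor-2 search brackets the 50 % FE crossing, a short bisection
    localizes it, and the final curve uses equally spaced levels across a
    symmetric span around the crossing with the full trial count.
    """
    sr = 0.0 if variant == "es-alone" else fiber.sr
    if span is None:
        span = config.level_span
    nb = config.n_bracket_trials

    def fe(level, n):
        return _fe_at_level(fiber, make_wave, level, variant, n, rng,
                            config.T, sr, config.burn_in)

    lo = hi = config.start_level
    fe_lo = fe_hi = fe(config.start_level, nb)
    for _ in range(14):
        if fe_hi >= 0.5:
            break
        hi *= 2.0
        fe_hi = fe(hi, nb)
    else:
        raise BracketingError("no suprathreshold level found")
    for _ in range(14):
        if fe_lo < 0.5:
            break
        lo /= 2.0
        fe_lo = fe(lo, nb)
    else:
        raise BracketingError("no subthreshold level found")
    if hi / lo > 2.0 * (1 + 1e-9):
        # bring the bracket back to a single factor-2 interval
        while hi / lo > 2.0 * (1 + 1e-9):
            mid = np.sqrt(lo * hi)
            if fe(mid, nb) >= 0.5:
                hi = mid
            else:
                lo = mid
    for _ in range(5):
        mid = np.sqrt(lo * hi)
        if fe(mid, nb) >= 0.5:
            hi = mid
        else:
            lo = mid
    mu_hat = np.sqrt(lo * hi)
    levels = np.linspace(mu_hat * (1.0 - span), mu_hat * (1.0 + span),
                         config.n_levels)
    fes = np.array([fe(lv, config.n_trials_fe) for lv in levels])
    return FECurve(levels=levels, fe=fes, n_trials=config.n_trials_fe,
                   T=config.T)


def fit_threshold(fiber, make_wave, variant, rng, config: ExperimentConfig,
                  ) -> tuple[ThresholdFit, FECurve]:
    """FE-curve fit with automatic widening of the level sweep."""
    span = config.level_span
    last_exc: Exception | None = None
    for _ in range(3):
        curve = estimate_fe_curve(fiber, make_wave, variant, rng, config,
                                  span=span)
        try:
            return fit_fe_curve(curve), curve
        except BracketingError as exc:
            last_exc = exc
            span *= 1.6
    raise BracketingError(f"could not bracket FE transition: {last_exc}")


# ---------------------------------------------------------------------------
# experiment 1: monophasic single pulses


def run_experiment1(config: ExperimentConfig,
                    fibers: list[FiberParams] | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Thresholds, RS, latency and jitter for monophasic single pulses.

    Returns (per-fiber table, population summary in mean +/- SD layout).
    """
    root = np.random.SeedSequence([config.seed, 1])
    pop_rng = np.random.default_rng(root.spawn(1)[0])
    if fibers is None:
        fibers = config.population(pop_rng)
    rows = []
    for i, fiber in enumerate(fibers):
        for width in config.phase_widths:
            for pol in config.polarities:
                rng = np.random.default_rng(
                    np.random.SeedSequence(
                        [config.seed, 1, i, int(width * 1e9),
                         0 if pol == "cathodic" else 1]))

                def make_wave(level, _w=width, _p=pol):
                    return monophasic_pulse(level, _w, _p, config.dt,
                                            _w + config.T)

                fit, _ = fit_threshold(fiber, make_wave, "es-alone", rng,
                                       config)
                trains = es_model.run_es_alone(
                    fiber, make_wave(fit.mu), config.n_trials_fe, rng,
                    config.burn_in)
                lat, jit = latency_jitter(
                    [tr.spike_times for tr in trains], [0.0], config.T)
                rows.append(dict(
                    fiber_id=i, sr_group=fiber.sr_group, sr=fiber.sr,
                    phase_width_us=width * 1e6, polarity=pol,
                    threshold_mA=fit.mu,
                    threshold_db=20.0 * np.log10(fit.mu),
                    rs_pct=100.0 * fit.rs, dr_db=fit.dr_db,
                    latency_s=lat, jitter_s=jit))
    df = pd.DataFrame(rows)
    summary = (df.groupby(["phase_width_us", "polarity"])
               [["threshold_db", "rs_pct", "latency_s", "jitter_s"]]
               .agg(["mean", "std"]))
    return df, summary


# ---------------------------------------------------------------------------
# experiment 2: biphasic trains, electric only


def _first_pulse_wave(config: ExperimentConfig):
    """Single leading pulse of the 250 pps biphasic train plus analysis
    window; sufficient for first-pulse firing efficiency."""
    period = 1.0 / config.pulse_rate

    def make_wave(level):
        return biphasic_pulse_train(
            level, config.train_phase_width, "cathodic", config.pulse_rate,
            train_duration=period, dt=config.dt,
            total_duration=2 * config.train_phase_width + config.T)

    return make_wave


def _train_wave(config: ExperimentConfig, level: float,
                train_duration: float | None = None) -> ElectricWaveform:
    dur = config.train_duration if train_duration is None else train_duration
    return biphasic_pulse_train(level, config.train_phase_width, "cathodic",
                                config.pulse_rate, train_duration=dur,
                                dt=config.dt,
                                total_duration=dur + config.T)


def _all_pulse_fe(fiber, variant, level, n_pres, rng, config) -> float:
    """Train-wide firing efficiency: one analysis window per pulse,
    ``M`` = total pulses over all presentations (SR-corrected)."""
    wave = _train_wave(config, level)
    arrays = _fe_spike_arrays(fiber, wave, variant, n_pres, rng,
                              config.burn_in)
    sr = 0.0 if variant == "es-alone" else fiber.sr
    n_pulses = len(wave.pulse_onsets)
    n = 0
    for t in arrays:
        for onset in wave.pulse_onsets:
            n += int(np.count_nonzero((t >= onset) & (t < onset + config.T)))
    M = n_pres * n_pulses
    return (n - sr * config.T * M) / M


def _find_fe50_level(fiber, variant, start, rng, config,
                     n_pres: int = 2) -> float:
    """Level at which the train-wide FE crosses 50 % (geometric bisection).

    Timing statistics are evaluated at this level: with one analysis
    window per pulse, 50 % FE corresponds to 0.5 expected evoked spikes
    per window, matching the analytic latency/jitter estimates.  The
    search starts from the first-pulse threshold, which is always close.
    """
    lo, hi = start / 1.3, start * 1.3
    fe_lo = _all_pulse_fe(fiber, variant, lo, n_pres, rng, config)
    fe_hi = _all_pulse_fe(fiber, variant, hi, n_pres, rng, config)
    for _ in range(6):
        if fe_hi >= 0.5:
            break
        lo, fe_lo = hi, fe_hi
        hi *= 1.3
        fe_hi = _all_pulse_fe(fiber, variant, hi, n_pres, rng, config)
    for _ in range(6):
        if fe_lo < 0.5:
            break
        hi, fe_hi = lo, fe_lo
        lo /= 1.3
        fe_lo = _all_pulse_fe(fiber, variant, lo, n_pres, rng, config)
    for _ in range(4):
        mid = np.sqrt(lo * hi)
        if _all_pulse_fe(fiber, variant, mid, n_pres, rng, config) >= 0.5:
            hi = mid
        else:
            lo = mid
    return float(np.sqrt(lo * hi))


def run_experiment2(config: ExperimentConfig,
                    fibers: list[FiberParams] | None = None,
                    ) -> tuple[pd.DataFrame, dict]:
    """First-pulse thresholds/DRs and at-threshold timing for pulse trains.

    Returns the per-fiber results table and a dict of population
    statistics (Mann-Whitney tests across variants, Wilcoxon tests of
    latency/jitter deviations from the analytic estimates per SR group,
    and regressions of coupled-minus-ES differences on SR and ARP).
    """
    root = np.random.SeedSequence([config.seed, 2])
    pop_rng = np.random.default_rng(root.spawn(1)[0])
    if fibers is None:
        fibers = config.population(pop_rng)
    make_wave = _first_pulse_wave(config)
    rows = []
    for i, fiber in enumerate(fibers):
        es_lat = es_jit = np.nan
        for variant in config.variants:
            rng = np.random.default_rng(np.random.SeedSequence(
                [config.seed, 2, i, VARIANTS.index(variant)]))
            cfg = dataclasses.replace(config,
                                      n_trials_fe=config.n_fe_presentations)
            fit, _ = fit_threshold(fiber, make_wave, variant, rng, cfg)
            # timing at the train-wide 50 % FE level (0.5 evoked spikes
            # expected per post-pulse window)
            level50 = _find_fe50_level(fiber, variant, fit.mu, rng, config)
            wave = _train_wave(config, level50)
            n_pres = max(4, config.n_train_presentations // 4)
            arrays = _fe_spike_arrays(fiber, wave, variant, n_pres, rng,
                                      config.burn_in)
            lat, jit = latency_jitter(arrays, wave.pulse_onsets, config.T)
            if variant == "es-alone":
                es_lat, es_jit = lat, jit
            sr_eff = 0.0 if variant == "es-alone" else fiber.sr
            lat_est = response_stats.analytic_latency(
                sr_eff, config.T, 0.5, es_lat)
            jit_est = response_stats.analytic_jitter(
                sr_eff, config.T, 0.5, es_lat, es_jit)
            rows.append(dict(
                fiber_id=i, sr_group=fiber.sr_group, sr=fiber.sr,
                t_abs_s=fiber.t_abs, variant=variant,
                threshold_mA=fit.mu, rs_pct=100.0 * fit.rs,
                dr_db=fit.dr_db, latency_s=lat, jitter_s=jit,
                latency_est_s=lat_est, jitter_est_s=jit_est))
    df = pd.DataFrame(rows)
    stats = _experiment2_stats(df)
    return df, stats


def _experiment2_stats(df: pd.DataFrame) -> dict:
    out: dict = {"mean_threshold_mA": {}, "mean_dr_db": {}, "tests": {},
                 "wilcoxon": {}, "regressions": {}}
    for variant, grp in df.groupby("variant"):
        out["mean_threshold_mA"][variant] = float(grp["threshold_mA"].mean())
        out["mean_dr_db"][variant] = float(grp["dr_db"].mean())
    pivot_thr = df.pivot(index="fiber_id", columns="variant",
                         values="threshold_mA")
    pivot_dr = df.pivot(index="fiber_id", columns="variant", values="dr_db")
    pairs = [("coupled", "es-alone"), ("coupled", "uncoupled"),
             ("uncoupled", "es-alone")]
    for a, b in pairs:
        if a in pivot_thr and b in pivot_thr:
            for name, piv in (("threshold", pivot_thr), ("dr", pivot_dr)):
                u, p = sps.mannwhitneyu(piv[a].dropna(), piv[b].dropna(),
                                        alternative="two-sided")
                out["tests"][f"{name}:{a}-vs-{b}"] = {"U": float(u),
                                                      "p": float(p)}
    # deviations of timing from the analytic non-interacting estimates
    for variant in ("uncoupled", "coupled"):
        sub = df[df["variant"] == variant]
        if not len(sub):
            continue
        for meas, est in (("latency_s", "latency_est_s"),
                          ("jitter_s", "jitter_est_s")):
            for gname, gsel in (("SR<=50", sub["sr"] <= 50),
                                ("SR>50", sub["sr"] > 50)):
                dev = (sub.loc[gsel, meas] - sub.loc[gsel, est]).dropna()
                if len(dev) >= 5 and np.any(dev != 0):
                    w, p = sps.wilcoxon(dev)
                    out["wilcoxon"][f"{variant}:{meas}:{gname}"] = {
                        "p": float(p), "n": int(len(dev)),
                        "median": float(dev.median())}
    if {"coupled", "es-alone"} <= set(pivot_thr.columns):
        meta = df[df["variant"] == "coupled"].set_index("fiber_id")
        d_thr = pivot_thr["coupled"] - pivot_thr["es-alone"]
        d_dr = pivot_dr["coupled"] - pivot_dr["es-alone"]
        for dname, diff in (("threshold_diff", d_thr), ("dr_diff", d_dr)):
            for xname in ("sr", "t_abs_s"):
                x = meta.loc[diff.index, xname]
                ok = diff.notna()
                res = sps.linregress(x[ok], diff[ok])
                out["regressions"][f"{dname}-vs-{xname}"] = {
                    "slope": float(res.slope), "p": float(res.pvalue),
                    "r": float(res.rvalue)}
    return out


# ---------------------------------------------------------------------------
# experiment 3: combined electric-acoustic stimulation


def _exp3_intervals(onset: float, offset: float) -> dict:
    return {
        "I1": (onset - 0.050, onset),
        "I2": (onset, onset + 0.020),
        "I3": (offset - 0.030, offset),
        "I4": (offset, offset + 0.020),
        "I5": (offset + 0.050, offset + 0.150),
        "I6": (offset + 0.150, offset + 0.250),
    }


def _select_as_level(fiber: FiberParams, config: ExperimentConfig) -> float:
    """Lowest level whose sustained driven rate exceeds the criterion."""
    lo, hi = config.as_level_range
    for level in np.arange(lo, hi + 0.5 * config.as_level_step,
                           config.as_level_step):
        if (as_surrogate.driven_spike_rate(level, fiber)
                >= config.as_rate_criterion * fiber.sr):
            return float(level)
    return float(hi)


def _run_condition(fiber, variant, elec, spec, rng, n_reps, burn_in):
    """Spike-time arrays for one (fiber, variant, condition)."""
    runner = {"uncoupled": eas_coupling.run_uncoupled,
              "coupled": eas_coupling.run_coupled,
              "alternative": eas_coupling.run_alternative}[variant]
    out = []
    for k in range(n_reps):
        tr = runner(fiber, elec, spec, rng, burn_in_duration=burn_in)
        out.append(tr.spike_times)
    return out


def run_experiment3(config: ExperimentConfig,
                    fibers: list[FiberParams] | None = None,
                    variants: tuple = ("uncoupled", "coupled"),
                    ) -> pd.DataFrame:
    """Per-interval EA-E differences and I3 rate-addition ratios.

    For each fiber the electric level sweep spans its fitted dynamic
    range (four uniform draws between the 10 % and 90 % FE levels of the
    coupled-model first-pulse fit); the acoustic level is the lowest one
    in the configured range whose sustained driven rate exceeds the
    spontaneous rate by the configured factor.  The electric-only and
    combined conditions are run with matched random seeds for paired
    differences.
    """
    root = np.random.SeedSequence([config.seed, 3])
    pop_rng = np.random.default_rng(root.spawn(1)[0])
    if fibers is None:
        fibers = config.population(pop_rng)
    make_wave = _first_pulse_wave(config)
    rows = []
    for i, fiber in enumerate(fibers):
        fit_rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 3, i, 101]))
        cfg = dataclasses.replace(config,
                                  n_trials_fe=config.n_fe_presentations)
        try:
            fit, _ = fit_threshold(fiber, make_wave, "coupled", fit_rng, cfg)
        except BracketingError:
            continue
        z = response_stats._Z90
        l10 = max(fit.mu - z * fit.sigma, 0.05 * fit.mu)
        l90 = fit.mu + z * fit.sigma
        lev_rng = np.random.default_rng(np.random.SeedSequence(
            [config.seed, 3, i, 102]))
        es_levels = lev_rng.uniform(l10, l90, config.n_es_levels)
        as_dur = config.as_durations[i % len(config.as_durations)]
        as_level = _select_as_level(fiber, config)
        onset = 0.050
        offset = onset + as_dur
        train_dur = offset + 0.250
        spec = AcousticStimulusSpec(level=as_level, onset=onset,
                                    duration=as_dur)
        intervals = _exp3_intervals(onset, offset)
        # acoustic-only reference: zero-amplitude electric trace so that
        # the simulation window covers all analysis intervals
        elec_zero = ElectricWaveform(dt=config.dt, samples=np.zeros(
            int(round(train_dur / config.dt))))
        arr_a_by_variant = {}
        for variant in variants:
            arr_a_by_variant[variant] = _run_condition(
                fiber, variant, elec_zero, spec,
                np.random.default_rng(np.random.SeedSequence(
                    [config.seed, 3, i, variants.index(variant), 7])),
                config.n_reps_exp3, config.burn_in)
        for j, level in enumerate(es_levels):
            elec = _train_wave(config, level, train_duration=train_dur)
            for variant in variants:
                seed = [config.seed, 3, i, j, variants.index(variant)]
                arr_ea = _run_condition(
                    fiber, variant, elec, spec,
                    np.random.default_rng(np.random.SeedSequence(seed + [0])),
                    config.n_reps_exp3, config.burn_in)
                arr_e = _run_condition(
                    fiber, variant, elec, None,
                    np.random.default_rng(np.random.SeedSequence(seed + [0])),
                    config.n_reps_exp3, config.burn_in)
                arr_a = arr_a_by_variant[variant]
                onsets = elec.pulse_onsets
                st_ea = response_stats.interval_stats(
                    arr_ea, intervals, fiber.sr, config.pulse_rate, onsets,
                    config.T)
                st_e = response_stats.interval_stats(
                    arr_e, intervals, fiber.sr, config.pulse_rate, onsets,
                    config.T)
                st_a = response_stats.interval_stats(
                    arr_a, intervals, fiber.sr, config.pulse_rate, onsets,
                    config.T)
                for s_ea, s_e, s_a in zip(st_ea, st_e, st_a):
                    rows.append(dict(
                        fiber_id=i, sr_group=fiber.sr_group, sr=fiber.sr,
                        variant=variant, es_level_mA=level,
                        as_level_db=as_level, as_duration_s=as_dur,
                        interval=s_ea.interval_id,
                        rate_ea=s_ea.rate, rate_e=s_e.rate, rate_a=s_a.rate,
                        d_rate=s_ea.rate - s_e.rate,
                        d_jitter=s_ea.jitter - s_e.jitter,
                        d_vs=s_ea.vs - s_e.vs))
    return pd.DataFrame(rows)
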