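# Methods

`easfiber` simulates spike times of single auditory nerve fibers (ANFs)
under electric stimulation (ES, cochlear-implant current pulses),
acoustic stimulation (AS), and combined electric-acoustic stimulation
(EAS), with the goal of studying the interaction between the two
modalities that is mediated by the refractoriness of the fiber.

## The electric-stimulation model

Each fiber's peripheral and central process is a point neuron of the
adaptive exponential integrate-and-fire family.  The membrane voltage
V (mV) of each neuron obeys

    C dV/dt = h(V) − I_sub − I_supra + I_noise + I_stim
    h(V)    = −g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T)

with subthreshold and suprathreshold adaptation currents

    τ_sub   dI_sub/dt   = a_sub  (V − E_L) − I_sub
    τ_supra dI_supra/dt = a_supra(V − E_L) − I_supra

A stimulus current waveform I(t) (mA, cathodic negative) is split per
sample into its cathodic part I⁻ = min(I, 0) and anodic part
I⁺ = max(I, 0) and weighted into the two neurons:

    I_stim_peripheral = −(I⁻ + β I⁺)        (cathodic depolarizes)
    I_stim_central    =  β I⁻ + I⁺          (anodic depolarizes)

with β = 0.75 the inhibitory compression.  A spike is emitted when
either membrane reaches V_peak = 24 mV; then both neurons are reset to
V_reset = −84 mV, both suprathreshold currents jump by b = 90 µA
(relative refractoriness), and all external drive — electric and
synaptic — is gated off for the dead time t_dead (absolute
refractoriness).  Intrinsic noise continues during the dead time; it is
a property of the membrane, not of the stimulation.

The membrane noise I_noise has a 1/f^α power spectrum (α = 0.80) and
per-neuron amplitude σ_noise (8.70 µA peripheral, 11.89 µA central).  It
is synthesized in the frequency domain (complex Gaussian spectrum shaped
by f^(−α/2), DC zeroed) and each realization is rescaled so its sample
variance equals σ_noise² exactly.  The two neurons receive independent
noise; the per-neuron amplitudes imply independent sources.

Fixed constants (peripheral / central): g_L = 1.1 / 2.7 mS,
Δ_T = 10.0 / 3.0 mV, E_L = −80 mV, V_T = −70 mV (the "threshold
potential" of the exponential term; V_peak is the separate detection
threshold), τ_sub = 250 µs, a_sub = 2.0 mS, a_supra = 3.0 mS, baseline
τ_supra0 = 4500 / 2500 µs.

### Numerics

Forward Euler at dt = 1 µs (all time constants ≥ 250 µs); the test suite
verifies that halving the step moves fitted thresholds by < 1 %.  The
exponential argument is clamped at 25 and the voltage at V_peak, the
standard exponential-IF overflow handling: once the upswing is under
way the spike time is set by the first sample at V ≥ V_peak.  Spikes are
suppressed (and drive gated) while t < t_spike + t_dead; the interval is
half open, so a spike exactly at the dead-time boundary is allowed.
Each trial starts from a random membrane state obtained by a 20 ms
noise-only burn-in (≥ 8 membrane time constants, ≥ 4 τ_supra for every
fiber; a two-sample KS check confirms the V distribution is stationary
by then).  Internally all quantities use one canonical unit system
(s, mV, µA, mS, nF), in which dV/dt [mV/s] = 10⁶·I[µA]/C[nF]; the mixed
units of the published constants are converted once, at construction.

## Population variability

Interunit variability follows published population distributions:

| parameter | distribution |
|---|---|
| CF (kHz) | log-uniform on [0.125, 40] |
| SR (spikes/s) | truncated normal per group: LSR N(0.1, 0.1²) on [10⁻³, 0.2]; MSR N(4, 4²) on [0.2, 18]; HSR N(70, 30²) on [18, 180] |
| t_abs (µs) | uniform [208.5, 691.5] |
| t_rel (µs) | uniform [131.0, 894.0] |
| C (nF) | C = 10^x − α, x ~ N(µ, σ²) truncated at ±2σ; peripheral µ = −6.1514, σ = 0.1947, α = −164 nF; central µ = −5.7547, σ = 0.2010, α = −32.7 nF |

SR truncation uses rejection sampling, not clipping, to avoid probability
atoms at the limits.  The absolute and relative refractory periods are
linearly correlated — a single uniform draw is mapped onto both ranges —
so each marginal matches the table while fibers with a long ARP also
recover slowly; the correlation is what makes the interaction effects
grow along the ARP axis.  The electric refractory parameters are slaved to
the acoustic ones so a fiber behaves consistently across modalities:
t_dead = t_abs, and τ_supra = τ_supra0 · t_rel/⟨t_rel⟩ with
⟨t_rel⟩ = 512.5 µs.  Consequently the mean dead time of the population
is 450 µs.  CF is carried for bookkeeping only: neither the electric
model nor the surrogate acoustic front end is tonotopically tuned.

## The surrogate acoustic front end

The full auditory-periphery signal path (middle ear, basilar membrane,
hair cells, power-law synapse) is out of scope here.  It is replaced by
a surrogate that generates neurotransmitter-release events directly: an
inhomogeneous Poisson process (thinning algorithm, events snapped to a
10 µs grid, at most one per cell) whose rate profile captures the
features the coupling experiments depend on:

* spontaneous release rate r0 calibrated so that the spike output after
  refractory thinning equals the fiber's SR.  For the memoryless
  refractory rule used here (random refractory period t_abs + Exp(mean
  t_rel) after each spike) the calibration is exact in closed form,
  r0 = SR/(1 − SR·(t_abs + t_rel)); an optional simulation-based
  bisection refinement exists for alternative refractory rules.
* a logistic rate-level function of the effective level
  (dB SPL − hearing loss, default 26 dB), with L50 = 55 dB SPL and
  slope 6 dB, saturating where the sustained driven spike rate reaches
  150 spikes/s;
* onset emphasis: the driven rate starts at 2.5× its sustained value and
  decays with τ_adapt = 10 ms;
* offset suppression: after stimulus offset the spontaneous rate is
  suppressed (depth 1.0) and recovers with τ_rec = 80 ms.

A spike generator converts releases to spikes, discarding releases
within the random refractory period of the last spike.  Any object with
a `release_times(fiber, stimulus, window, rng)` method can replace the
surrogate, so a full periphery model can be plugged in unchanged.

What the surrogate does *not* emulate: cochlear tuning and phase
locking to stimulus fine structure, power-law (long-range) adaptation,
bursty/clustered release statistics of a ribbon synapse with a finite
vesicle pool, and level-dependent onset dynamics.  Passing tests
therefore validate the coupling and statistics machinery under
Poisson-release conditions, not the full periphery.

## EAS coupling variants

* **Uncoupled**: electric-only and acoustic-only trains merged without
  deduplication — the non-interacting baseline.
* **Coupled**: the acoustic spike generator is replaced by the
  peripheral neuron.  Every release injects a rectangular cathodic
  current (t_neuro = 40 µs, I_neuro = 3.0 mA) into the peripheral
  neuron, strongly suprathreshold so that every release fires the
  membrane unless it is refractory.  Overlapping injections sum (they
  are rare and already suprathreshold).  The synaptic current is gated
  off during the dead time exactly like the electric drive.
* **Alternative (spike exchange)**: both models keep their own spike
  generation but every spike sets *both* systems into their absolute
  and relative refractory states (membrane: reset + b + dead time;
  generator: new random refractory period).  The output is the merged
  train with same-step duplicates collapsed.

Interaction in the coupled variants is restricted to the suprathreshold
regime by construction (subthreshold facilitation between modalities is
not modeled).

## Response statistics

* Firing efficiency FE = (N − SR·T·M)/M with N the spike count in M
  analysis windows of duration T = 3.5 ms (default).
* Threshold and relative spread: integrated-Gaussian fit
  FE(L) = Φ((L − µ)/σ) by quasi-binomial weighted least squares with a
  variance floor of 0.01; threshold = µ (FE = 50 %), RS = σ/µ.  Level
  placement: a factor-2 search brackets the 50 % crossing, a 5-step
  geometric bisection localizes it, and the final curve uses 10 equally
  spaced levels across ±35 % of the crossing (widened by 1.6× and
  retried if the curve does not span FE 0.2–0.8).  Synthetic-binomial
  checks show the protocol recovers µ to < 0.1 % and RS to < 0.1
  percentage points at 100 trials per level.
* Dynamic range: DR = 20·log10(L90/L10) with L10/L90 the 10 %/90 % FE
  levels of the fit (µ ∓ 1.2816 σ).  This reproduces the conventional
  ≈ 0.9 dB at RS ≈ 4 %.
* Latency/jitter: mean/SD of the latencies of **all** spikes in the
  3.5 ms windows following pulse onsets (not first spikes only); under
  this pooling the analytic mixture estimates below are exact.
* Vector strength at the pulse rate ν:
  VS = |Σ exp(2πiνt_k)| / N.
* Analytic non-interacting estimates, with N_S = SR·T spontaneous and
  N_E evoked spikes per window, L_E/J_E the evoked-only timing:

      L = (N_S·(T/2) + N_E·L_E) / (N_S + N_E)
      J² = w_S·T²/12 + w_E·J_E² + w_S·w_E·(T/2 − L_E)²

  (law of total variance of the uniform + evoked mixture).

## Experiment protocols

All experiments default to a 150-fiber population (30 LSR, 30 MSR,
90 HSR) and are pure functions of (config, seed).

1. **Monophasic single pulses** (ES alone): 26 and 39 µs phases, both
   polarities; threshold, RS, and latency/jitter at threshold from 100
   trials.
2. **Biphasic trains, electric only**: 300 ms trains of 40 µs/phase
   cathodic-leading biphasic pulses at 250 pps.  Thresholds and DRs are
   fitted from the response to the *first* pulse (40 presentations per
   level; the protocol requires at least 15 — 40 keeps the fitted-σ
   bias of the sparse-presentation probit fit below ~4 %).
   Latency/jitter are measured at the level where the *train-wide* FE
   crosses 50 %, i.e. 0.5 expected evoked spikes per post-pulse window,
   which is the operating point assumed by the analytic estimates.
   Variants are compared by Mann-Whitney U tests; deviations from the
   analytic timing estimates by Wilcoxon signed-rank tests within the
   SR ≤ 50 and SR > 50 groups.
3. **Combined EAS**: the electric train starts 50 ms before the
   acoustic broadband noise (100/200/300 ms, one third of the fibers
   each) and ends 250 ms after its offset.  Four electric levels per
   fiber are drawn uniformly between the fitted 10 % and 90 % FE levels
   of the coupled model (the same levels are reused for the uncoupled
   variant so the EA−E comparisons are paired; electric-only and
   combined runs use matched seeds).  The acoustic level is the lowest
   one in 70–100 dB SPL (5 dB steps) whose sustained driven rate
   exceeds 2.5× SR, else 100 dB.  Statistics are computed per analysis
   interval — I1: the 50 ms before AS onset; I2: 20 ms after onset;
   I3: last 30 ms of the stimulus; I4: 20 ms after offset; I5:
   offset+50 to offset+150 ms; I6: offset+150 to offset+250 ms — as
   EA−E differences in SR-corrected rate, jitter and VS, plus EA/E and
   EA/A sustained-rate ratios in I3.

### Problem sizes in the shipped checks

The test suite runs the three protocols on reduced populations (30, 48
and 24 fibers, same 1:1:3 group mix) and widens tolerances on population
means by the corresponding sampling error; `scripts/acceptance.py` uses
48 fibers for the monophasic protocol and 96 for the pulse-train
protocol.  These sizes keep a full run in the tens of minutes on one
core while the population means remain stable to a few percent.

## Design choices where the design was open

* The reset applies to both neurons regardless of which one spiked, and
  both variants of the published dual naming of thresholds are resolved
  as: V_T = −70 mV in the exponential term, V_peak = 24 mV for
  detection.
* Zero interphase gap for biphasic pulses (not stated in the protocol).
* Polarity decomposition is per sample, not per phase — identical for
  rectangular pulses.
* The capacitance law C = 10^x − α is taken literally with the negative
  α values (the offset adds capacitance).
* Noise is retained during the dead time (only *stimulation* is gated).
* The uncoupled merge does not deduplicate coincident spikes
  (measure-zero on a continuous timeline); the alternative variant
  collapses duplicates only within one integration step.

## Known limitations

* The coupled model's threshold elevation and DR increase for
  high-SR fibers are driven by how often a spontaneous spike precedes a
  pulse and by the graded relative-refractory elevation (b = 90 µA
  decaying with τ_supra).  With Poisson release statistics this yields
  a mean coupled threshold elevation of ~10–15 % and a pronounced slow
  saturation tail in the FE curve; a front end with clustered releases
  or stronger post-spike suppression would shift both.
* Latencies of the electric model are short compared to animal data
  (a property inherited from the underlying point-neuron model).
* Electrophonic excitation (hair-cell-mediated response to current) is
  deliberately not modeled.
* The fitted σ (hence RS and DR) of saturating FE curves depends on the
  span of levels sampled; the ±35 % span around the crossing is a fixed
  protocol choice.
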