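"""Randomized auditory-nerve-fiber parameter sets.

A simulated ANF is described by two coupled parameter groups:

* acoustic-pathway parameters (characteristic frequency CF, spontaneous
  rate SR, absolute refractory period ``t_abs``, baseline relative
  refractory period ``t_rel``), drawn from published population
  distributions for the feline auditory nerve; and
* electric-pathway parameters for the two-point integrate-and-fire model
  (membrane capacitances of the peripheral and central neuron, the
  suprathreshold adaptation time constants, the dead time).

The electric refractory parameters are tied to the acoustic ones so that a
fiber shows consistent refractoriness whichever pathway evoked the spike:
the electric dead time equals ``t_abs`` and the suprathreshold adaptation
time constants are scaled by ``t_rel`` relative to its population mean.

Units
-----
All times are stored in **seconds**, potentials in mV, currents in µA,
conductances in mS and capacitances in nF.  The literature values quoted
in the defaults below mix µs/mV/µA/nF; conversion to the canonical system
happens exactly once, in this module, at construction time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ESNeuronConstants",
    "FiberParams",
    "PERIPHERAL",
    "CENTRAL",
    "T_REL_MEAN",
    "sample_capacitance",
    "sample_fiber",
    "sample_population",
    "population_to_csv",
    "population_to_json",
    "population_from_csv",
]

US = 1e-6  # µs -> s

#: Population mean of the uniform t_rel distribution [131.0, 894.0] µs.
T_REL_MEAN = 512.5 * US


@dataclass(frozen=True)
class ESNeuronConstants:
    """Fixed constants of one point neuron of the electric-stimulation model.

    Two instances exist, :data:`PERIPHERAL` and :data:`CENTRAL`, holding the
    published parameter set for the peripheral and central process.

    Attributes
    ----------
    g_L : membrane conductance (mS)
    Delta_T : slope factor of the exponential spiking term (mV)
    E_L : resting potential (mV)
    v_thr : threshold potential of the exponential term (mV)
    v_peak : spike detection potential (mV)
    v_reset : post-spike reset potential (mV)
    alpha_noise : spectral exponent of the 1/f^alpha noise current
    beta : inhibitory compression factor for opposite-polarity current
    tau_sub : subthreshold adaptation time constant (s)
    tau_supra0 : baseline suprathreshold adaptation time constant (s);
        per-fiber values scale this by ``t_rel / <t_rel>``
    a_sub, a_supra : adaptation conductances (mS)
    b : spike-triggered increment of the suprathreshold current (µA)
    sigma_noise : noise current amplitude (µA)
    cap_mu, cap_sigma : mean / SD of the normal variable x in the membrane
        capacitance law C = 10**x - cap_alpha (x in log10-farads)
    cap_alpha : offset of the capacitance law (nF)
    """

    g_L: float
    Delta_T: float
    E_L: float
    v_thr: float
    v_peak: float
    v_reset: float
    alpha_noise: float
    beta: float
    tau_sub: float
    tau_supra0: float
    a_sub: float
    a_supra: float
    b: float
    sigma_noise: float
    cap_mu: float
    cap_sigma: float
    cap_alpha: float

    def __post_init__(self) -> None:
        if not 0.0 < self.beta <= 1.0:
            raise ValueError("beta must be in (0, 1]")
        if self.tau_sub <= 0 or self.tau_supra0 <= 0:
            raise ValueError("adaptation time constants must be positive")


_SHARED = dict(
    E_L=-80.0,
    v_thr=-70.0,
    v_peak=24.0,
    v_reset=-84.0,
    alpha_noise=0.80,
    beta=0.75,
    tau_sub=250.0 * US,
    a_sub=2.0,
    a_supra=3.0,
    b=90.0,
)

#: Published constants of the peripheral point neuron.
PERIPHERAL = ESNeuronConstants(
    g_L=1.1,
    Delta_T=10.0,
    tau_supra0=4500.0 * US,
    sigma_noise=8.70,
    cap_mu=-6.1514,
    cap_sigma=0.1947,
    cap_alpha=-164.0,
    **_SHARED,
)

#: Published constants of the central point neuron.
CENTRAL = ESNeuronConstants(
    g_L=2.7,
    Delta_T=3.0,
    tau_supra0=2500.0 * US,
    sigma_noise=11.89,
    cap_mu=-5.7547,
    cap_sigma=0.2010,
    cap_alpha=-32.7,
    **_SHARED,
)

# Spontaneous-rate groups: (mean, sd, low, high) in spikes/s.
_SR_GROUPS = {
    "LSR": (0.1, 0.1, 1e-3, 0.2),
    "MSR": (4.0, 4.0, 0.2, 18.0),
    "HSR": (70.0, 30.0, 18.0, 180.0),
}

_T_ABS_LIMITS = (208.5 * US, 691.5 * US)
_T_REL_LIMITS = (131.0 * US, 894.0 * US)
_CF_LIMITS_KHZ = (0.125, 40.0)


@dataclass(frozen=True)
class FiberParams:
    """One fiber's randomized parameter set.

    Attributes
    ----------
    cf : characteristic frequency (kHz); bookkeeping only
    sr : spontaneous spike rate (spikes/s)
    sr_group : ``"LSR"``, ``"MSR"`` or ``"HSR"``
    t_abs : absolute refractory period of the acoustic pathway (s)
    t_rel : baseline relative refractory period (s)
    C_per, C_cen : membrane capacitances (nF)
    tau_supra_per, tau_supra_cen : per-fiber suprathreshold adaptation
        time constants (s), scaled by ``t_rel / <t_rel>``
    t_dead : dead time of the electric model (s); equals ``t_abs``
    hearing_loss : flat acoustic threshold shift (dB)
    """

    cf: float
    sr: float
    sr_group: str
    t_abs: float
    t_rel: float
    C_per: float
    C_cen: float
    tau_supra_per: float
    tau_supra_cen: float
    t_dead: float
    hearing_loss: float = 26.0


def sample_capacitance(
    rng: np.random.Generator,
    which: Literal["peripheral", "central"],
    x: float | None = None,
) -> float:
    """Draw one membrane capacitance in nF.

    The capacitance follows ``C = 10**x - alpha`` where ``10**x`` is in
    farads (converted to nF) and ``x`` is normal with mean ``cap_mu`` and
    SD ``cap_sigma``, truncated at ±2 SD.  ``alpha`` (``cap_alpha``) is
    given in nF and is negative for both neurons, so the offset adds
    capacitance.

    Parameters
    ----------
    rng : seeded random generator
    which : "peripheral" or "central" parameter row
    x : optional override of the normal draw (used for testing the
        closed form at a fixed quantile)
    """
    consts = {"peripheral": PERIPHERAL, "central": CENTRAL}[which]
    if x is None:
        while True:
            x = rng.normal(consts.cap_mu, consts.cap_sigma)
            if abs(x - consts.cap_mu) <= 2.0 * consts.cap_sigma:
                break
    return 10.0**x * 1e9 - consts.cap_alpha


def _truncated_normal(rng: np.random.Generator, mu: float, sd: float,
                      lo: float, hi: float) -> float:
    # Rejection sampling keeps the shape of the parent density inside the
    # limits (clipping would pile probability mass onto the limits).
    while True:
        v = rng.normal(mu, sd)
        if lo <= v <= hi:
            return v


def sample_fiber(rng: np.random.Generator, sr_group: str,
                 hearing_loss: float = 26.0) -> FiberParams:
    """Draw a complete fiber parameter set for the given SR group.

    CF is log-uniform on [0.125, 40] kHz; SR is a truncated normal with
    group-specific parameters; ``t_abs`` and ``t_rel`` are uniform on their
    published limits.  The electric-pathway parameters are then derived:
    ``t_dead = t_abs`` and the suprathreshold time constants are the
    baseline values scaled by ``t_rel / <t_rel>``.
    """
    if sr_group not in _SR_GROUPS:
        raise ValueError(f"unknown SR group {sr_group!r}; expected one of "
                         f"{sorted(_SR_GROUPS)}")
    mu, sd, lo, hi = _SR_GROUPS[sr_group]
    lo_cf, hi_cf = _CF_LIMITS_KHZ
    cf = float(np.exp(rng.uniform(np.log(lo_cf), np.log(hi_cf))))
    sr = _truncated_normal(rng, mu, sd, lo, hi)
    # The absolute and relative refractory periods are linearly
    # correlated: one uniform draw maps onto both ranges, so each
    # marginal matches its published limits while long-ARP fibers also
    # recover slowly.
    u = rng.uniform()
    t_abs = _T_ABS_LIMITS[0] + u * (_T_ABS_LIMITS[1] - _T_ABS_LIMITS[0])
    t_rel = _T_REL_LIMITS[0] + u * (_T_REL_LIMITS[1] - _T_REL_LIMITS[0])
    scale = t_rel / T_REL_MEAN
    return FiberParams(
        cf=cf,
        sr=float(sr),
        sr_group=sr_group,
        t_abs=t_abs,
        t_rel=t_rel,
        C_per=float(sample_capacitance(rng, "peripheral")),
        C_cen=float(sample_capacitance(rng, "central")),
        tau_supra_per=PERIPHERAL.tau_supra0 * scale,
        tau_supra_cen=CENTRAL.tau_supra0 * scale,
        t_dead=t_abs,
        hearing_loss=hearing_loss,
    )


def sample_population(rng: np.random.Generator, n_lsr: int, n_msr: int,
                      n_hsr: int, hearing_loss: float = 26.0,
                      ) -> list[FiberParams]:
    """Draw a fiber population with the given counts per SR group."""
    fibers: list[FiberParams] = []
    for group, n in (("LSR", n_lsr), ("MSR", n_msr), ("HSR", n_hsr)):
        if n < 0:
            raise ValueError("fiber counts must be non-negative")
        fibers.extend(sample_fiber(rng, group, hearing_loss) for _ in range(n))
    return fibers


def population_to_frame(fibers: Sequence[FiberParams]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(f) for f in fibers])


def population_to_csv(fibers: Sequence[FiberParams], path) -> None:
    population_to_frame(fibers).to_csv(path, index=False)


def population_to_json(fibers: Sequence[FiberParams], path) -> None:
    with open(path, "w") as fh:
        json.dump([dataclasses.asdict(f) for f in fibers], fh, indent=1)


def population_from_csv(path) -> list[FiberParams]:
    df = pd.read_csv(path)
    return [FiberParams(**{k: (row[k] if k != "sr_group" else str(row[k]))
                           for k in df.columns}) for _, row in df.iterrows()]
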