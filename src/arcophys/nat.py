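"""Phenomenological transient Na+ current (I_NaT).

The transient current is described by three separable pieces fitted directly
to voltage-clamp data:

* a Boltzmann conductance I-V curve,
      I(V) = g_max (V - V_rev) / (1 + exp((V_half - V) / k)),
* power-law activation in time,
      I(t) = I_max (1 - exp(-t / tau_a))^N,
  where N is the apparent number of first-order activation transitions, and
* single-exponential inactivation, exp(-t / tau_h).

At a fixed step potential the product of these pieces is mathematically
identical to an N-th power first-order activation gate with an independent
inactivation gate, which is how the surrogate neuron uses the same
parameters (see :mod:`arcophys.dynclamp`).

Units: conductance nS, voltage mV, time ms, current nA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TransientNaParams",
    "boltzmann_iv",
    "powerlaw_activation",
    "half_rise_time",
    "simulate_inat",
]


@dataclass(frozen=True)
class TransientNaParams:
    """Boltzmann conductance plus activation/inactivation kinetics of I_NaT."""

    g_max: float   # nS
    V_rev: float   # mV
    V_half: float  # mV
    k: float       # mV, slope factor (> 0)
    tau_a: float   # ms, activation time constant
    N: float       # power-law exponent (>= 1)
    tau_h: float   # ms, inactivation time constant

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")
        if self.k <= 0:
            raise ValueError("slope factor k must be > 0")
        if self.tau_a <= 0 or self.tau_h <= 0:
            raise ValueError("time constants must be > 0")
        if self.N < 1:
            raise ValueError("power-law exponent N must be >= 1")


def boltzmann_iv(V, p: TransientNaParams):
    """Steady activation I-V: I = g_max (V - V_rev) / (1 + exp((V_half - V)/k)).

    Returns nA for g_max in nS and V in mV, scaled by 1e-3 (nS*mV = pA).
    """
    V = np.asarray(V, dtype=float)
    I_pA = p.g_max * (V - p.V_rev) / (1.0 + np.exp((p.V_half - V) / p.k))
    I = I_pA * 1e-3
    return float(I) if I.ndim == 0 else I


def powerlaw_activation(t, I_max: float, tau_a: float, N: float):
    """Power-law activation time course I(t) = I_max (1 - exp(-t/tau_a))^N."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    I = I_max * (1.0 - np.exp(-t / tau_a)) ** N
    return float(I) if I.ndim == 0 else I


def half_rise_time(tau_a: float, N: float) -> float:
    """Time at which the power-law rise reaches half of I_max (closed form)."""
    return -tau_a * math.log(1.0 - 0.5 ** (1.0 / N))


def simulate_inat(step_V: float, hold_V: float, dur: float, dt: float,
                  p: TransientNaParams, *, onset_latency: float = 0.0,
                  inactivating: bool = True) -> np.ndarray:
    """Current trace (nA) for a single step from ``hold_V`` to ``step_V``.

    The response is the Boltzmann driving-force current at ``step_V``
    modulated by power-law activation and (optionally) single-exponential
    inactivation; ``onset_latency`` delays the response relative to the step.
    The hold segment is not included: the trace starts at the step onset.
    """
    if dur <= 0 or dt <= 0:
        raise ValueError("dur and dt must be > 0")
    t = np.arange(int(round(dur / dt))) * dt
    ts = np.clip(t - onset_latency, 0.0, None)
    I = boltzmann_iv(step_V, p) * (1.0 - np.exp(-ts / p.tau_a)) ** p.N
    if inactivating:
        I = I * np.exp(-ts / p.tau_h)
    return I
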