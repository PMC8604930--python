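"""Hodgkin-Huxley style resurgent Na+ current (I_NaR) gating model.

The resurgent current is modelled as a single conductance controlled by two
first-order gating particles: an activating particle ``s`` and an
inactivating particle ``f``::

    I_NaR = g_NaR * s * f * (V - E_NaR)

Each particle ``x`` has voltage-dependent opening (alpha_x) and closing
(beta_x) rate constants, from which

    tau_x  = 1 / (alpha_x + beta_x)
    x_inf  = alpha_x * tau_x
    dx/dt  = (x_inf - x) / tau_x

The state equations are integrated with a first-order Euler method, default
time step 0.03 ms, matching the loop rate of the dynamic-clamp use case.

Sign convention: inward current is negative (physiology convention).
Conductance is in uS, voltage in mV, time in ms, current in nA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np

__all__ = [
    "RateForm",
    "RateLaw",
    "GatingState",
    "ResurgentChannelParams",
    "rate_constant",
    "steady_state_and_tau",
    "euler_step",
    "resurgent_current",
    "integrate_gates",
]

logger = logging.getLogger(__name__)

#: voltage range (mV) over which a rate law must evaluate to something finite
#: and non-negative for the channel model to be considered well-formed
_VALID_RANGE_MV = (-100.0, 60.0)


class RateForm(str, Enum):
    """Functional form of a voltage-dependent rate constant."""

    EXPONENTIAL = "exponential"  # A * exp((V - V0) / K)
    LINOID = "linoid"            # A * (V - V0) / (exp((V - V0) / K) - 1)
    SIGMOID = "sigmoid"          # A / (1 + exp((V - V0) / K))


@dataclass(frozen=True)
class RateLaw:
    """One voltage-dependent rate constant alpha_x(V) or beta_x(V).

    Parameters
    ----------
    form:
        Functional form, see :class:`RateForm`.
    A:
        Rate amplitude in 1/ms.  Must be positive: the sign structure of a
        rate law lives in ``K`` and ``V0``, never in a fitted sign of ``A``.
    V0:
        Voltage offset in mV.
    K:
        Voltage slope factor in mV; appears in the exponential-term
        denominator.  Must be nonzero.
    Q:
        Dimensionless multiplicative temperature factor (1.0 at the
        room-temperature reference condition).
    """

    form: RateForm
    A: float
    V0: float
    K: float
    Q: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "form", RateForm(self.form))
        if not (self.A > 0):
            raise ValueError(f"rate amplitude A must be > 0, got {self.A}")
        if self.K == 0:
            raise ValueError("rate slope K must be nonzero")
        if not (self.Q > 0):
            raise ValueError(f"temperature factor Q must be > 0, got {self.Q}")

    def __call__(self, V):
        return rate_constant(V, self)


def rate_constant(V, law: RateLaw):
    """Evaluate a rate law at membrane potential ``V`` (mV) -> rate in 1/ms.

    Accepts scalars or arrays.  Raises ``ValueError`` for non-finite voltage.
    The linoid form has a removable singularity at ``V == V0`` where its
    limit ``A * K`` is returned.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    x = (V - law.V0) / law.K
    if law.form is RateForm.EXPONENTIAL:
        r = law.A * np.exp(x)
    elif law.form is RateForm.SIGMOID:
        r = law.A / (1.0 + np.exp(x))
    elif law.form is RateForm.LINOID:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(
                np.abs(x) < 1e-9,
                law.A * law.K,
                law.A * (V - law.V0) / np.expm1(x),
            )
    else:  # pragma: no cover - enum is exhaustive
        raise ValueError(f"unknown rate form {law.form}")
    r = r * law.Q
    if r.ndim == 0:
        return float(r)
    return r


@dataclass
class GatingState:
    """Open probabilities of the activating (s) and inactivating (f) particles."""

    s: float
    f: float

    def __post_init__(self) -> None:
        for name in ("s", "f"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"gating variable {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ResurgentChannelParams:
    """Parameters of the two-particle resurgent Na+ channel.

    ``g_NaR`` is the maximal conductance in uS, ``E_NaR`` the reversal
    potential in mV (+67 mV default, the calculated Na+ reversal of the
    recording solutions), and the four rate laws define the s and f
    particle kinetics.
    """

    alpha_s: RateLaw
    beta_s: RateLaw
    alpha_f: RateLaw
    beta_f: RateLaw
    g_NaR: float = 1.0
    E_NaR: float = 67.0
    dt_default: float = 0.03

    def __post_init__(self) -> None:
        if self.g_NaR < 0:
            raise ValueError("g_NaR must be >= 0")
        if not (self.dt_default > 0):
            raise ValueError("dt_default must be > 0")
        # rates must be finite and non-negative across the physiological range
        vv = np.linspace(*_VALID_RANGE_MV, 33)
        for name in ("alpha_s", "beta_s", "alpha_f", "beta_f"):
            r = rate_constant(vv, getattr(self, name))
            if not np.all(np.isfinite(r)) or np.any(r < 0):
                raise ValueError(f"rate law {name} invalid over {_VALID_RANGE_MV} mV")

    def with_conductance(self, g_NaR: float) -> "ResurgentChannelParams":
        return replace(self, g_NaR=g_NaR)

    def resting_state(self, V: float) -> GatingState:
        """Gating state at steady state for holding potential ``V``."""
        s_inf, _ = steady_state_and_tau(V, self.alpha_s, self.beta_s)
        f_inf, _ = steady_state_and_tau(V, self.alpha_f, self.beta_f)
        return GatingState(s=s_inf, f=f_inf)


def steady_state_and_tau(V, alpha: RateLaw, beta: RateLaw):
    """Steady state ``x_inf`` and time constant ``tau_x`` (ms) at voltage V.

    tau_x = 1/(alpha + beta), x_inf = alpha * tau_x.
    """
    a = rate_constant(V, alpha)
    b = rate_constant(V, beta)
    denom = a + b
    if np.any(np.asarray(denom) <= 0):
        raise ZeroDivisionError(
            "alpha + beta vanished: gating kinetics degenerate at this voltage"
        )
    tau = 1.0 / denom
    return a * tau, tau


class _StabilityWarner:
    """Log the Euler stability warning once per process run."""

    warned = False

    @classmethod
    def warn(cls, dt: float, tau: float) -> None:
        if not cls.warned:
            logger.warning(
                "Euler step dt=%.4g ms exceeds gating time constant tau=%.4g ms; "
                "trajectory may overshoot (clamped to [0, 1])", dt, tau,
            )
            cls.warned = True


def euler_step(state: GatingState, V: float, dt: float,
               params: ResurgentChannelParams) -> GatingState:
    """Advance both gating particles one forward-Euler step of ``dt`` ms.

    The update is ``x <- x + dt * (x_inf - x) / tau_x``; results are clamped
    to [0, 1] (first-order Euler can overshoot when dt/tau > 1; a warning is
    logged once per run if that regime is entered).
    """
    if not (dt > 0):
        raise ValueError("dt must be > 0")
    new = {}
    for name, x0, (al, be) in (
        ("s", state.s, (params.alpha_s, params.beta_s)),
        ("f", state.f, (params.alpha_f, params.beta_f)),
    ):
        x_inf, tau = steady_state_and_tau(V, al, be)
        if dt / tau > 1.0:
            _StabilityWarner.warn(dt, tau)
        x = x0 + dt * (x_inf - x0) / tau
        new[name] = min(1.0, max(0.0, x))
    return GatingState(**new)


def resurgent_current(state: GatingState, V: float,
                      params: ResurgentChannelParams) -> float:
    """I_NaR = g_NaR * s * f * (V - E_NaR), in nA (inward negative)."""
    return params.g_NaR * state.s * state.f * (V - params.E_NaR)


def integrate_gates(command_mV: np.ndarray, dt: float,
                    params: ResurgentChannelParams,
                    state: GatingState | None = None):
    """Integrate s, f along a voltage-command waveform; return (I, s, f) arrays.

    The initial state defaults to steady state at the first command sample.
    Vectorised over the trace; one Euler update per sample, current evaluated
    at the post-update state and the sample's voltage.
    """
    V = np.asarray(command_mV, dtype=float)
    if state is None:
        state = params.resting_state(float(V[0]))
    n = V.size
    a_s = rate_constant(V, params.alpha_s)
    b_s = rate_constant(V, params.beta_s)
    a_f = rate_constant(V, params.alpha_f)
    b_f = rate_constant(V, params.beta_f)
    s = np.empty(n)
    f = np.empty(n)
    cs, cf = state.s, state.f
    min_tau = 1.0 / max(np.max(a_s + b_s), np.max(a_f + b_f))
    if dt / min_tau > 1.0:
        _StabilityWarner.warn(dt, min_tau)
    for i in range(n):
        rs = a_s[i] + b_s[i]
        rf = a_f[i] + b_f[i]
        cs = cs + dt * (a_s[i] - rs * cs)
        cf = cf + dt * (a_f[i] - rf * cf)
        cs = min(1.0, max(0.0, cs))
        cf = min(1.0, max(0.0, cf))
        s[i] = cs
        f[i] = cf
    I = params.g_NaR * s * f * (V - params.E_NaR)
    return I, s, f
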