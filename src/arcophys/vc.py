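"""Voltage-clamp protocol simulation and measurement.

Covers the resurgent-current protocol (conditioning depolarization followed
by a family of repolarizing test steps), peak measurement and I_NaR/I_NaT
normalization, single-exponential decay fits, onset-latency detection,
P/4 leak/capacitance subtraction, Boltzmann I-V fits and power-law
activation fits.

Currents are inward-negative throughout; "peak" of a Na+ current window
means the most negative sample, and magnitudes are used for ratios.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import OptimizeWarning, curve_fit

from .gating import ResurgentChannelParams, integrate_gates
from .nat import TransientNaParams
from .sweeps import Sweep, SweepSet, StepProtocol, resurgent_protocol

__all__ = [
    "IVCurve",
    "FitResult",
    "NaTGateKinetics",
    "run_resurgent_protocol",
    "measure_peaks",
    "measure_iv",
    "fit_exp_decay",
    "detect_onset",
    "p4_subtract",
    "fit_boltzmann_iv",
    "fit_powerlaw_onset",
]

#: start of the resurgent-current search window, ms after the test-step
#: transition, excluding residual capacitive/transient artifacts
NAR_SETTLE_MS = 0.5


@dataclass
class IVCurve:
    """Peak currents versus test potential for one sweep family."""

    V: np.ndarray        # test potentials, mV (strictly ordered)
    I_peak: np.ndarray   # peak I_NaR per sweep, nA (signed, inward negative)
    I_norm: np.ndarray   # |peak I_NaR| / |peak I_NaT| per sweep

    def __post_init__(self) -> None:
        self.V = np.asarray(self.V, dtype=float)
        self.I_peak = np.asarray(self.I_peak, dtype=float)
        self.I_norm = np.asarray(self.I_norm, dtype=float)
        d = np.diff(self.V)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("test potentials must be strictly ordered")

    @property
    def peak_level(self) -> float:
        """Test potential of maximal peak-current magnitude."""
        return float(self.V[np.argmax(np.abs(self.I_peak))])


@dataclass
class FitResult:
    """Outcome of a least-squares fit; ``success=False`` flags failure."""

    params: dict
    success: bool
    message: str = ""
    window: tuple | None = None
    rms_residual: float = float("nan")

    def __getitem__(self, key):
        return self.params[key]


# ---------------------------------------------------------------------------
# transient Na+ current as a gate ODE (for multi-segment protocols)

class NaTGateKinetics:
    """ODE-gate equivalent of the separable I_NaT description.

    Activation is an N-th power first-order gate with time constant tau_a and
    steady state m_inf(V) = (1 + exp((V_half - V)/k))^(-1/N), so that at a
    fixed step from rest the current reproduces the fitted power-law rise.
    Inactivation is a single first-order gate with time constant tau_h and a
    Boltzmann steady state (midpoint/slope are a stated calibration choice,
    not a fitted quantity).
    """

    def __init__(self, p: TransientNaParams, h_half: float = -65.0,
                 h_slope: float = 6.0):
        self.p = p
        self.h_half = h_half
        self.h_slope = h_slope

    def m_inf(self, V):
        return (1.0 / (1.0 + np.exp((self.p.V_half - np.asarray(V, float))
                                    / self.p.k))) ** (1.0 / self.p.N)

    def h_inf(self, V):
        return 1.0 / (1.0 + np.exp((np.asarray(V, float) - self.h_half)
                                   / self.h_slope))

    def simulate(self, command_mV: np.ndarray, dt: float) -> np.ndarray:
        """Forward-Euler integration of m, h along a command; returns nA."""
        V = np.asarray(command_mV, dtype=float)
        m_inf = self.m_inf(V)
        h_inf = self.h_inf(V)
        am = dt / self.p.tau_a
        ah = dt / self.p.tau_h
        m = np.empty(V.size)
        h = np.empty(V.size)
        cm, ch = float(m_inf[0]), float(h_inf[0])
        for i in range(V.size):
            cm += am * (m_inf[i] - cm)
            ch += ah * (h_inf[i] - ch)
            m[i] = cm
            h[i] = ch
        g_frac = m ** self.p.N * h
        return self.p.g_max * g_frac * (V - self.p.V_rev) * 1e-3


# ---------------------------------------------------------------------------
# protocol simulation

def run_resurgent_protocol(resurgent: ResurgentChannelParams | None = None,
                           nat: NaTGateKinetics | TransientNaParams | None = None,
                           protocol: StepProtocol | None = None,
                           leak_nS: float = 0.0,
                           leak_E: float = -90.0) -> SweepSet:
    """Simulate the resurgent protocol for the given channel models.

    Each sweep starts from steady state at the holding potential (the 2 s
    intersweep interval is treated as fully re-equilibrating), so sweeps are
    independent.  The response is the sum of the resurgent current, the
    transient current and an optional linear leak.
    """
    if protocol is None:
        protocol = resurgent_protocol()
    if isinstance(nat, TransientNaParams):
        nat = NaTGateKinetics(nat)
    sweeps = []
    for level in protocol.test_levels:
        cmd = protocol.command_for(level)
        t = np.arange(cmd.size) * protocol.dt
        y = np.zeros_like(cmd)
        if resurgent is not None:
            if protocol.dt > resurgent.dt_default + 1e-12:
                # integrate on the channel's stability step, then decimate
                sub = max(1, int(math.ceil(protocol.dt / resurgent.dt_default)))
            else:
                sub = 1
            if sub == 1:
                I, _, _ = integrate_gates(cmd, protocol.dt, resurgent)
            else:
                fine = np.repeat(cmd, sub)
                I, _, _ = integrate_gates(fine, protocol.dt / sub, resurgent)
                I = I[sub - 1::sub]
            y = y + I
        if nat is not None:
            y = y + nat.simulate(cmd, protocol.dt)
        if leak_nS:
            y = y + leak_nS * (cmd - leak_E) * 1e-3
        sweeps.append(Sweep(t=t, y=y, command=cmd, y_units="nA",
                            meta={"protocol": "resurgent",
                                  "test_level": float(level),
                                  "test_onset": protocol.test_onset,
                                  "conditioning_onset": protocol.pre_duration,
                                  "dt": protocol.dt}))
    return SweepSet(sweeps=sweeps, meta={"protocol": "resurgent",
                                         "holding": protocol.holding,
                                         "dt": protocol.dt})


# ---------------------------------------------------------------------------
# measurement

def measure_peaks(sweep: Sweep, nat_window: tuple | None = None,
                  nar_window: tuple | None = None):
    """Peak (most negative) I_NaT and I_NaR of one sweep, plus their ratio.

    Windows default to the conditioning step (I_NaT) and the test step
    beginning ``NAR_SETTLE_MS`` after the transition (I_NaR), taken from the
    sweep metadata.  Returns ``(peak_nat, peak_nar, i_norm)`` with
    ``i_norm = |peak_nar| / |peak_nat|``.
    """
    meta = sweep.meta
    if nat_window is None:
        nat_window = (meta["conditioning_onset"], meta["test_onset"])
    if nar_window is None:
        nar_window = (meta["test_onset"] + NAR_SETTLE_MS, sweep.t[-1] + sweep.dt)
    win_t = sweep.window(*nat_window)
    win_r = sweep.window(*nar_window)
    if win_t.stop <= win_t.start or win_r.stop <= win_r.start:
        raise ValueError("empty measurement window")
    peak_nat = float(np.min(sweep.y[win_t]))
    peak_nar = float(np.min(sweep.y[win_r]))
    i_norm = abs(peak_nar) / abs(peak_nat) if peak_nat != 0 else float("nan")
    return peak_nat, peak_nar, i_norm


def measure_iv(sweepset: SweepSet) -> IVCurve:
    """Peak I_NaR I-V (and I_NaR/I_NaT normalization) across a sweep family."""
    rows = sorted(((s.meta["test_level"],) + measure_peaks(s) for s in sweepset),
                  key=lambda r: r[0])
    V = np.array([r[0] for r in rows])
    return IVCurve(V=V,
                   I_peak=np.array([r[2] for r in rows]),
                   I_norm=np.array([r[3] for r in rows]))


def fit_exp_decay(t: np.ndarray, y: np.ndarray) -> FitResult:
    """Least-squares fit of ``A * exp(-t/tau) + C`` to a decay segment.

    ``t`` is taken relative to its first sample.  A segment that does not
    decay (constant, rising, or fit not converging to tau > 0) returns a
    flagged failure rather than a silent value.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 4:
        return FitResult({}, False, "segment too short")
    ts = t - t[0]
    span = float(np.ptp(y))
    if span == 0.0:
        return FitResult({}, False, "constant segment: no decay to fit")
    a0 = y[0] - y[-1]
    # crude tau guess: time to fall to 1/e of the initial excursion
    target = y[-1] + a0 / math.e
    idx = np.nonzero((y - target) * np.sign(a0) <= 0)[0]
    tau0 = ts[idx[0]] if idx.size and ts[idx[0]] > 0 else ts[-1] / 3.0

    def model(tt, A, tau, C):
        with np.errstate(over="ignore"):
            return A * np.exp(np.clip(-tt / tau, -700.0, 700.0)) + C

    try:
        with warnings.catch_warnings():
            # degenerate segments are reported through the failure flag
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(model, ts, y, p0=[a0, tau0, y[-1]],
                                maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return FitResult({}, False, f"fit did not converge: {exc}")
    A, tau, C = popt
    resid = y - model(ts, *popt)
    rms = float(np.sqrt(np.mean(resid ** 2)))
    if tau <= 0 or not np.isfinite(tau):
        return FitResult({}, False, "fitted tau not positive: segment not decaying")
    rss_const = float(np.sum((y - y.mean()) ** 2))
    rss_fit = float(np.sum(resid ** 2))
    if rss_fit > rss_const * (1 - 1e-9):
        return FitResult({}, False, "exponential no better than constant")
    return FitResult({"A": float(A), "tau": float(tau), "C": float(C)},
                     True, rms_residual=rms)


def detect_onset(sweep: Sweep, stim_onset: float,
                 baseline_window: tuple | None = None,
                 c: float = 3.0, m: int = 2):
    """Latency (ms) from ``stim_onset`` to the first deviation from baseline.

    A line is fitted to the pre-stimulus baseline window; the onset is the
    first post-stimulus sample whose residual from the extrapolated line
    exceeds ``c`` baseline standard deviations for ``m`` consecutive samples.
    Returns ``None`` if no crossing is found.
    """
    if baseline_window is None:
        baseline_window = (max(0.0, stim_onset - 2.0), stim_onset)
    if baseline_window[1] - baseline_window[0] < 2.0 - 1e-9:
        raise ValueError("need >= 2 ms of pre-stimulus baseline")
    base = sweep.window(*baseline_window)
    tb, yb = sweep.t[base], sweep.y[base]
    coef = np.polyfit(tb, yb, 1)
    sigma = float(np.std(yb - np.polyval(coef, tb)))
    # noiseless traces: fall back to a small absolute floor so that any real
    # deviation is detected at the first sample
    floor = 1e-9 * max(1.0, float(np.max(np.abs(yb))))
    thresh = max(c * sigma, floor)
    post = sweep.window(stim_onset, sweep.t[-1] + sweep.dt)
    resid = np.abs(sweep.y[post] - np.polyval(coef, sweep.t[post]))
    above = resid > thresh
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= m:
            onset_idx = i - m + 1
            return float(sweep.t[post][onset_idx] - stim_onset)
    return None


def p4_subtract(main: Sweep, subsweeps: list, baseline_window: tuple | None = None) -> Sweep:
    """P/4 leak and capacitive-transient subtraction.

    ``subsweeps`` are the responses to four commands of 1/4 amplitude
    (relative to their own holding level).  Each trace is zeroed on its
    pre-stimulus baseline, then the summed subsweeps are subtracted from the
    main sweep.  For a purely linear cell the corrected trace is identically
    zero; any nonlinear (channel) current is recovered exactly by
    superposition.
    """
    if len(subsweeps) != 4:
        raise ValueError("P/4 requires exactly 4 subsweeps")
    for s in subsweeps:
        if len(s.y) != len(main.y) or abs(s.dt - main.dt) > 1e-12:
            raise ValueError("subsweep length/dt mismatch with main sweep")
    if baseline_window is None:
        t0 = main.meta.get("conditioning_onset", main.t[min(len(main.t) - 1, 1)])
        baseline_window = (0.0, t0)
    bw = main.window(*baseline_window)
    if bw.stop <= bw.start:
        raise ValueError("empty baseline window")
    corrected = main.y - float(np.mean(main.y[bw]))
    for s in subsweeps:
        corrected = corrected - (s.y - float(np.mean(s.y[bw])))
    return Sweep(t=main.t.copy(), y=corrected, command=main.command.copy(),
                 y_units=main.y_units, command_units=main.command_units,
                 meta={**main.meta, "p4_corrected": True})


def fit_boltzmann_iv(V: np.ndarray, I: np.ndarray) -> FitResult:
    """Fit the Boltzmann conductance I-V to peak-current data.

    ``I = g_max (V - V_rev) / (1 + exp((V_half - V)/k))`` with I in nA,
    g_max in nS.  Requires >= 6 points spanning activation and reversal.
    A flat (all-zero) curve is flagged: g_max ~ 0 with V_half unidentifiable.
    """
    V = np.asarray(V, dtype=float)
    I = np.asarray(I, dtype=float)
    if V.size < 6:
        return FitResult({}, False, "need >= 6 I-V points")
    scale = float(np.max(np.abs(I)))
    if scale == 0.0:
        return FitResult({"g_max": 0.0}, False,
                         "flat I-V: g_max ~ 0, V_half unidentifiable")

    def model(v, g_max, V_rev, V_half, k):
        return g_max * (v - V_rev) / (1.0 + np.exp((V_half - v) / k)) * 1e-3

    # initial guesses: reversal from the most depolarized zero crossing,
    # conductance from the slope of the depolarized limb
    i_min = int(np.argmin(I))
    V_half0 = V[i_min] - 5.0
    upper = V > V[i_min]
    if np.count_nonzero(upper) >= 2:
        slope = np.polyfit(V[upper], I[upper], 1)
        g0 = max(slope[0] * 1e3, 1.0)
        V_rev0 = -slope[1] / slope[0] if slope[0] != 0 else 60.0
    else:
        g0, V_rev0 = 100.0, 60.0
    try:
        popt, _ = curve_fit(model, V, I, p0=[g0, V_rev0, V_half0, 7.0],
                            maxfev=50000)
    except (RuntimeError, ValueError) as exc:
        return FitResult({}, False, f"fit did not converge: {exc}")
    g_max, V_rev, V_half, k = popt
    resid = I - model(V, *popt)
    return FitResult({"g_max": float(g_max), "V_rev": float(V_rev),
                      "V_half": float(V_half), "k": float(abs(k))},
                     True, rms_residual=float(np.sqrt(np.mean(resid ** 2))))


def fit_powerlaw_onset(t: np.ndarray, y: np.ndarray, peak_fraction: float = 0.4,
                       onset_t: float = 0.0, I_max: float | None = None) -> FitResult:
    """Fit the power-law activation rise from onset to ~``peak_fraction`` of peak.

    ``I(t) = I_max (1 - exp(-(t - onset)/tau_a))^N``.  ``I_max`` defaults to
    the signed extremum of the whole trace; only (tau_a, N) are free.  The
    fit window runs from ``onset_t`` to the first sample whose magnitude
    reaches ``peak_fraction`` of the peak magnitude; windows shorter than 5
    samples are an error.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    i_pk = int(np.argmax(np.abs(y)))
    peak = y[i_pk]
    if I_max is None:
        # prefer the settled tail of the rise (averaging beats trusting one
        # noisy extremum); fall back to near-peak samples for decaying traces
        tail = y[-max(5, y.size // 10):]
        if abs(np.mean(tail)) >= 0.97 * abs(peak):
            I_max = float(np.mean(tail))
        else:
            near = np.abs(y) >= 0.95 * abs(peak)
            I_max = float(np.mean(y[near]))
    i_on = int(np.searchsorted(t, onset_t - 1e-12))
    cross = np.nonzero(np.abs(y[i_on:i_pk + 1]) >= peak_fraction * abs(peak))[0]
    if cross.size == 0:
        raise ValueError("trace never reaches the peak-fraction level")
    i_end = i_on + cross[0] + 1
    if i_end - i_on < 5:
        raise ValueError("fit window shorter than 5 samples")
    tw = t[i_on:i_end] - t[i_on]
    yw = y[i_on:i_end]

    def model(tt, tau_a, N):
        return I_max * (1.0 - np.exp(-tt / tau_a)) ** N

    try:
        popt, _ = curve_fit(model, tw, yw, p0=[max(tw[-1] / 3.0, 1e-3), 3.0],
                            bounds=([1e-6, 1.0], [np.inf, 100.0]), maxfev=50000)
    except (RuntimeError, ValueError) as exc:
        return FitResult({}, False, f"fit did not converge: {exc}",
                         window=(float(t[i_on]), float(t[i_end - 1])))
    tau_a, N = popt
    resid = yw - model(tw, *popt)
    return FitResult({"tau_a": float(tau_a), "N": float(N), "I_max": float(I_max)},
                     True, window=(float(t[i_on]), float(t[i_end - 1])),
                     rms_residual=float(np.sqrt(np.mean(resid ** 2))))
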