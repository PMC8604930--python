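"""Action-potential and passive-property analysis of current-clamp sweeps.

Implements spike detection, per-spike waveform features (threshold,
amplitude, half-width, maximum depolarization/repolarization rates, AHP),
phase-plane trajectories, train-level excitability metrics (spikes/s,
instantaneous firing frequency, adaptation ratios, mean Vm), the
membrane-potential residence distribution, passive-property estimation from
hyperpolarizing steps, and the capacitive estimate of the peak Na+ current
flowing during the upstroke.

Conventions
-----------
* Voltages in mV, time in ms; dV/dt is then numerically in V/s.
* Spike threshold is the voltage at the first sample whose dV/dt reaches
  ``THRESHOLD_RATE`` (10 V/s) on the ascent into the spike (a stated
  convention; configurable).
* Amplitude is peak minus threshold; half-width is measured at
  threshold + amplitude/2 with sub-sample interpolation of the crossings.
* Derivatives use centered finite differences without smoothing so that
  phase-plane plots are faithful to the raw trace.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sweeps import Sweep
from .vc import fit_exp_decay

__all__ = [
    "SpikeFeatures",
    "TrainFeatures",
    "PassiveProps",
    "dvdt",
    "detect_spikes",
    "spike_features",
    "phase_plane",
    "train_metrics",
    "vm_residence",
    "passive_props",
    "estimate_peak_ina",
]

THRESHOLD_RATE = 10.0   # V/s, dV/dt criterion defining spike threshold
DETECTION_RATE = 20.0   # V/s, upstroke criterion for spike detection
PEAK_FLOOR = -20.0      # mV, minimum peak voltage for a detected spike


@dataclass
class SpikeFeatures:
    threshold: float       # mV
    peak: float            # mV
    amplitude: float       # mV, peak - threshold
    half_width: float      # ms
    max_depol_rate: float  # V/s (positive)
    max_repol_rate: float  # V/s (magnitude)
    ahp: float             # mV, most negative Vm after the spike
    t_peak: float          # ms
    clipped: bool = False  # True when the window did not contain the full spike


@dataclass
class TrainFeatures:
    spikes_per_s: float
    iff_first_pair: float | None     # Hz, 1000/first ISI; None if < 2 spikes
    amplitude_ratio_last_first: float | None
    maxd_ratio_2nd_1st: float | None
    mean_vm: float                   # mV over the stimulus window
    n_spikes: int
    iff_series: np.ndarray | None = None  # Hz per consecutive pair


@dataclass
class PassiveProps:
    r_in: float    # MOhm
    tau_m: float   # ms
    c_m: float     # pF
    sag: float     # mV


def dvdt(trace: Sweep) -> np.ndarray:
    """Centered-difference derivative of the voltage trace, in V/s."""
    return np.gradient(trace.y, trace.t)


def detect_spikes(trace: Sweep, detection_rate: float = DETECTION_RATE,
                  peak_floor: float = PEAK_FLOOR,
                  refractory: float = 1.0) -> np.ndarray:
    """Spike peak times (ms) in ascending order.

    A spike is an upstroke whose dV/dt exceeds ``detection_rate`` followed by
    a voltage peak above ``peak_floor``; peaks closer than ``refractory`` ms
    are merged.  Returns an empty array for subthreshold traces.
    """
    d = dvdt(trace)
    fast = d >= detection_rate
    if not np.any(fast):
        return np.array([])
    starts = np.nonzero(fast & ~np.roll(fast, 1))[0]
    if fast[0]:
        starts = np.concatenate([[0], starts[starts != 0]])
    times = []
    n = len(trace.y)
    horizon = max(1, int(round(5.0 / trace.dt)))  # peak search window, 5 ms
    for i0 in starts:
        i1 = min(n, i0 + horizon)
        # peak = first local maximum after the upstroke run
        seg = trace.y[i0:i1]
        ipk = i0 + int(np.argmax(seg))
        if trace.y[ipk] < peak_floor:
            continue
        tpk = trace.t[ipk]
        if times and tpk - times[-1] < refractory:
            continue
        times.append(tpk)
    return np.asarray(times)


def _interp_crossing(t0, t1, y0, y1, level):
    return t0 + (level - y0) / (y1 - y0) * (t1 - t0)


def spike_features(trace: Sweep, spike_time: float,
                   threshold_rate: float = THRESHOLD_RATE,
                   window: float = 10.0) -> SpikeFeatures:
    """Waveform features of the spike peaking at ``spike_time``.

    ``window`` ms around the peak is analysed; the AHP is the most negative
    voltage between this peak and the next detected threshold crossing (or
    window end).  Raises ``ValueError`` if the trace has no spike at that
    time or the margins are too thin (< 2 ms on either side).
    """
    t, y = trace.t, trace.y
    if spike_time - t[0] < 2.0 or t[-1] - spike_time < 2.0:
        raise ValueError("spike not contained in trace with >= 2 ms margins")
    d = dvdt(trace)
    ipk = int(np.argmin(np.abs(t - spike_time)))
    # center on the true local maximum
    lo = max(0, ipk - int(1.0 / trace.dt))
    hi = min(len(y), ipk + int(1.0 / trace.dt) + 1)
    ipk = lo + int(np.argmax(y[lo:hi]))
    if np.max(d[max(0, ipk - int(window / trace.dt)):ipk + 1]) < threshold_rate:
        raise ValueError("no suprathreshold upstroke ascending into this time")

    # threshold: walk back from the fastest point of the upstroke to where
    # dV/dt first drops below the criterion; the threshold sample is the
    # first criterion-reaching sample of that ascent
    iw = max(0, ipk - int(window / trace.dt))
    i = iw + int(np.argmax(d[iw:ipk + 1]))
    while i > 0 and d[i - 1] >= threshold_rate:
        i -= 1
    i_thr = i
    threshold = float(y[i_thr])
    peak = float(y[ipk])
    amplitude = peak - threshold

    clipped = False
    half_level = threshold + amplitude / 2.0
    # rising crossing
    i = ipk
    while i > 0 and y[i - 1] > half_level:
        i -= 1
    if i == 0:
        clipped = True
        t_up = t[0]
    else:
        t_up = _interp_crossing(t[i - 1], t[i], y[i - 1], y[i], half_level)
    # falling crossing
    j = ipk
    jmax = min(len(y) - 1, ipk + int(window / trace.dt))
    while j < jmax and y[j + 1] > half_level:
        j += 1
    if j == jmax:
        clipped = True
        t_down = t[jmax]
    else:
        t_down = _interp_crossing(t[j], t[j + 1], y[j], y[j + 1], half_level)
    half_width = float(t_down - t_up)

    iw0 = max(0, i_thr)
    iw1 = jmax
    max_depol = float(np.max(d[iw0:ipk + 1]))
    # repolarization: from peak until Vm returns below threshold (or window end)
    k = ipk
    while k < iw1 and y[k] > threshold:
        k += 1
    max_repol = float(abs(np.min(d[ipk:k + 1]))) if k > ipk else float("nan")
    # AHP: minimum after the downstroke, before the next upstroke
    m = k
    mmax = min(len(y) - 1, ipk + int(window / trace.dt))
    while m < mmax and d[m] < threshold_rate:
        m += 1
    ahp = float(np.min(y[k:m + 1])) if m > k else float(y[k])
    return SpikeFeatures(threshold=threshold, peak=peak, amplitude=amplitude,
                         half_width=half_width, max_depol_rate=max_depol,
                         max_repol_rate=max_repol, ahp=ahp,
                         t_peak=float(t[ipk]), clipped=clipped)


def phase_plane(trace: Sweep, window: tuple | None = None) -> np.ndarray:
    """Ordered (V, dV/dt) pairs for a spike window (or the whole trace)."""
    d = dvdt(trace)
    if window is not None:
        sl = trace.window(*window)
    else:
        sl = slice(None)
    return np.column_stack([trace.y[sl], d[sl]])


def train_metrics(trace: Sweep, stimulus_window: tuple,
                  with_iff_series: bool = False) -> TrainFeatures:
    """Train-level excitability metrics over a stimulus window.

    ``spikes_per_s`` counts spikes in the window divided by its duration;
    the instantaneous firing frequency (IFF) is the reciprocal of the first
    interspike interval.  With fewer than two spikes the IFF (and ratios) are
    flagged ``None`` rather than silently zero.
    """
    t0, t1 = stimulus_window
    times = detect_spikes(trace)
    times = times[(times >= t0) & (times < t1)]
    sl = trace.window(t0, t1)
    mean_vm = float(np.mean(trace.y[sl]))
    n = len(times)
    spikes_per_s = n / ((t1 - t0) / 1000.0)
    iff = amp_ratio = maxd_ratio = None
    iff_series = None
    if n >= 2:
        isis = np.diff(times)
        iff = float(1000.0 / isis[0])
        if with_iff_series:
            iff_series = 1000.0 / isis
        try:
            f = [spike_features(trace, tt) for tt in (times[0], times[1], times[-1])]
            if f[0].max_depol_rate > 0:
                maxd_ratio = f[1].max_depol_rate / f[0].max_depol_rate
            if f[0].amplitude > 0:
                amp_ratio = f[2].amplitude / f[0].amplitude
        except ValueError:
            pass
    return TrainFeatures(spikes_per_s=spikes_per_s, iff_first_pair=iff,
                         amplitude_ratio_last_first=amp_ratio,
                         maxd_ratio_2nd_1st=maxd_ratio, mean_vm=mean_vm,
                         n_spikes=n, iff_series=iff_series)


def vm_residence(trace: Sweep, stimulus_window: tuple,
                 bin_width: float = 1.0):
    """Probability distribution of membrane potential over a window.

    Returns ``(bin_edges, probabilities)``; probabilities sum to 1.
    """
    sl = trace.window(*stimulus_window)
    v = trace.y[sl]
    lo = math.floor(v.min() / bin_width) * bin_width
    hi = math.ceil(v.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    return edges, counts / counts.sum()


def passive_props(trace: Sweep, step_pA: float, step_window: tuple,
                  baseline_window: tuple | None = None) -> PassiveProps:
    """Passive membrane properties from a hyperpolarizing current step.

    ``R_in`` is the steady-state voltage deflection over the injected
    current; ``tau_m`` is the time constant of a single-exponential fit to
    the onset; ``C_m = 1000 * tau_m / R_in`` (pF for ms and MOhm); the sag is
    the difference between the peak and steady-state deflections.
    """
    if step_pA >= 0:
        raise ValueError("passive_props expects a hyperpolarizing (negative) step")
    t0, t1 = step_window
    if baseline_window is None:
        baseline_window = (max(trace.t[0], t0 - 50.0), t0)
    v_base = float(np.mean(trace.y[trace.window(*baseline_window)]))
    sl = trace.window(t0, t1)
    seg_t, seg_v = trace.t[sl], trace.y[sl]
    n_ss = max(1, int(0.2 * len(seg_v)))
    v_ss = float(np.mean(seg_v[-n_ss:]))
    dv = v_ss - v_base
    r_in = dv / (step_pA * 1e-3)  # mV / nA = MOhm
    v_peak = float(np.min(seg_v))
    sag = abs(v_peak - v_ss)
    # tau from the onset relaxation, fit up to the peak (sag-free portion);
    # decimated for speed on long high-rate sweeps (the relaxation is slow)
    i_pk = int(np.argmin(seg_v)) + 1
    stride = max(1, i_pk // 1500)
    fit = fit_exp_decay(seg_t[:i_pk:stride], seg_v[:i_pk:stride])
    if not fit.success:
        raise RuntimeError(f"membrane time-constant fit failed: {fit.message}")
    tau_m = fit["tau"]
    c_m = 1000.0 * tau_m / r_in
    return PassiveProps(r_in=float(r_in), tau_m=float(tau_m), c_m=float(c_m),
                        sag=float(sag))


def estimate_peak_ina(c_m_pF: float, max_depol_rate_V_per_s: float) -> float:
    """Peak Na+ current (nA) from membrane capacitance and max dV/dt.

    I = C_m * max dV/dt; pF * V/s = pA, reported in nA.
    """
    if c_m_pF <= 0 or max_depol_rate_V_per_s <= 0:
        raise ValueError("capacitance and depolarization rate must be > 0")
    return c_m_pF * max_depol_rate_V_per_s * 1e-3
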