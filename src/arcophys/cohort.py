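"""Synthetic cohorts of cells and sweeps with the statistical structure of
the recorded group tables.

The generator draws per-cell parameters from Gaussian distributions whose
mean is the group mean and whose SD is SEM * sqrt(N) (the implied per-cell
SD), symmetrically truncated so that physical bounds are respected without
biasing the group mean (see :func:`_draw_truncated`).  From those parameters
it synthesizes:

* current-clamp spike trains whose waveform features (threshold, amplitude,
  half-width, maximum depolarization/repolarization rates) carry the drawn
  per-cell values by construction -- the spike template is assembled as a
  slope profile on the sample grid, so that the centered-difference
  derivative used downstream reads the programmed rates exactly, the
  10 V/s threshold criterion lands on the programmed threshold sample, and
  half-widths are matched to within half a sample;
* passive hyperpolarizing-step responses (analytic RC relaxation, optional
  sag component) from the drawn input resistance and capacitance;
* raw voltage-clamp sweep families (channel currents + linear leak +
  capacitive transients + P/4 subsweeps) wrapping the protocol simulator.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gating import ResurgentChannelParams
from .presets import cohort_table
from .sweeps import DT_40KHZ, Sweep, SweepSet, StepProtocol, resurgent_protocol
from .vc import NaTGateKinetics, run_resurgent_protocol

__all__ = [
    "CohortSpec",
    "NoiseModel",
    "generate_cohort",
    "synthesize_cc_sweep",
    "synthesize_passive_sweep",
    "synthesize_vc_sweepset",
    "extract_cell_features",
    "recover_cohort",
]

#: columns that carry a physical positivity bound
_POSITIVE = ("r_in", "tau_m", "c_m", "spont_freq", "hw", "amp",
             "max_depol", "max_repol")
#: voltage-threshold bounds, mV
_THRESHOLD_BOUNDS = (-75.0, -15.0)
#: slowest admissible spontaneous rate (Hz): a "spontaneously active" cell
#: must spike within the observation window; also bounds the trace length
_MIN_RATE_HZ = 0.5

#: correlation of the spike-speed columns (the two maximum rates move
#: together, and larger spikes come with faster rates), mirroring the
#: dominant principal component of the recorded waveforms
_SPEED_COLS = ["max_depol", "max_repol", "amp"]
_SPEED_CORR = np.array([[1.00, 0.95, 0.80],
                        [0.95, 1.00, 0.80],
                        [0.80, 0.80, 1.00]])


@dataclass(frozen=True)
class CohortSpec:
    """Per-group parameter statistics for the synthetic generator."""

    group: str
    params: dict          # column -> {"mean", "sem", "n", "recover"}
    channel_preset: str   # I_NaT preset name for VC synthesis

    @classmethod
    def from_group(cls, group: str) -> "CohortSpec":
        table = cohort_table()
        if group not in table:
            raise KeyError(f"unknown cohort group {group!r}; "
                           f"have {sorted(table)}")
        raw = dict(table[group])
        preset = raw.pop("channel_preset")
        raw.pop("extrapolated_passive", None)
        params = {}
        for col, d in raw.items():
            if d["sem"] < 0 or d["n"] < 1:
                raise ValueError(f"{group}.{col}: SEM must be >= 0 and N >= 1")
            params[col] = {"mean": float(d["mean"]), "sem": float(d["sem"]),
                           "n": int(d["n"]),
                           "recover": bool(d.get("recover", True))}
        return cls(group=group, params=params, channel_preset=preset)

    def sd(self, col: str) -> float:
        d = self.params[col]
        return d["sem"] * math.sqrt(d["n"])

    @property
    def recover_columns(self) -> list:
        return [c for c, d in self.params.items() if d["recover"]]


@dataclass(frozen=True)
class NoiseModel:
    """Additive instrument noise for synthesized sweeps.

    The current-clamp default is small compared with raw instrument noise
    because the reference recordings are low-pass filtered at acquisition,
    while the template path synthesizes the post-filter trace directly.
    """

    current_sd_pA: float = 2.0
    voltage_sd_mV: float = 0.005
    leak_jitter: float = 0.0   # fractional per-subsweep leak conductance jitter

    def __post_init__(self) -> None:
        if self.current_sd_pA < 0 or self.voltage_sd_mV < 0 or self.leak_jitter < 0:
            raise ValueError("noise SDs must be >= 0")


def _draw_truncated(rng, mean, sd, lo=-np.inf, hi=np.inf, size=1):
    """Gaussian draw with symmetric truncation at the nearest physical bound.

    The truncation half-width is min(3 SD, distance to either bound), applied
    on BOTH sides, so the draw respects the bounds while its expectation
    remains exactly ``mean``.
    """
    if sd == 0:
        return np.full(size, mean)
    k = min(3.0, (mean - lo) / sd, (hi - mean) / sd)
    if k <= 0:
        raise ValueError(f"group mean {mean} outside physical bounds ({lo}, {hi})")
    out = rng.normal(mean, sd, size)
    bad = np.abs(out - mean) > k * sd
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = np.abs(out - mean) > k * sd
    return out


def _cell_feasible(cell: dict, dt: float = DT_40KHZ) -> bool:
    """True when the drawn spike features can be rendered at the sampling rate.

    Joint tails (very fast rates with modest amplitude, or half-widths below
    the waveform floor implied by the drawn rates) cannot be represented by
    any 40 kHz trace; such cells are redrawn.
    """
    needed = ("threshold", "amp", "hw", "max_depol", "max_repol")
    if not all(k in cell for k in needed):
        return True
    try:
        _spike_profile(dt, cell["threshold"], cell["amp"], cell["hw"],
                       cell["max_depol"], cell["max_repol"], t_rec=8.0,
                       strict=True)
    except ValueError:
        return False
    return True


def generate_cohort(spec: CohortSpec, n_cells: int, seed: int) -> pd.DataFrame:
    """Draw ``n_cells`` parameter sets; bitwise reproducible from the seed.

    Columns are the spec's parameters plus ``g_scale`` (a per-cell channel
    conductance scaling factor) and the derived ``tau_rc`` (= R_in * C_m,
    the RC time constant actually used to synthesize the passive response;
    the printed R_in/tau_m/C_m means are not mutually consistent with the
    capacitance equation, so tau is derived rather than drawn).  Cells whose
    joint spike-feature draw is unrepresentable at 40 kHz are redrawn (see
    :func:`_cell_feasible`); the induced mean shift is measured in the test
    suite and is small compared with the recovery tolerances.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    bounds = {}
    for col in spec.params:
        if col == "threshold":
            bounds[col] = _THRESHOLD_BOUNDS
        elif col == "spont_freq":
            bounds[col] = (_MIN_RATE_HZ, np.inf)
        elif col in _POSITIVE:
            bounds[col] = (0.0, np.inf)
        else:
            bounds[col] = (-np.inf, np.inf)
    # the spike-speed columns (max rates, amplitude) are drawn jointly with
    # the correlation structure seen in the recordings; marginals (and thus
    # group means) are untouched
    speed = [c for c in _SPEED_COLS if c in spec.params]
    have_spikes = len(speed) == 3 and "hw" in spec.params
    chol = np.linalg.cholesky(_SPEED_CORR[np.ix_(
        [_SPEED_COLS.index(c) for c in speed],
        [_SPEED_COLS.index(c) for c in speed])]) if len(speed) > 1 else None

    def band_k(col):
        m, s = spec.params[col]["mean"], spec.sd(col)
        lo, hi = bounds[col]
        return min(3.0, (m - lo) / s if np.isfinite(lo) else 3.0,
                   (hi - m) / s if np.isfinite(hi) else 3.0)

    def draw_cell():
        cell = {}
        if chol is not None:
            while True:
                z = chol @ rng.standard_normal(len(speed))
                vals = {c: spec.params[c]["mean"] + spec.sd(c) * float(zz)
                        for c, zz in zip(speed, z)}
                # symmetric per-column bands keep the accepted mean unbiased
                if not all(spec.sd(c) == 0 or
                           abs(vals[c] - spec.params[c]["mean"]) <=
                           band_k(c) * spec.sd(c) for c in speed):
                    continue
                if have_spikes:
                    # the rise/fall must be representable at the sampling
                    # rate (trims a thin fast-rate/small-amplitude corner)
                    try:
                        _waveform_floor(DT_40KHZ, vals["amp"],
                                        vals["max_depol"], vals["max_repol"])
                    except ValueError:
                        continue
                cell.update(vals)
                break
        for col, d in spec.params.items():
            if col not in cell and col != "hw":
                cell[col] = float(_draw_truncated(
                    rng, d["mean"], spec.sd(col), *bounds[col])[0])
        if ("threshold" in cell and "amp" in cell
                and cell["threshold"] + cell["amp"] < -10.0):
            return None   # a spike must overshoot -10 mV; redraw the cell
        cell["g_scale"] = float(_draw_truncated(rng, 1.0, 0.1, 0.0, np.inf)[0])
        return cell

    rows = []
    for i in range(n_cells):
        for _ in range(1000):
            cell = draw_cell()
            if cell is not None:
                rows.append(cell)
                break
        else:  # pragma: no cover - would need a pathological spec
            raise RuntimeError(f"no feasible draw for {spec.group} cell {i}")
    # the half-width is built as the waveform floor implied by each cell's
    # rates plus a common excess, so every cell is representable at the
    # sampling rate and the group mean equals the table mean exactly; the
    # spread comes from the floor's natural variation plus a residual term
    if have_spikes:
        floors = np.array([_waveform_floor(DT_40KHZ, c["amp"], c["max_depol"],
                                           c["max_repol"]) for c in rows])
        hw_d = spec.params["hw"]
        mu_e = hw_d["mean"] - float(np.mean(floors))
        eps = DT_40KHZ
        if mu_e <= eps:
            raise ValueError(
                f"{spec.group}: table half-width {hw_d['mean']} ms is below "
                "the waveform floor implied by the group's rates")
        sd_e = min(math.sqrt(max(spec.sd("hw") ** 2 - float(np.var(floors)),
                                 0.0)), (mu_e - eps) / 3.0)
        e = _draw_truncated(rng, mu_e, sd_e, size=len(rows))
        for cell, fl, ee in zip(rows, floors, e):
            cell["hw"] = float(fl + ee)
    elif "hw" in spec.params:  # pragma: no cover - all groups have rates
        for cell in rows:
            cell["hw"] = float(_draw_truncated(
                rng, spec.params["hw"]["mean"], spec.sd("hw"), 0.0, np.inf)[0])
    df = pd.DataFrame(rows)
    df.insert(0, "cell", [f"{spec.group}_{i:04d}" for i in range(n_cells)])
    if "r_in" in df and "c_m" in df:
        df["tau_rc"] = df["r_in"] * df["c_m"] * 1e-3  # ms
    return df


# ---------------------------------------------------------------------------
# spike-train templates

def _cos_ramp(s0: float, s1: float, n: int) -> np.ndarray:
    """n interval slopes ramping smoothly from s0 to s1 (endpoints excluded)."""
    x = (np.arange(1, n + 1) - 0.5) / n
    return s0 + (s1 - s0) * 0.5 * (1.0 - np.cos(np.pi * x))


def _rise_profile(dt: float, amp: float, d_up: float):
    """Upstroke interval slopes from threshold to peak; see _spike_profile."""
    ramp1 = _cos_ramp(10.0, d_up, 2)
    if (ramp1.sum() + 2.0 * d_up) * dt > amp:
        ramp1 = ramp1[:0]       # jump straight to full speed
    dv_left = amp - ramp1.sum() * dt
    n2 = int(dv_left // (d_up * dt))
    if n2 < 2:
        raise ValueError("spike amplitude too small for the programmed rates")
    resid = (dv_left - n2 * d_up * dt) / dt   # leftover slope units
    # fold the leftover into the entry ramp where room allows (keeps the
    # profile one interval shorter, i.e. at the physical floor); whatever
    # cannot be absorbed becomes a final sub-maximal interval
    ramp1 = ramp1.copy()
    for j in range(ramp1.size):
        add = min(resid, d_up - ramp1[j])
        ramp1[j] += add
        resid -= add
    tail_up = np.array([resid]) if resid > 1e-9 else np.array([])
    up = np.concatenate([ramp1, np.full(n2, d_up), tail_up])
    cum = np.concatenate([[0.0], np.cumsum(up) * dt])
    t_half_rise = float(np.interp(amp / 2.0, cum, np.arange(cum.size) * dt))
    t_rise = (cum.size - 1) * dt - t_half_rise
    return up, t_rise


def _fall_profile(dt: float, amp: float, d_down: float):
    """Repolarization interval slopes from peak to the AHP floor."""
    depth = amp + 12.0          # nominal peak-to-AHP-floor depth
    n5 = max(2, int(math.ceil(0.55 * amp / (d_down * dt))))
    fall_head = np.full(n5, -d_down)
    dv_head = -fall_head.sum() * dt
    dv_tail = depth - dv_head
    if dv_tail <= 0:
        fall_tail = np.array([])
    else:
        tau6 = dv_tail / d_down
        n6 = int(math.ceil(tau6 / dt * math.log(d_down / 0.5))) if d_down > 0.5 else 1
        j = np.arange(1, max(n6, 1) + 1)
        fall_tail = -d_down * np.exp(-j * dt / tau6)
    fall = np.concatenate([fall_head, fall_tail])
    cumf = np.concatenate([[0.0], -np.cumsum(fall) * dt])  # depth below peak
    t_half_fall = float(np.interp(amp / 2.0, cumf, np.arange(cumf.size) * dt))
    return fall, cumf, t_half_fall


def _waveform_floor(dt: float, amp: float, d_up: float, d_down: float) -> float:
    """Smallest representable half-width for these rates (zero-length dwell)."""
    _, t_rise = _rise_profile(dt, amp, d_up)
    _, _, t_half_fall = _fall_profile(dt, amp, d_down)
    return t_rise + t_half_fall


def _spike_profile(dt: float, thr: float, amp: float, hw: float,
                   d_up: float, d_down: float, t_rec: float,
                   strict: bool = False):
    """Interval slopes (mV/ms) for one spike, baseline to end of recovery.

    Returns ``(slopes, i_thr, i_peak, v_rest)``: indices of the threshold
    and peak samples within the profile (sample i accumulates interval i)
    and the interspike baseline voltage the profile starts and ends at.
    The profile is built so that, after cumulative summation from
    ``v_rest``, the centered-difference derivative reads 10 V/s first at
    the threshold sample (where V = thr exactly), max d_up on the upstroke
    plateau and -d_down on the repolarization plateau, the peak equals
    thr + amp exactly, and the half-width matches ``hw`` to within half a
    sample.
    """
    if amp <= 0 or hw <= 0 or d_up <= 10.0 or d_down <= 0:
        raise ValueError("unphysical spike parameters")
    slopes = []
    # foot: quadratic sub-criterion approach ending exactly at threshold
    n_foot = max(4, int(round(2.0 / dt)))
    slopes.extend(9.0 * ((np.arange(1, n_foot + 1) / n_foot) ** 2))
    slopes.append(10.0)      # interval reaching the threshold sample
    i_thr = len(slopes) - 1  # sample index within the profile (see caller)
    dv_pre = float(np.sum(slopes)) * dt
    v_rest = thr - dv_pre    # baseline such that V(i_thr) = thr exactly

    # upstroke: optional short ramp 10 -> d_up, full-speed run at d_up (>= 2
    # intervals so interior samples read d_up exactly), then one residual
    # interval closing the amplitude; no deceleration ramp, keeping the
    # half-to-peak time near its physical floor (A/2)/d_up
    up, t_rise = _rise_profile(dt, amp, d_up)
    slopes.extend(up)

    # repolarization: optional short ramp 0 -> -d_down, full-speed plateau
    # carrying the half-amplitude crossing, exponential tail to the AHP floor
    fall, cumf, t_half_fall = _fall_profile(dt, amp, d_down)

    # peak dwell closes the half-width budget (zero-length dwell is fine:
    # the junction sample between upstroke and fall carries the exact peak)
    n_dwell = int(round((hw - t_rise - t_half_fall) / dt))
    if strict and n_dwell < 0:
        raise ValueError("half-width below the waveform floor for these rates")
    n_dwell = max(0, n_dwell)
    i_peak = i_thr + up.size   # first sample of the peak dwell
    slopes.extend(np.zeros(n_dwell))
    slopes.extend(fall)

    # recovery from the AHP floor back to the interspike baseline; slopes are
    # kept well below the threshold criterion so they never read as an upstroke
    dv_rec = float(cumf[-1]) - amp - dv_pre  # rise back to v_rest (> 0)
    n_rec = max(4, int(round(t_rec / dt)),
                int(math.ceil(2.0 * abs(dv_rec) / (6.0 * dt))))
    shape = 0.5 * (1.0 - np.cos(np.pi * np.arange(0, n_rec + 1) / n_rec))
    rec = dv_rec * np.diff(shape) / dt
    slopes.extend(rec)
    return np.asarray(slopes, dtype=float), i_thr, i_peak, v_rest


def synthesize_cc_sweep(cell, n_spikes: int = 3, rate_hz: float | None = None,
                        noise: NoiseModel | None = None, seed: int = 0,
                        dt: float = DT_40KHZ, pre_ms: float = 20.0) -> Sweep:
    """Current-clamp spike train carrying the cell's generating features.

    ``cell`` is a mapping with threshold/amp/hw/max_depol/max_repol (and
    spont_freq, used as the train rate when ``rate_hz`` is None).  Spike
    peaks are placed at exactly the interspike interval, so the mean rate
    measured from peak times reproduces the generating rate.  With noise
    disabled, repeated calls are identical.
    """
    if noise is None:
        noise = NoiseModel()
    thr = float(cell["threshold"])
    amp = float(cell["amp"])
    hw = float(cell["hw"])
    d_up = float(cell["max_depol"])
    d_down = float(cell["max_repol"])
    rate = float(rate_hz if rate_hz is not None else cell["spont_freq"])
    if rate <= 0:
        raise ValueError("train rate must be > 0")
    isi = 1000.0 / rate
    t_rec = min(8.0, 0.4 * isi)
    prof, i_thr, i_peak, v_rest = _spike_profile(dt, thr, amp, hw, d_up,
                                                 d_down, t_rec)
    if prof.size * dt > isi:
        raise ValueError(
            f"spike template ({prof.size * dt:.1f} ms) does not fit the "
            f"interspike interval ({isi:.1f} ms)")
    n_pre = int(round(pre_ms / dt))
    n_isi = int(round(isi / dt))
    n_total = n_pre + (n_spikes - 1) * n_isi + prof.size + n_pre
    slopes = np.zeros(n_total)
    for k in range(n_spikes):
        i0 = n_pre + k * n_isi
        slopes[i0:i0 + prof.size] = prof
    # sample i accumulates the interval ending at i; slopes[: n_pre] are zero
    v = v_rest + np.cumsum(slopes) * dt
    if noise.voltage_sd_mV > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise.voltage_sd_mV, v.size)
    t = np.arange(n_total) * dt
    return Sweep(t=t, y=v, command=np.zeros(n_total), y_units="mV",
                 command_units="pA",
                 meta={"kind": "cc_train", "rate_hz": rate, "dt": dt,
                       "truth": {k: float(cell[k]) for k in
                                 ("threshold", "amp", "hw", "max_depol",
                                  "max_repol")},
                       "first_peak_ms": (n_pre + i_peak) * dt,
                       "isi_ms": n_isi * dt})


def synthesize_passive_sweep(cell, step_pA: float = -150.0,
                             step_onset: float = 50.0,
                             step_duration: float | None = None,
                             sag_amp: float = 0.0, tau_sag: float = 60.0,
                             noise: NoiseModel | None = None, seed: int = 0,
                             dt: float = 0.1, v_rest: float = -70.0) -> Sweep:
    """Hyperpolarizing-step response of the cell's RC equivalent.

    The steady-state deflection is exactly R_in * I; a sag component of
    amplitude ``sag_amp`` (mV) rides on the onset and relaxes with
    ``tau_sag`` while leaving the steady state untouched, so measured R_in
    and sag both recover their generating values.
    """
    if noise is None:
        noise = NoiseModel()
    r_in = float(cell["r_in"])
    tau = float(cell["tau_rc"]) if "tau_rc" in cell else r_in * float(cell["c_m"]) * 1e-3
    if step_duration is None:
        # long enough for a clean steady state (and for the sag to settle)
        step_duration = max(8.0 * tau, 250.0)
        if sag_amp:
            step_duration = max(step_duration,
                                7.0 * tau + 35.0 + 5.0 * tau_sag + 60.0)
    dur_total = step_onset + step_duration + 100.0
    t = np.arange(int(round(dur_total / dt))) * dt
    v = np.full(t.size, v_rest)
    dv = r_in * step_pA * 1e-3  # MOhm * nA = mV
    inside = (t >= step_onset) & (t < step_onset + step_duration)
    ts = t[inside] - step_onset
    v[inside] = v_rest + dv * (1.0 - np.exp(-ts / tau))
    if sag_amp:
        # flat-topped dip placed after the RC transient has settled, so the
        # extracted |peak - steady state| equals sag_amp by construction
        t_on = 7.0 * tau
        x = np.clip((ts - t_on) / 15.0, 0.0, 1.0)
        w = 0.5 * (1.0 - np.cos(np.pi * x))
        after = ts > t_on + 35.0
        w[after] = np.exp(-(ts[after] - t_on - 35.0) / tau_sag)
        v[inside] -= sag_amp * w
    after = t >= step_onset + step_duration
    ta = t[after] - (step_onset + step_duration)
    v[after] = v_rest + dv * np.exp(-ta / tau)
    cmd = np.where(inside, step_pA, 0.0)
    if noise.voltage_sd_mV > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise.voltage_sd_mV, v.size)
    return Sweep(t=t, y=v, command=cmd, y_units="mV", command_units="pA",
                 meta={"kind": "cc_passive", "step_pA": step_pA,
                       "step_onset": step_onset, "step_duration": step_duration,
                       "dt": dt,
                       "truth": {"r_in": r_in, "tau_rc": tau,
                                 "sag": float(sag_amp)}})


# ---------------------------------------------------------------------------
# voltage clamp

#: series resistance and capacitive-transient time constant of the
#: linear-cell contamination model
_RS_MOHM = 10.0
_TAU_CAP_MS = 0.1


def _linear_response(cmd: np.ndarray, dt: float, hold: float,
                     g_leak_nS: float, e_leak: float) -> np.ndarray:
    """Leak + capacitive-transient current (nA) of a linear cell under VC."""
    I = g_leak_nS * (cmd - e_leak) * 1e-3
    # capacitive spikes: one exponential per command transition
    steps = np.nonzero(np.diff(cmd) != 0)[0]
    t = np.arange(cmd.size) * dt
    for i in steps:
        dv = cmd[i + 1] - cmd[i]
        amp = dv / _RS_MOHM  # mV / MOhm = nA
        tail = t[i + 1:] - t[i + 1]
        I[i + 1:] += amp * np.exp(-tail / _TAU_CAP_MS)
    return I


def synthesize_vc_sweepset(nat: NaTGateKinetics | None,
                           resurgent: ResurgentChannelParams | None,
                           protocol: StepProtocol | None = None,
                           noise: NoiseModel | None = None, seed: int = 0,
                           g_leak_nS: float = 3.0, e_leak: float = -90.0,
                           subtraction_holding: float = -120.0):
    """Raw VC sweep family plus P/4 subsweeps.

    Returns ``(raw SweepSet, dict test_level -> list of 4 subsweeps)``.
    Raw sweeps carry channel currents + linear leak + capacitive transients
    + current noise; subsweeps are recorded from a hyperpolarized
    subtraction holding at 1/4 command amplitude so that
    :func:`arcophys.vc.p4_subtract` recovers the channel currents within
    noise.
    """
    if protocol is None:
        protocol = resurgent_protocol()
    if noise is None:
        noise = NoiseModel()
    rng = np.random.default_rng(seed)
    clean = run_resurgent_protocol(resurgent=resurgent, nat=nat,
                                   protocol=protocol)
    raw_sweeps = []
    subs = {}
    for sweep in clean:
        cmd = sweep.command
        lin = _linear_response(cmd, protocol.dt, protocol.holding,
                               g_leak_nS, e_leak)
        y = sweep.y + lin
        if noise.current_sd_pA > 0:
            y = y + rng.normal(0.0, noise.current_sd_pA * 1e-3, y.size)
        raw_sweeps.append(Sweep(t=sweep.t, y=y, command=cmd, y_units="nA",
                                meta=dict(sweep.meta, raw=True)))
        level = sweep.meta["test_level"]
        sub_cmd = subtraction_holding + (cmd - protocol.holding) / 4.0
        four = []
        for k in range(4):
            g_eff = g_leak_nS
            if noise.leak_jitter:
                g_eff = g_leak_nS * (1.0 + noise.leak_jitter * rng.normal())
            ysub = _linear_response(sub_cmd, protocol.dt, subtraction_holding,
                                    g_eff, e_leak)
            if noise.current_sd_pA > 0:
                ysub = ysub + rng.normal(0.0, noise.current_sd_pA * 1e-3,
                                         ysub.size)
            four.append(Sweep(t=sweep.t, y=ysub, command=sub_cmd,
                              y_units="nA",
                              meta=dict(sweep.meta, p4_subsweep=k)))
        subs[level] = four
    return SweepSet(sweeps=raw_sweeps, meta=dict(clean.meta, raw=True)), subs


# ---------------------------------------------------------------------------
# end-to-end pipeline: cohort -> sweeps -> extracted features

def extract_cell_features(cc: Sweep, passive: Sweep) -> dict:
    """Run the current-clamp analysis stack on one cell's synthetic sweeps."""
    from .ap import detect_spikes, passive_props, spike_features

    times = detect_spikes(cc)
    if len(times) == 0:
        raise RuntimeError("no spikes detected in synthetic train")
    feats = [spike_features(cc, tt) for tt in times
             if tt - cc.t[0] >= 2.0 and cc.t[-1] - tt >= 2.0]
    out = {
        "threshold": float(np.mean([f.threshold for f in feats])),
        "amp": float(np.mean([f.amplitude for f in feats])),
        "hw": float(np.mean([f.half_width for f in feats])),
        "max_depol": float(np.mean([f.max_depol_rate for f in feats])),
        "max_repol": float(np.mean([f.max_repol_rate for f in feats])),
    }
    if len(times) >= 2:
        out["spont_freq"] = 1000.0 * (len(times) - 1) / (times[-1] - times[0])
    pp = passive_props(passive, passive.meta["step_pA"],
                       (passive.meta["step_onset"],
                        passive.meta["step_onset"] + passive.meta["step_duration"]))
    out["r_in"] = pp.r_in
    out["tau_m"] = pp.tau_m
    out["c_m"] = pp.c_m
    out["sag"] = pp.sag
    return out


def recover_cohort(group: str, n_cells: int, seed: int,
                   noise: NoiseModel | None = None):
    """Generate a cohort, synthesize sweeps, extract features per cell.

    Returns ``(spec, cohort DataFrame, extracted DataFrame)``; the extracted
    frame has one row per cell with the columns of the group table that the
    pipeline recovers.
    """
    spec = CohortSpec.from_group(group)
    cohort = generate_cohort(spec, n_cells, seed)
    rows = []
    for i, cell in cohort.iterrows():
        cc = synthesize_cc_sweep(cell, noise=noise, seed=seed + 1000 + i)
        pas = synthesize_passive_sweep(cell, noise=noise, seed=seed + 5000 + i)
        rows.append(extract_cell_features(cc, pas))
    return spec, cohort, pd.DataFrame(rows)
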