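"""Voltage-clamp protocol, measurement and fitting tests."""

import numpy as np
import pytest

from arcophys.cohort import NoiseModel, synthesize_vc_sweepset
from arcophys.presets import (G_NAR_JUVENILE, nat_gate_kinetics,
                              resurgent_channel)
from arcophys.sweeps import Sweep, resurgent_protocol
from arcophys.vc import (detect_onset, fit_boltzmann_iv, fit_exp_decay,
                         fit_powerlaw_onset, measure_iv, measure_peaks,
                         p4_subtract, run_resurgent_protocol)


@pytest.fixture(scope="module")
def fast_protocol():
    return resurgent_protocol(dt=0.03)


@pytest.fixture(scope="module")
def adult_sweeps(fast_protocol):
    return run_resurgent_protocol(resurgent=resurgent_channel(),
                                  nat=nat_gate_kinetics("adult_24C"),
                                  protocol=fast_protocol)


class TestProtocol:
    def test_default_levels(self, fast_protocol):
        assert fast_protocol.test_levels == (15.0, 0.0, -15.0, -30.0, -45.0,
                                             -60.0, -75.0)
        assert fast_protocol.holding == -90.0
        assert fast_protocol.segments == ((30.0, 10.0),)

    def test_zero_conductance_gives_zero_sweeps(self, fast_protocol):
        ss = run_resurgent_protocol(resurgent=resurgent_channel(g_NaR=0.0),
                                    protocol=fast_protocol)
        assert len(ss) == 7
        for sw in ss:
            assert np.allclose(sw.y, 0.0)

    def test_peak_resurgent_level_is_minus_45(self, adult_sweeps):
        iv = measure_iv(adult_sweeps)
        assert iv.peak_level == -45.0

    def test_peak_level_invariant_under_conductance_scaling(self, fast_protocol):
        for g in (0.5, 2.0):
            ss = run_resurgent_protocol(
                resurgent=resurgent_channel().with_conductance(g),
                protocol=fast_protocol)
            assert measure_iv(ss).peak_level == -45.0

    def test_adult_normalization_anchor(self, adult_sweeps):
        iv = measure_iv(adult_sweeps)
        i45 = np.argwhere(iv.V == -45.0)[0][0]
        assert iv.I_norm[i45] == pytest.approx(0.28, abs=0.02)
        assert np.argmax(iv.I_norm) == i45
        assert np.all(iv.I_norm < 1.0) and np.all(iv.I_norm >= 0.0)

    def test_juvenile_resurgent_nearly_absent(self, fast_protocol):
        ss = run_resurgent_protocol(
            resurgent=resurgent_channel(g_NaR=G_NAR_JUVENILE),
            nat=nat_gate_kinetics("juvenile_20dph_24C"),
            protocol=fast_protocol)
        assert measure_iv(ss).I_norm.max() < 0.05

    def test_decay_tau_envelope(self, adult_sweeps):
        # single-exponential decay constants between 2 and 45 ms over the
        # -75..-15 mV test range, increasing with depolarization
        taus = {}
        for sw in adult_sweeps:
            lvl = sw.meta["test_level"]
            if not (-75.0 <= lvl <= -15.0):
                continue
            w = sw.window(sw.meta["test_onset"] + 0.5, sw.t[-1])
            seg_t, seg_y = sw.t[w], sw.y[w]
            i_pk = int(np.argmin(seg_y))
            fit = fit_exp_decay(seg_t[i_pk:], seg_y[i_pk:])
            assert fit.success
            taus[lvl] = fit["tau"]
        levels = sorted(taus)
        vals = [taus[v] for v in levels]
        assert all(2.0 <= t <= 45.0 for t in vals)
        assert vals == sorted(vals)  # monotone with depolarization


class TestMeasurePeaks:
    def test_exact_recovery_of_injected_peaks(self):
        dt = 0.025
        t = np.arange(0, 40, dt)
        y = np.zeros_like(t)
        y[(t >= 6) & (t < 7)] = -3.5    # conditioning-window peak
        y[(t >= 20) & (t < 22)] = -1.4  # test-window peak
        sw = Sweep(t=t, y=y, command=np.zeros_like(t),
                   meta={"conditioning_onset": 5.0, "test_onset": 15.0})
        pk_nat, pk_nar, norm = measure_peaks(sw)
        assert (pk_nat, pk_nar) == (-3.5, -1.4)
        assert norm == pytest.approx(1.4 / 3.5)

    def test_empty_window_is_an_error(self):
        t = np.arange(0, 10, 0.025)
        sw = Sweep(t=t, y=np.zeros_like(t), command=np.zeros_like(t),
                   meta={"conditioning_onset": 5.0, "test_onset": 8.0})
        with pytest.raises(ValueError):
            measure_peaks(sw, nat_window=(5.0, 5.0))


class TestExpDecayFit:
    def test_noiseless_recovery(self):
        t = np.arange(0, 60, 0.025)
        y = -2.0 * np.exp(-t / 5.0) + 0.1
        fit = fit_exp_decay(t, y)
        assert fit.success
        assert fit["tau"] == pytest.approx(5.0, rel=1e-3)
        assert fit["A"] == pytest.approx(-2.0, rel=1e-3)

    def test_constant_segment_flagged(self):
        t = np.arange(0, 10, 0.025)
        fit = fit_exp_decay(t, np.full_like(t, 0.7))
        assert not fit.success

    def test_rising_segment_not_reported_as_decay(self):
        t = np.arange(0, 10, 0.025)
        fit = fit_exp_decay(t, t * 0.3)
        assert (not fit.success) or fit["tau"] > 0


class TestOnsetDetection:
    def _step_sweep(self, delay, dt=0.025, noise=0.0, seed=0):
        t = np.arange(0, 20, dt)
        y = np.zeros_like(t)
        onset = 10.0 + delay
        y[t >= onset] = -2.0 * (1 - np.exp(-(t[t >= onset] - onset) / 0.2))
        if noise:
            y = y + np.random.default_rng(seed).normal(0, noise, y.size)
        return Sweep(t=t, y=y, command=np.zeros_like(t))

    def test_zero_delay_detected_within_one_sample(self):
        sw = self._step_sweep(0.0)
        lat = detect_onset(sw, stim_onset=10.0)
        assert lat is not None and lat <= sw.dt + 1e-12

    @pytest.mark.parametrize("delay", [0.11, 0.17])
    def test_programmed_delays_recovered(self, delay):
        sw = self._step_sweep(delay, noise=0.002, seed=3)
        lat = detect_onset(sw, stim_onset=10.0)
        assert lat == pytest.approx(delay, abs=sw.dt)

    def test_flat_trace_reports_no_onset(self):
        t = np.arange(0, 20, 0.025)
        sw = Sweep(t=t, y=np.zeros_like(t), command=np.zeros_like(t))
        assert detect_onset(sw, stim_onset=10.0) is None


class TestP4Subtraction:
    def test_linear_cell_annihilated_to_machine_precision(self):
        raw, subs = synthesize_vc_sweepset(None, None,
                                           noise=NoiseModel(0.0, 0.0, 0.0))
        for sw in raw:
            corrected = p4_subtract(sw, subs[sw.meta["test_level"]])
            scale = np.max(np.abs(sw.y))
            assert np.max(np.abs(corrected.y)) < 1e-9 * scale

    def test_superposition_recovers_channel_current(self, fast_protocol):
        clean = run_resurgent_protocol(resurgent=resurgent_channel(),
                                       nat=nat_gate_kinetics("adult_24C"),
                                       protocol=fast_protocol)
        raw, subs = synthesize_vc_sweepset(nat_gate_kinetics("adult_24C"),
                                           resurgent_channel(),
                                           protocol=fast_protocol,
                                           noise=NoiseModel(0.0, 0.0, 0.0))
        for sw_clean, sw_raw in zip(clean, raw):
            corrected = p4_subtract(sw_raw, subs[sw_raw.meta["test_level"]])
            # corrected traces are baseline-zeroed by construction, so the
            # clean channel current is recovered up to its resting offset
            base = sw_clean.window(0.0, sw_clean.meta["conditioning_onset"])
            expect = sw_clean.y - np.mean(sw_clean.y[base])
            assert np.allclose(corrected.y, expect, atol=1e-6)

    def test_zero_amplitude_command_leaves_main_untouched(self):
        t = np.arange(0, 10, 0.025)
        y = np.sin(t)
        main = Sweep(t=t, y=y, command=np.full_like(t, -90.0),
                     meta={"conditioning_onset": 2.0})
        subs = [Sweep(t=t, y=np.zeros_like(t), command=np.full_like(t, -120.0))
                for _ in range(4)]
        corrected = p4_subtract(main, subs)
        assert np.allclose(corrected.y, y - np.mean(y[t < 2.0]))

    def test_wrong_subsweep_count_rejected(self):
        t = np.arange(0, 5, 0.025)
        sw = Sweep(t=t, y=np.zeros_like(t), command=np.zeros_like(t))
        with pytest.raises(ValueError):
            p4_subtract(sw, [sw, sw, sw])


class TestBoltzmannFit:
    def test_noiseless_round_trip(self, adult_nat):
        from arcophys.nat import boltzmann_iv
        V = np.arange(-70.0, 61.0, 10.0)
        fit = fit_boltzmann_iv(V, boltzmann_iv(V, adult_nat))
        assert fit.success
        for key, truth in (("g_max", 174.0), ("V_rev", 66.5),
                           ("V_half", -44.6), ("k", 6.6)):
            assert fit[key] == pytest.approx(truth, rel=1e-3)

    def test_flat_curve_flagged_degenerate(self):
        V = np.arange(-70.0, 61.0, 10.0)
        fit = fit_boltzmann_iv(V, np.zeros_like(V))
        assert not fit.success
        assert fit.params.get("g_max") == 0.0

    def test_too_few_points_rejected(self):
        fit = fit_boltzmann_iv(np.array([-60., -30., 0., 30., 60.]),
                               np.array([0., -1., -2., -1., 1.]))
        assert not fit.success


class TestPowerLawFit:
    def test_noiseless_round_trip(self):
        dt = 0.0025
        t = np.arange(0, 2.0, dt)
        y = -5.0 * (1 - np.exp(-t / 0.10)) ** 10.7
        fit = fit_powerlaw_onset(t, y)
        assert fit.success
        assert fit["tau_a"] == pytest.approx(0.10, rel=1e-3)
        assert fit["N"] == pytest.approx(10.7, rel=0.05)

    def test_exponent_one_reduces_to_single_exponential_rise(self):
        # with N = 1 the rise is 1 - e^(-t/tau): its mirror image is the
        # plain exponential decay, so both fitters must agree on tau
        dt = 0.005
        t = np.arange(0, 3.0, dt)
        tau = 0.4
        rise = -2.0 * (1 - np.exp(-t / tau))
        fit = fit_powerlaw_onset(t, rise, peak_fraction=0.95)
        mirror = fit_exp_decay(t, -2.0 * np.exp(-t / tau))
        assert fit.success and mirror.success
        assert fit["tau_a"] == pytest.approx(mirror["tau"], rel=0.02)

    def test_window_too_short_rejected(self):
        t = np.arange(0, 0.05, 0.025)
        with pytest.raises(ValueError):
            fit_powerlaw_onset(t, -np.linspace(0, 1, t.size))
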