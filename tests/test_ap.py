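"""Current-clamp feature extraction tests."""

import numpy as np
import pytest

from arcophys.ap import (detect_spikes, estimate_peak_ina, passive_props,
                         phase_plane, spike_features, train_metrics,
                         vm_residence)
from arcophys.cohort import NoiseModel, synthesize_cc_sweep
from arcophys.sweeps import Sweep


def template_train(threshold=-50.0, amp=90.0, hw=0.8, max_depol=400.0,
                   max_repol=120.0, rate=10.0, n_spikes=3, dt=0.025,
                   noise=0.0):
    cell = {"threshold": threshold, "amp": amp, "hw": hw,
            "max_depol": max_depol, "max_repol": max_repol,
            "spont_freq": rate}
    return synthesize_cc_sweep(cell, n_spikes=n_spikes, dt=dt,
                               noise=NoiseModel(voltage_sd_mV=noise))


class TestDetectSpikes:
    def test_flat_trace_has_no_spikes(self):
        t = np.arange(0, 1000, 0.025)
        sw = Sweep(t=t, y=np.full_like(t, -70.0), command=np.zeros_like(t),
                   y_units="mV")
        assert detect_spikes(sw).size == 0

    def test_known_spike_count_recovered(self):
        sw = template_train(rate=9.0, n_spikes=9)
        assert detect_spikes(sw).size == 9

    def test_regular_train_rate_readout(self):
        # 9 spikes at a 9 Hz interspike interval -> measured rate 9 Hz
        sw = template_train(rate=9.0, n_spikes=9)
        times = detect_spikes(sw)
        rate = 1000.0 * (times.size - 1) / (times[-1] - times[0])
        assert rate == pytest.approx(9.0, rel=1e-3)


class TestSpikeFeatures:
    def test_template_features_recovered_exactly(self):
        sw = template_train()
        f = spike_features(sw, detect_spikes(sw)[0])
        assert f.threshold == pytest.approx(-50.0, abs=1e-9)
        assert f.amplitude == pytest.approx(90.0, abs=1e-9)
        assert f.max_depol_rate == pytest.approx(400.0, abs=1e-9)
        assert f.max_repol_rate == pytest.approx(120.0, abs=1e-9)
        assert f.half_width == pytest.approx(0.8, abs=0.013)

    def test_subthreshold_ramp_rejected(self):
        t = np.arange(0, 100, 0.025)
        sw = Sweep(t=t, y=-70.0 + 0.005 * t, command=np.zeros_like(t),
                   y_units="mV")
        with pytest.raises(ValueError):
            spike_features(sw, 50.0)

    def test_sampling_rate_stability(self):
        # features at 40 vs 80 kHz on the same waveform differ < 2%
        f40 = spike_features(*(lambda s: (s, detect_spikes(s)[0]))(
            template_train(dt=0.025)))
        f80 = spike_features(*(lambda s: (s, detect_spikes(s)[0]))(
            template_train(dt=0.0125)))
        for attr in ("threshold", "amplitude", "half_width",
                     "max_depol_rate", "max_repol_rate"):
            a, b = getattr(f40, attr), getattr(f80, attr)
            assert abs(a - b) / abs(b) < 0.02


class TestPhasePlane:
    def test_sinusoid_traces_an_ellipse(self):
        dt = 0.025
        t = np.arange(0, 20, dt)
        sw = Sweep(t=t, y=10 * np.sin(2 * np.pi * t / 5.0),
                   command=np.zeros_like(t), y_units="mV")
        pp = phase_plane(sw)
        # (V/a)^2 + (dVdt/(a*omega))^2 = 1 away from the trace edges
        a, omega = 10.0, 2 * np.pi / 5.0
        r = (pp[2:-2, 0] / a) ** 2 + (pp[2:-2, 1] / (a * omega)) ** 2
        assert np.allclose(r, 1.0, atol=1e-3)

    def test_max_dvdt_consistent_with_spike_features(self):
        sw = template_train()
        t0 = detect_spikes(sw)[0]
        f = spike_features(sw, t0)
        pp = phase_plane(sw, window=(t0 - 3.0, t0 + 3.0))
        assert pp[:, 1].max() == pytest.approx(f.max_depol_rate, rel=1e-9)


class TestTrainMetrics:
    def test_iff_from_first_pair(self):
        sw = template_train(rate=100.0, n_spikes=3)  # 10 ms ISI
        tm = train_metrics(sw, (0.0, sw.t[-1]))
        assert tm.iff_first_pair == pytest.approx(100.0, rel=1e-6)

    def test_single_spike_flags_missing_iff(self):
        sw = template_train(n_spikes=1)
        tm = train_metrics(sw, (0.0, sw.t[-1]))
        assert tm.n_spikes == 1 and tm.iff_first_pair is None

    def test_identical_spikes_have_unit_ratios(self):
        sw = template_train(n_spikes=4, rate=20.0)
        tm = train_metrics(sw, (0.0, sw.t[-1]))
        assert tm.maxd_ratio_2nd_1st == pytest.approx(1.0, abs=1e-6)
        assert tm.amplitude_ratio_last_first == pytest.approx(1.0, abs=1e-6)


class TestVmResidence:
    def test_constant_trace_single_bin(self):
        t = np.arange(0, 100, 0.025)
        sw = Sweep(t=t, y=np.full_like(t, -70.0), command=np.zeros_like(t),
                   y_units="mV")
        edges, p = vm_residence(sw, (0.0, 100.0))
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.count_nonzero(p) == 1

    def test_probabilities_sum_to_one_and_mean_matches(self):
        sw = template_train(rate=20.0, n_spikes=4)
        edges, p = vm_residence(sw, (0.0, sw.t[-1]), bin_width=0.5)
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        centers = (edges[:-1] + edges[1:]) / 2
        vm = sw.y[sw.window(0.0, sw.t[-1])]
        assert np.sum(centers * p) == pytest.approx(vm.mean(), abs=0.5)

    def test_adult_like_train_more_hyperpolarized_than_juvenile_like(self):
        # narrow fast adult spikes at high rate vs broad slow juvenile
        # spikes: the adult-like train has the lower mean Vm and the lower
        # modal residence probability
        adult = template_train(threshold=-54.0, amp=90.5, hw=0.6,
                               max_depol=534.5, max_repol=181.9,
                               rate=80.0, n_spikes=20)
        juv = template_train(threshold=-43.7, amp=85.1, hw=1.8,
                             max_depol=260.0, max_repol=42.8,
                             rate=30.0, n_spikes=8)
        wa = (0.0, adult.t[-1])
        wj = (0.0, juv.t[-1])
        assert np.mean(adult.y[adult.window(*wa)]) < np.mean(juv.y[juv.window(*wj)])
        _, pa = vm_residence(adult, wa)
        _, pj = vm_residence(juv, wj)
        assert pa.max() < pj.max()


class TestPassiveProps:
    def test_rc_cell_recovered_below_one_percent(self):
        # R = 200 MOhm, C = 100 pF -> tau = 20 ms
        dt = 0.05
        t = np.arange(0, 600, dt)
        v = np.full_like(t, -70.0)
        inside = (t >= 100) & (t < 500)
        ts = t[inside] - 100.0
        v[inside] = -70.0 + 200.0 * (-0.150) * (1 - np.exp(-ts / 20.0))
        sw = Sweep(t=t, y=v, command=np.where(inside, -150.0, 0.0),
                   y_units="mV", command_units="pA")
        pp = passive_props(sw, -150.0, (100.0, 500.0))
        assert pp.r_in == pytest.approx(200.0, rel=0.01)
        assert pp.tau_m == pytest.approx(20.0, rel=0.01)
        assert pp.c_m == pytest.approx(100.0, rel=0.01)
        assert pp.sag == pytest.approx(0.0, abs=0.05)

    def test_depolarizing_step_rejected(self):
        t = np.arange(0, 100, 0.05)
        sw = Sweep(t=t, y=np.full_like(t, -70.0), command=np.zeros_like(t),
                   y_units="mV")
        with pytest.raises(ValueError):
            passive_props(sw, 150.0, (10.0, 90.0))

    def test_surrogate_sag_near_recorded_magnitude(self):
        # passive configuration of the adult surrogate: ~5 mV sag at -150 pA
        from dataclasses import replace

        from arcophys.dynclamp import neuron_preset, simulate_neuron
        p = replace(neuron_preset("adult"), g_na=0.0, g_k=0.0)
        sw = simulate_neuron(p, step_pA=-150.0, duration=1000.0,
                             step_onset=200.0, step_duration=600.0)
        pp = passive_props(sw, -150.0, (200.0, 800.0))
        assert pp.sag == pytest.approx(5.0, abs=0.5)

    def test_no_sag_conductance_means_no_sag(self):
        from dataclasses import replace

        from arcophys.dynclamp import neuron_preset, simulate_neuron
        p = replace(neuron_preset("adult"), g_na=0.0, g_k=0.0, g_sag=0.0)
        sw = simulate_neuron(p, step_pA=-150.0, duration=1000.0,
                             step_onset=200.0, step_duration=600.0)
        pp = passive_props(sw, -150.0, (200.0, 800.0))
        assert pp.sag == pytest.approx(0.0, abs=0.05)
        assert pp.r_in == pytest.approx(190.2, rel=0.01)
        assert pp.c_m == pytest.approx(114.3, rel=0.02)


class TestEstimatePeakINa:
    def test_unit_identity(self):
        assert estimate_peak_ina(1.0, 1.0) == pytest.approx(0.001)

    def test_adult_worked_example(self):
        assert estimate_peak_ina(114.0, 534.5) == pytest.approx(60.9, abs=0.05)

    def test_rejects_nonpositive_inputs(self):
        with pytest.raises(ValueError):
            estimate_peak_ina(-1.0, 100.0)


class TestHalfWidthNarrowsWithFasterRepolarization:
    def test_surrogate_hw_monotone_in_k_current_speed(self):
        # speeding up the delayed rectifier narrows the surrogate's spike
        from dataclasses import replace

        from arcophys.dynclamp import neuron_preset, simulate_neuron
        hws = []
        for tau_n in (1.6, 1.0, 0.7):
            p = replace(neuron_preset("adult"), tau_n=tau_n)
            sw = simulate_neuron(p, step_pA=500.0, duration=400.0,
                                 step_onset=100.0, step_duration=300.0)
            times = detect_spikes(sw)
            f = spike_features(sw, times[1])
            hws.append(f.half_width)
        assert hws[0] > hws[1] > hws[2]
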