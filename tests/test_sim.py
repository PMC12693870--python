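"""Simulator: kinematics, arrivals, rendering, noise filtering, composition."""
import numpy as np
import pytest
from scipy import signal as sps

import pulsekit as pk
from pulsekit.errors import ConfigError
from pulsekit.sim import (
    event_rate_per_s,
    filter_noise,
    per_stage_cutoff_hz,
    render_events,
    sample_true_events,
)

from conftest import analytic_extrema


class TestKinematics:
    def test_mean_velocity_from_flow_and_cross_section(self):
        # 2 uL/min = 3.333e7 um^3/s over a 900 um^2 cross-section
        kin = pk.derive_kinematics(pk.SimulationConfig(Q_uL_min=2.0))
        assert kin.v_um_s == pytest.approx(3.7037e4, rel=1e-3)

    def test_peak_separation_is_pitch_over_velocity(self):
        kin = pk.derive_kinematics(pk.SimulationConfig(Q_uL_min=2.0))
        assert kin.delta_s == pytest.approx(40.0 / 37037.037, rel=1e-6)
        assert kin.delta_s == pytest.approx(1.080e-3, rel=1e-3)

    def test_doubling_flow_halves_separation(self):
        k1 = pk.derive_kinematics(pk.SimulationConfig(Q_uL_min=1.5))
        k2 = pk.derive_kinematics(pk.SimulationConfig(Q_uL_min=3.0))
        assert k1.delta_s == pytest.approx(2.0 * k2.delta_s, rel=1e-12)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ConfigError):
            pk.SimulationConfig(Q_uL_min=-1.0)
        with pytest.raises(ConfigError):
            pk.SimulationConfig(channel_side_um=0.0)


class TestArrivals:
    def test_rate_is_concentration_times_flow(self):
        cfg = pk.SimulationConfig(rho_per_uL=1e3, Q_uL_min=2.0)
        assert event_rate_per_s(cfg) == pytest.approx(1000.0 * 2.0 / 60.0)

    def test_zero_cv_gives_exact_diameters(self):
        cfg = pk.SimulationConfig(CV=0.0, duration_s=5.0)
        evs = sample_true_events(cfg, np.random.default_rng(0))
        assert all(ev.d_um == cfg.D_um for ev in evs)

    def test_poisson_count_moment(self):
        # empirical mean count over repetitions within 3 standard errors of
        # lambda * T = 33.33/s * 30 s = 1000
        cfg = pk.SimulationConfig(duration_s=30.0)
        reps = 200
        counts = [
            len(sample_true_events(cfg, np.random.default_rng(10_000 + i)))
            for i in range(reps)
        ]
        lam_t = event_rate_per_s(cfg) * cfg.duration_s
        se = np.sqrt(lam_t / reps)
        assert abs(np.mean(counts) - lam_t) < 3 * se

    def test_events_sorted_and_peaks_straddle_center(self):
        cfg = pk.SimulationConfig(duration_s=5.0)
        evs = sample_true_events(cfg, np.random.default_rng(3))
        t0s = [ev.t0_s for ev in evs]
        assert t0s == sorted(t0s)
        for ev in evs[:20]:
            assert ev.t_pos_s < ev.t0_s < ev.t_neg_s
            assert ev.t_neg_s - ev.t_pos_s == pytest.approx(ev.delta_s)


class TestRendering:
    def test_zero_at_event_center(self, clean_single_pulse):
        ev, trace = clean_single_pulse
        i0 = trace.time_to_index(ev.t0_s)
        # odd symmetry about the center: the value at t0 is zero (within one
        # grid step of interpolation error)
        assert abs(trace.samples[i0]) < 1e-2 * ev.A_V

    def test_maximum_matches_closed_form(self, clean_single_pulse):
        # for delta = 4 sigma the positive peak is A(1 - e^-8)
        ev, trace = clean_single_pulse
        assert ev.delta_s == pytest.approx(4.0 * ev.sigma_s)
        expected = ev.A_V * (1.0 - np.exp(-8.0))
        assert trace.samples.max() == pytest.approx(expected, rel=1e-4)

    def test_antisymmetric_lobes_integrate_to_zero(self, clean_single_pulse):
        ev, trace = clean_single_pulse
        integral = trace.samples.sum() / trace.fs_Sa_s
        assert abs(integral) < 1e-9 * ev.A_V * ev.sigma_s / 1e-3

    def test_rendering_is_linear(self, default_kinematics):
        kin = default_kinematics
        fs = 115_100.0
        grid = pk.TimeGrid(int(0.2 * fs), fs)
        evs = []
        for t0, a in ((0.05, 5e-6), (0.11, 8e-6)):
            evs.append(pk.TrueEvent(
                t0_s=t0, d_um=2.0, A_V=a, delta_s=kin.delta_s,
                sigma_s=kin.sigma_s, t_pos_s=t0 - kin.delta_s / 2,
                t_neg_s=t0 + kin.delta_s / 2, label="x"))
        summed = pk.render_event(evs[0], grid).samples + pk.render_event(evs[1], grid).samples
        joint = render_events(evs, grid).samples
        np.testing.assert_allclose(joint, summed, rtol=0, atol=1e-20)

    def test_event_outside_grid_renders_zero(self, default_kinematics):
        kin = default_kinematics
        ev = pk.TrueEvent(t0_s=10.0, d_um=2.0, A_V=1e-6, delta_s=kin.delta_s,
                          sigma_s=kin.sigma_s, t_pos_s=10.0 - kin.delta_s / 2,
                          t_neg_s=10.0 + kin.delta_s / 2, label="x")
        grid = pk.TimeGrid(1000, 115_100.0)
        assert not pk.render_event(ev, grid).samples.any()

    def test_true_peak_times_near_analytic_extrema(self, default_kinematics):
        # the stored +-delta/2 convention agrees with the exact extrema to
        # well under a sample at default timing
        kin = default_kinematics
        t_pos, t_neg = analytic_extrema(1.0, kin.sigma_s, kin.delta_s, 0.0)
        assert t_pos == pytest.approx(-kin.delta_s / 2, abs=0.02 * kin.sigma_s)
        assert t_neg == pytest.approx(+kin.delta_s / 2, abs=0.02 * kin.sigma_s)


class TestNoiseFilter:
    def test_per_stage_cutoff(self):
        # 4 stages at 500 Hz overall: f1 = 500 / sqrt(2^0.25 - 1)
        assert per_stage_cutoff_hz(4, 500.0) == pytest.approx(1149.48, rel=1e-4)
        assert per_stage_cutoff_hz(1, 500.0) == pytest.approx(500.0)

    def test_unity_dc_gain(self):
        fs = 115_100.0
        const = pk.SignalTrace(np.full(40_000, 2.5), fs)
        out = filter_noise(const, 4, 500.0).samples
        assert out[-1] == pytest.approx(2.5, rel=1e-6)

    def test_minus_3db_at_bandwidth(self):
        # sine probe at BW: cascade magnitude response within +-0.2 dB of -3 dB
        fs, bw = 115_100.0, 500.0
        t = np.arange(int(4 * fs)) / fs
        probe = pk.SignalTrace(np.sin(2 * np.pi * bw * t), fs)
        out = filter_noise(probe, 4, bw).samples
        tail = out[out.size // 2:]
        gain_db = 20 * np.log10(np.sqrt(2) * tail.std())
        assert gain_db == pytest.approx(-3.01, abs=0.2)

    def test_bandwidth_must_be_below_nyquist(self):
        fs = 10_000.0
        white = pk.SignalTrace(np.random.default_rng(0).normal(size=1000), fs)
        with pytest.raises(ConfigError):
            filter_noise(white, 4, 5_000.0)

    def test_output_sd_below_input_and_monotone_in_bw(self):
        # the filter only removes power; narrower bands remove more
        fs = 115_100.0
        white = pk.SignalTrace(
            np.random.default_rng(1).normal(0, 1.3e-6, 500_000), fs)
        sds = []
        for bw in (1000.0, 500.0, 100.0):
            out = filter_noise(white, 4, bw).samples[100_000:]
            sds.append(out.std())
        assert all(sd < 1.3e-6 for sd in sds)
        assert sds[0] > sds[1] > sds[2]

    def test_spectral_rolloff_consistent_with_n_poles(self):
        # periodogram at 10x BW at least (6n - 3) dB below the passband
        fs, bw, n = 115_100.0, 500.0, 4
        white = pk.SignalTrace(
            np.random.default_rng(2).normal(0, 1.0, 2_000_000), fs)
        out = filter_noise(white, n, bw).samples
        f, psd = sps.welch(out, fs=fs, nperseg=1 << 14)
        plateau = np.median(psd[(f > 0.02 * bw) & (f < 0.2 * bw)])
        stop = np.median(psd[(f > 9 * bw) & (f < 11 * bw)])
        drop_db = 10 * np.log10(plateau / stop)
        assert drop_db >= 6 * n - 3


class TestSynthesize:
    def test_table_defaults_sample_count(self, default_config):
        # 30 s at 115.1 kSa/s
        assert default_config.n_samples == 3_453_000

    def test_component_decomposition(self, short_stream):
        s = short_stream
        total = (s.components["e"].samples + s.components["b"].samples
                 + s.components["n"].samples)
        scale = np.abs(s.trace.samples).max()
        assert np.max(np.abs(total - s.trace.samples)) <= 1e-12 * scale

    def test_truth_within_duration(self, short_stream):
        for ev in short_stream.truth:
            assert 0.0 <= ev.t0_s <= short_stream.config.duration_s

    def test_zero_noise_stream_equals_event_superposition(self):
        cfg = pk.SimulationConfig(duration_s=1.0, sigmaN_V=0.0, seed=5)
        s = pk.synthesize_stream(cfg)
        np.testing.assert_array_equal(s.trace.samples, s.components["e"].samples)

    def test_same_seed_bit_identical(self):
        cfg = pk.SimulationConfig(duration_s=1.0)
        a = pk.synthesize_stream(cfg, seed=9)
        b = pk.synthesize_stream(cfg, seed=9)
        np.testing.assert_array_equal(a.trace.samples, b.trace.samples)
        assert len(a.truth) == len(b.truth)

    def test_drift_component_present_when_requested(self):
        cfg = pk.SimulationConfig(
            duration_s=1.0, seed=1,
            drift=pk.DriftSpec(kind="sine", amplitude_V=5e-6, freq_Hz=2.0))
        s = pk.synthesize_stream(cfg)
        b = s.components["b"].samples
        assert b.max() == pytest.approx(5e-6, rel=1e-3)
        ramp_cfg = pk.SimulationConfig(
            duration_s=1.0, seed=1,
            drift=pk.DriftSpec(kind="ramp", amplitude_V=5e-6))
        r = pk.synthesize_stream(ramp_cfg).components["b"].samples
        assert r[0] == 0.0 and r[-1] == pytest.approx(5e-6)
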