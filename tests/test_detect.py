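"""Derivative computation, thresholding and event extraction."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pulsekit as pk
from pulsekit.detect import _runs, auto_threshold, compute_derivative, detect_events
from pulsekit.errors import ConfigError, DegenerateThresholdError, TraceTooShortError

from conftest import analytic_extrema


def make_pulse_trace(kin, t0s, A=10e-6, fs=115_100.0, duration=0.1):
    evs = [
        pk.TrueEvent(t0_s=t0, d_um=2.0, A_V=A, delta_s=kin.delta_s,
                     sigma_s=kin.sigma_s, t_pos_s=t0 - kin.delta_s / 2,
                     t_neg_s=t0 + kin.delta_s / 2, label="x")
        for t0 in t0s
    ]
    from pulsekit.sim import render_events
    grid = pk.TimeGrid(int(duration * fs), fs)
    return evs, render_events(evs, grid)


def manual_theta(trace, frac=0.3):
    d = compute_derivative(trace)
    return frac * np.abs(d.values).max()


class TestDerivative:
    def test_constant_trace_zero_derivative(self):
        t = pk.SignalTrace(np.full(100, 3.3), 1000.0)
        assert not compute_derivative(t).values.any()

    @given(a=st.integers(min_value=-100, max_value=100),
           b=st.integers(min_value=-1000, max_value=1000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_exact_for_linear_signals_including_boundaries(self, a, b):
        fs = 1.0
        s = a * np.arange(50, dtype=float) + b
        d = compute_derivative(pk.SignalTrace(s, fs)).values
        np.testing.assert_array_equal(d, np.full(50, float(a)))

    def test_central_difference_truncation_bound_on_sine(self):
        # interior points obey the third-derivative truncation bound
        fs, f0, amp = 115_100.0, 50.0, 1.0
        t = np.arange(int(0.5 * fs)) / fs
        s = amp * np.sin(2 * np.pi * f0 * t)
        d = compute_derivative(pk.SignalTrace(s, fs)).values
        exact = amp * 2 * np.pi * f0 * np.cos(2 * np.pi * f0 * t)
        bound = (2 * np.pi * f0) ** 3 / (6 * fs**2) * amp
        interior_err = np.abs(d[1:-1] - exact[1:-1]).max()
        assert interior_err <= bound * 1.01

    def test_too_short_trace_rejected(self):
        with pytest.raises(TraceTooShortError):
            compute_derivative(pk.SignalTrace(np.array([1.0, 2.0]), 1.0))


class TestAutoThreshold:
    def test_mad_scale_consistent_with_gaussian_sd(self):
        rng = np.random.default_rng(0)
        sigma = 3.7
        d = pk.DerivativeTrace(rng.normal(0, sigma, 100_000), 1.0)
        theta = auto_threshold(d, k=5.0)
        assert theta / 5.0 == pytest.approx(sigma, rel=0.05)

    def test_robust_to_sparse_large_events(self):
        # 0.5% of samples carry event-scale slopes; the MAD scale barely
        # moves while a mean-based (sd) scale explodes
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1.0, 100_000)
        contaminated = base.copy()
        idx = rng.choice(base.size, size=base.size // 200, replace=False)
        contaminated[idx] += 500.0
        t0 = auto_threshold(pk.DerivativeTrace(base, 1.0), 1.0)
        t1 = auto_threshold(pk.DerivativeTrace(contaminated, 1.0), 1.0)
        assert abs(t1 - t0) / t0 < 0.01
        assert contaminated.std() / base.std() > 10.0

    def test_homogeneity_under_scaling(self):
        rng = np.random.default_rng(2)
        v = rng.normal(0, 1.0, 10_001)
        t1 = auto_threshold(pk.DerivativeTrace(v, 1.0), 3.0)
        t10 = auto_threshold(pk.DerivativeTrace(10.0 * v, 1.0), 3.0)
        assert t10 == pytest.approx(10.0 * t1, rel=1e-12)

    def test_degenerate_zero_scale_refuses(self):
        d = pk.DerivativeTrace(np.zeros(100), 1.0)
        with pytest.raises(DegenerateThresholdError):
            auto_threshold(d, 5.0)
        flat = pk.SignalTrace(np.full(100, 1.0), 1000.0)
        with pytest.raises(DegenerateThresholdError):
            pk.run_pipeline(flat, pk.DetectorConfig(auto_k=5.0))


class TestDetectEvents:
    def test_zero_trace_empty(self):
        t = pk.SignalTrace(np.zeros(1000), 1000.0)
        d = compute_derivative(t)
        cfg = pk.DetectorConfig(threshold_V_s=1.0, auto_k=None)
        assert detect_events(d, t, cfg) == []

    def test_single_noiseless_pulse_peaks_at_analytic_extrema(
            self, default_kinematics):
        kin = default_kinematics
        evs, trace = make_pulse_trace(kin, [0.05])
        cfg = pk.DetectorConfig.from_kinematics(
            kin.delta_s, kin.sigma_s, trace.fs_Sa_s,
            threshold_V_s=manual_theta(trace), auto_k=None)
        found = pk.run_pipeline(trace, cfg)
        assert len(found) == 1
        t_pos, t_neg = analytic_extrema(10e-6, kin.sigma_s, kin.delta_s, 0.05)
        dt = 1.0 / trace.fs_Sa_s
        assert abs(found[0].t_pos_s - t_pos) <= dt
        assert abs(found[0].t_neg_s - t_neg) <= dt

    def test_two_pulses_20ms_apart(self, default_kinematics):
        kin = default_kinematics
        evs, trace = make_pulse_trace(kin, [0.03, 0.05])
        cfg = pk.DetectorConfig.from_kinematics(
            kin.delta_s, kin.sigma_s, trace.fs_Sa_s,
            threshold_V_s=manual_theta(trace), auto_k=None)
        found = pk.run_pipeline(trace, cfg)
        assert len(found) == 2
        assert found[0].t_center_s < found[1].t_center_s
        assert found[0].t_center_s == pytest.approx(0.03, abs=1e-4)
        assert found[1].t_center_s == pytest.approx(0.05, abs=1e-4)

    def test_landmark_consistency(self, default_kinematics):
        # s' changes sign at the reported crossings; the raw positive peak
        # dominates the window edges
        kin = default_kinematics
        evs, trace = make_pulse_trace(kin, [0.05])
        cfg = pk.DetectorConfig.from_kinematics(
            kin.delta_s, kin.sigma_s, trace.fs_Sa_s,
            threshold_V_s=manual_theta(trace), auto_k=None)
        ev = pk.run_pipeline(trace, cfg)[0]
        v = compute_derivative(trace).values
        lm = ev.landmarks
        for j in (lm.pos_peak_idx, lm.neg_peak_idx):
            window = v[max(j - 1, 0): j + 2]
            assert window.min() <= 0.0 <= window.max()
        s = trace.samples
        assert s[lm.pos_peak_idx] >= s[lm.left_zc_idx]
        assert s[lm.pos_peak_idx] >= s[lm.right_zc_idx]

    def test_offset_invariance_exact(self, default_kinematics):
        # differentiation removes any constant: detection decisions, peak
        # landmarks and features are identical under s -> s + 1 V.  (Only the
        # outer window boundaries may move within their search horizon: the
        # large offset quantises the sub-femtovolt Gaussian-tail dust where
        # those don't-care crossings live.)
        kin = default_kinematics
        evs, trace = make_pulse_trace(kin, [0.03, 0.06])
        theta = manual_theta(trace)
        cfg = pk.DetectorConfig.from_kinematics(
            kin.delta_s, kin.sigma_s, trace.fs_Sa_s,
            threshold_V_s=theta, auto_k=None)
        base = pk.run_pipeline(trace, cfg)
        shifted = pk.SignalTrace(trace.samples + 1.0, trace.fs_Sa_s)
        moved = pk.run_pipeline(shifted, cfg)
        assert len(base) == len(moved) == 2
        gap_n = int(round(cfg.max_gap_s * trace.fs_Sa_s))
        for a, b in zip(base, moved):
            # deriv_extrema is excluded: the bipolar pulse's central slope
            # lobe has two symmetric equal-depth minima, so its argmin
            # tie-breaks on numerical dust
            assert a.landmarks.pos_peak_idx == b.landmarks.pos_peak_idx
            assert a.landmarks.neg_peak_idx == b.landmarks.neg_peak_idx
            dt = 1.0 / trace.fs_Sa_s
            assert a.t_pos_s == pytest.approx(b.t_pos_s, abs=1e-3 * dt)
            assert a.t_neg_s == pytest.approx(b.t_neg_s, abs=1e-3 * dt)
            assert a.features.dt_s == pytest.approx(b.features.dt_s, abs=1e-3 * dt)
            assert abs(a.landmarks.left_zc_idx - b.landmarks.left_zc_idx) <= gap_n
            assert abs(a.landmarks.right_zc_idx - b.landmarks.right_zc_idx) <= gap_n

    def test_drift_moves_peaks_by_at_most_two_samples(self, default_kinematics):
        # 2 Hz, 50 uV drift slope is far below the event slopes
        kin = default_kinematics
        fs = 115_100.0
        evs, clean = make_pulse_trace(kin, [0.05, 0.11, 0.17], duration=0.25)
        t = clean.times()
        drift = 50e-6 * np.sin(2 * np.pi * 2.0 * t)
        noisy = pk.SignalTrace(clean.samples + drift, fs)
        cfg = pk.DetectorConfig.from_kinematics(
            kin.delta_s, kin.sigma_s, fs,
            threshold_V_s=manual_theta(clean), auto_k=None)
        a = pk.run_pipeline(clean, cfg)
        b = pk.run_pipeline(noisy, cfg)
        assert len(a) == len(b) == 3
        for ea, eb in zip(a, b):
            assert abs(ea.landmarks.pos_peak_idx - eb.landmarks.pos_peak_idx) <= 2
            assert abs(ea.landmarks.neg_peak_idx - eb.landmarks.neg_peak_idx) <= 2


# ---------------------------------------------------------------------------
# Brute-force oracle: an explicit-loop reimplementation of the documented
# detection semantics, independent of the vectorised single-pass code path.
# ---------------------------------------------------------------------------

def brute_force_detect(trace, theta, min_lobe, max_gap_s, refractory_s):
    v = compute_derivative(trace).values
    s = trace.samples
    fs = trace.fs_Sa_s
    n = v.size
    # maximal supra-threshold runs with sign
    runs = []
    i = 0
    while i < n:
        if abs(v[i]) > theta:
            j = i
            while j < n and abs(v[j]) > theta:
                j += 1
            if j - i >= min_lobe:
                runs.append((i, j, 1 if v[i] > 0 else -1))
            i = j
        else:
            i += 1

    def first_desc(start):
        for j in range(max(start, 1), n):
            if v[j - 1] > 0 and v[j] <= 0:
                return j
        return None

    def first_asc(start):
        for j in range(max(start, 1), n):
            if v[j - 1] <= 0 and v[j] > 0:
                return j
        return None

    def last_asc(limit):
        found = None
        for j in range(1, limit + 1):
            if v[j - 1] <= 0 and v[j] > 0:
                found = j
        return found

    def near(j):
        frac = v[j - 1] / (v[j - 1] - v[j])
        return (j - 1 + frac) / fs, j - 1 + (1 if frac > 0.5 else 0)

    gap_n = max(1, round(max_gap_s * fs))
    cands = []
    for k in range(len(runs) - 1):
        (ps, pe, g0), (ns, ne, g1) = runs[k], runs[k + 1]
        if not (g0 > 0 and g1 < 0 and (ns - pe) / fs <= max_gap_s):
            continue
        if ps == 0 or ne == n:
            continue
        jp, jn = first_desc(pe), first_asc(ne)
        if jp is None or jn is None:
            continue
        t_pos, ip = near(jp)
        t_neg, iq = near(jn)
        jl = last_asc(ps)
        il = max(jl - 1 if jl is not None else ps - gap_n, ps - gap_n)
        jr = first_desc(jn + 1)
        ir = min(jr if jr is not None else ne + gap_n, ne + gap_n)
        il = max(min(il, ip - 1), 0)
        ir = min(max(ir, iq + 1), n - 1)
        if ip >= iq or s[ip] <= s[iq] or il >= ir:
            continue
        cands.append([0.5 * (t_pos + t_neg), s[ip] - s[iq], il, ir, ip, iq])
    cands.sort()
    kept = []
    for c in cands:
        if kept:
            p = kept[-1]
            if c[0] - p[0] < refractory_s or c[4] <= p[5] + 1:
                if c[1] > p[1]:
                    kept[-1] = c
                continue
            if c[2] <= p[3]:  # distinct events with overlapping windows
                mid = (p[5] + c[4]) // 2
                p[3] = min(p[3], max(mid, p[5] + 1))
                c[2] = min(max(c[2], mid + 1), c[4] - 1)
        kept.append(c)
    return [(c[4], c[5], c[2], c[3]) for c in kept]


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_single_pass_matches_brute_force_on_noisy_traces(self, seed):
        fs = 115_100.0
        n = 10_000
        cfg = pk.SimulationConfig(duration_s=n / fs, rho_per_uL=4e3, seed=seed)
        stream = pk.synthesize_stream(cfg)
        trace = stream.trace
        d = compute_derivative(trace)
        kin = pk.derive_kinematics(cfg)
        theta = 2.0 * auto_threshold(d, 1.0)
        dcfg = pk.DetectorConfig.from_kinematics(
            kin.delta_s, kin.sigma_s, fs, threshold_V_s=theta, auto_k=None)
        fast = detect_events(d, trace, dcfg)
        slow = brute_force_detect(trace, theta, dcfg.min_lobe_samples,
                                  dcfg.max_gap_s, dcfg.refractory_s)
        assert len(fast) == len(slow)
        for ev, (ip, iq, il, ir) in zip(fast, slow):
            assert ev.landmarks.pos_peak_idx == ip
            assert ev.landmarks.neg_peak_idx == iq
            assert ev.landmarks.left_zc_idx == il
            assert ev.landmarks.right_zc_idx == ir


class TestRuns:
    def test_run_extraction(self):
        mask = np.array([1, 1, 0, 0, 1, 0, 1, 1, 1], dtype=bool)
        starts, ends = _runs(mask)
        np.testing.assert_array_equal(starts, [0, 4, 6])
        np.testing.assert_array_equal(ends, [2, 5, 9])

    def test_grid_mismatch_rejected(self):
        t = pk.SignalTrace(np.zeros(100), 1000.0)
        d = pk.DerivativeTrace(np.zeros(50), 1000.0)
        with pytest.raises(ConfigError):
            detect_events(d, t, pk.DetectorConfig(threshold_V_s=1.0, auto_k=None))
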