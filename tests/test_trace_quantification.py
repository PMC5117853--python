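"""ΔF/F₀, T₅₀, detection, transient counting and scalar measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gcamp_plasticity.imaging_io import (
    FluorescenceTrace,
    ROI,
    extract_trace,
)
from gcamp_plasticity.synthetic_cohort import (
    DEFAULT_KINETICS,
    HIGH_K_DECLINE,
    Optics,
    make_k_series,
    place_cells,
    render_stack,
    spikes_to_fluorescence,
)
from gcamp_plasticity.trace_quantification import (
    DegenerateBaselineError,
    QuantConfig,
    ResponseMeasure,
    ZeroBaselineResponseError,
    adjacent_normalize,
    classify_gcamp_positive,
    compute_dff,
    compute_t50,
    conduction_velocity,
    count_transients,
    detect_response,
    percent_change,
)

DT = 0.05


def trace_from(values, dt=DT, background=0.0):
    return FluorescenceTrace(np.asarray(values, dtype=float), dt, background)


class TestComputeDff:
    def test_constant_trace_gives_zero(self):
        tr = trace_from(np.full(100, 42.0))
        m = compute_dff(tr, (0, 2), (2, 5))
        assert m.peak_dff_pct == pytest.approx(0.0)
        assert m.baseline_sd_dff == pytest.approx(0.0)

    def test_textbook_values(self):
        vals = np.full(100, 100.0)
        vals[60] = 150.0
        m = compute_dff(trace_from(vals), (0, 2), (2, 5))
        assert m.peak_dff_pct == pytest.approx(50.0)
        assert m.peak_time_s == pytest.approx((60 + 0.5) * DT)

    def test_background_subtracted_before_ratio(self):
        vals = np.full(100, 120.0)
        vals[60] = 170.0
        m = compute_dff(trace_from(vals, background=20.0), (0, 2), (2, 5))
        assert m.peak_dff_pct == pytest.approx(50.0)

    def test_degenerate_baseline_raises(self):
        tr = trace_from(np.full(100, 5.0), background=10.0)
        with pytest.raises(DegenerateBaselineError):
            compute_dff(tr, (0, 2), (2, 5))

    def test_windows_must_be_ordered(self):
        tr = trace_from(np.full(100, 5.0))
        with pytest.raises(ValueError):
            compute_dff(tr, (2, 5), (0, 2))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 1000))
    def test_scale_invariance(self, scale, seed):
        """ΔF/F₀ is invariant to rescaling trace and background."""
        gen = np.random.default_rng(seed)
        vals = gen.uniform(50, 150, 100)
        bg = 10.0
        a = compute_dff(trace_from(vals, background=bg), (0, 2), (2, 5))
        b = compute_dff(trace_from(vals * scale, background=bg * scale),
                        (0, 2), (2, 5))
        assert b.peak_dff_pct == pytest.approx(a.peak_dff_pct, rel=1e-9)
        assert b.baseline_sd_dff == pytest.approx(a.baseline_sd_dff,
                                                  rel=1e-6, abs=1e-12)

    def test_end_to_end_matches_manual_pixel_recompute(self):
        """compute_dff on an extracted ROI trace equals the formula
        applied to a brute-force per-pixel mean."""
        tr_in = spikes_to_fluorescence([2.5], DEFAULT_KINETICS, 6.0, DT)
        optics = Optics()
        pos = place_cells(1, optics)
        stack = render_stack(pos, [tr_in], optics, seed=1)
        roi = ROI("c", pos[0], optics.soma_radius_px)
        tr = extract_trace(stack, roi, background=optics.background_au)
        m = compute_dff(tr, (0, 2), (2, 6))
        # manual recompute from raw pixels
        cx, cy = pos[0]
        yy, xx = np.mgrid[:64, :64]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= optics.soma_radius_px ** 2
        raw = stack.frames[:, mask].mean(axis=1) - optics.background_au
        t = stack.frame_times()
        f0 = raw[(t >= 0) & (t < 2)].mean()
        expected = 100 * (raw[(t >= 2) & (t < 6)].max() - f0) / f0
        assert m.peak_dff_pct == pytest.approx(expected, rel=1e-9)


class TestT50:
    @pytest.mark.parametrize("tau", [0.2, 0.5, 1.0, 2.0])
    def test_exponential_decay_half_life(self, tau):
        t = (np.arange(600) + 0.5) * DT
        vals = 100.0 + 80.0 * np.exp(-np.maximum(t - 2.0, 0) / tau)
        tr = trace_from(vals)
        t50 = compute_t50(tr, peak_time_s=2.0, baseline_f=100.0)
        assert t50 == pytest.approx(tau * np.log(2), abs=DT)

    def test_monotonically_rising_trace_undefined(self):
        tr = trace_from(np.linspace(100, 200, 100))
        assert compute_t50(tr, peak_time_s=0.0, baseline_f=100.0) is None

    def test_simulated_spike_matches_fine_grid(self):
        kin = DEFAULT_KINETICS
        tr = spikes_to_fluorescence([1.0], kin, 6.0, DT)
        f0 = kin.fluorescence(kin.ca_rest_nM)
        peak_t = tr.times()[np.argmax(tr.values)]
        t50 = compute_t50(tr, peak_t, f0)
        # fine-grid oracle on a 1e-4 s grid
        tt = np.arange(float(peak_t), 6.0, 1e-4)
        c = kin.ca_rest_nM + kin.ca_per_spike_nM * np.exp(
            -(tt - 1.0) / kin.tau_decay_s)
        f = kin.fluorescence(c)
        half = f0 + 0.5 * (f[0] - f0)
        expected = tt[np.argmax(f <= half)] - peak_t
        assert t50 == pytest.approx(expected, abs=DT)


class TestAdjacentNormalize:
    def _measure(self, peak, sd=1.0):
        return ResponseMeasure(peak_dff_pct=peak, peak_time_s=3.0,
                               baseline_sd_dff=sd)

    def test_zero_control_is_identity(self):
        m = adjacent_normalize(self._measure(40.0), self._measure(0.0))
        assert m.peak_dff_pct == pytest.approx(40.0)

    def test_subtraction_dialect(self):
        m = adjacent_normalize(self._measure(40.0), self._measure(10.0))
        assert m.peak_dff_pct == pytest.approx(30.0)
        assert m.contaminated   # control 10% crosses the 5% floor

    def test_ratio_dialect(self):
        cfg = QuantConfig(normalization="ratio")
        m = adjacent_normalize(self._measure(40.0), self._measure(10.0),
                               cfg)
        assert m.peak_dff_pct == pytest.approx(
            100 * (1.4 / 1.1 - 1))

    def test_missing_control_passes_through(self):
        m = adjacent_normalize(self._measure(40.0), None)
        assert m.peak_dff_pct == pytest.approx(40.0)

    def test_correction_improves_contaminated_measurement(self):
        """On a blurred two-cell stack the corrected peak is closer to
        the clean ground truth than the uncorrected one."""
        kin = DEFAULT_KINETICS
        active = spikes_to_fluorescence(
            list(np.linspace(2, 3, 6)), kin, 6.0, DT)
        silent = spikes_to_fluorescence([], kin, 6.0, DT)
        optics = Optics(blur_fraction=0.4, blur_sigma_px=4.0)
        # control ROI drawn over a nearby non-responding cell, so its
        # baseline fluorescence is comparable to the analyzed cell's
        pos = place_cells(3, optics)
        stack = render_stack(pos, [active, silent, silent], optics, seed=2)
        r = optics.soma_radius_px
        silent_roi = ROI("s", pos[1], r)
        ctrl_roi = ROI("a", pos[2], r, "adjacent_control", "s")
        bg = optics.background_au
        m_cell = compute_dff(extract_trace(stack, silent_roi, bg),
                             (0, 2), (2, 6))
        m_ctrl = compute_dff(extract_trace(stack, ctrl_roi, bg),
                             (0, 2), (2, 6))
        corrected = adjacent_normalize(m_cell, m_ctrl)
        # ground truth: the silent cell has zero evoked change
        assert abs(corrected.peak_dff_pct) < abs(m_cell.peak_dff_pct)


class TestDetectResponse:
    def test_zero_peak_never_responds(self):
        m = ResponseMeasure(0.0, 1.0, baseline_sd_dff=0.0)
        assert not detect_response(m)

    def test_strong_peak_responds(self):
        m = ResponseMeasure(50.0, 1.0, baseline_sd_dff=5.0)
        assert detect_response(m)

    def test_floor_blocks_small_peaks_in_quiet_traces(self):
        m = ResponseMeasure(3.0, 1.0, baseline_sd_dff=0.1)
        assert not detect_response(m, k_sd=3, min_peak_dff_pct=5.0)

    def test_false_positive_rate_matches_max_statistics_oracle(self):
        """With the absolute floor disabled, the k·SD rule's false-alarm
        rate on pure noise equals an independent Monte-Carlo of the same
        max-over-window statistic."""
        gen = np.random.default_rng(4)
        nb, nr, n_trials = 40, 60, 800
        hits = 0
        for _ in range(n_trials):
            vals = 100.0 + gen.normal(0, 1.0, nb + nr)
            m = compute_dff(trace_from(vals), (0, nb * DT),
                            (nb * DT, (nb + nr) * DT))
            hits += detect_response(m, k_sd=3, min_peak_dff_pct=0.0)
        rate = hits / n_trials
        # independent oracle: raw numpy replay of the same statistic
        gen2 = np.random.default_rng(14)
        b = gen2.normal(0, 1.0, (4000, nb))
        r = gen2.normal(0, 1.0, (4000, nr))
        oracle = np.mean(r.max(axis=1) - b.mean(axis=1)
                         > 3 * b.std(axis=1))
        se = np.sqrt(oracle * (1 - oracle) / n_trials)
        assert abs(rate - oracle) < 3 * se + 0.01


class TestCountTransients:
    @pytest.mark.parametrize("freq,n", [(1.0, 5), (5.0, 10), (10.0, 10)])
    def test_resolves_every_pulse_up_to_10hz(self, freq, n):
        pulses = list(1.0 + np.arange(n) / freq)
        tr = spikes_to_fluorescence(pulses, DEFAULT_KINETICS,
                                    pulses[-1] + 3.0, 0.02)
        assert count_transients(tr, pulses) == n

    def test_fuses_at_20hz(self):
        pulses = list(1.0 + np.arange(10) / 20.0)
        tr = spikes_to_fluorescence(pulses, DEFAULT_KINETICS, 4.0, 0.02)
        assert count_transients(tr, pulses) < 10

    def test_empty_pulse_list(self):
        tr = spikes_to_fluorescence([], DEFAULT_KINETICS, 2.0, 0.02)
        assert count_transients(tr, []) == 0


class TestPercentChange:
    def test_equal_responses_zero(self):
        assert percent_change(100.0, 100.0) == pytest.approx(0.0)

    def test_increase(self):
        assert percent_change(150.0, 100.0) == pytest.approx(0.5)

    def test_zero_baseline_routed_to_silent_logic(self):
        with pytest.raises(ZeroBaselineResponseError):
            percent_change(100.0, 0.0)

    def test_control_arm_mean_change_near_zero(self, vehicle_table):
        """Stability control: population mean percent change over 30 min
        is statistically indistinguishable from zero."""
        from gcamp_plasticity.pipeline import control_changes

        changes = np.asarray(control_changes(vehicle_table))
        assert len(changes) >= 30
        sem = changes.std(ddof=1) / np.sqrt(len(changes))
        assert abs(changes.mean()) < 2 * sem + 0.02


class TestScalarMeasures:
    def test_ihc_positive_above_5sd(self):
        assert classify_gcamp_positive(21.0, 10.0, 2.0)

    def test_ihc_boundary_exclusive(self):
        assert not classify_gcamp_positive(20.0, 10.0, 2.0)

    def test_ihc_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            classify_gcamp_positive(1.0, 0.0, -1.0)

    def test_ihc_matches_brute_force_on_simulated_field(self, rng):
        signals = rng.uniform(0, 40, 200)
        calls = [classify_gcamp_positive(s, 10.0, 2.0) for s in signals]
        assert calls == [bool(s > 20.0) for s in signals]

    def test_conduction_velocity(self):
        assert conduction_velocity(0.010, 0.020) == pytest.approx(0.5)
        assert conduction_velocity(0.0082, 0.001) == pytest.approx(8.2)

    def test_conduction_velocity_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            conduction_velocity(0.01, 0.0)


class TestHighKDecline:
    def test_repeated_application_decline_recovered(self):
        """Peak ΔF/F₀ as % of the first K⁺ application recovers the
        generator's amplitude decline factors."""
        traces, responder = make_k_series(300, seed=6)
        ratios = []
        for row, resp in zip(traces, responder):
            if not resp:
                continue
            peaks = []
            for tr in row:
                m = compute_dff(tr, (0, 10), (10, 40))
                peaks.append(m.peak_dff_pct)
            if peaks[0] > 0:
                ratios.append([p / peaks[0] for p in peaks])
        mean = np.mean(ratios, axis=0)
        for got, want in zip(mean, HIGH_K_DECLINE):
            assert got == pytest.approx(want, abs=0.02)

    def test_k_transients_return_to_baseline_with_measurable_t50(self):
        traces, responder = make_k_series(5, seed=7)
        tr = traces[int(np.nonzero(responder)[0][0])][0]
        m = compute_dff(tr, (0, 10), (10, 40))
        f0 = (tr.values - tr.background)[tr.times() < 10].mean()
        t50 = compute_t50(tr, m.peak_time_s, float(f0))
        assert t50 is not None and t50 > 0
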