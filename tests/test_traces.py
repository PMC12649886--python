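"""Per-ROI analysis: peak finding, plateau baselining, wave detection,
durations, sustained screening, and the inclusion rule."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

from osteoflow import SynthConfig, TraceParams, analyze_roi
from osteoflow.core import InputError
from osteoflow.synth import generate_trace, make_trace_from_waves
from osteoflow.traces import (ParameterError, detect_waves, estimate_baseline,
                              find_global_peak, flag_sustained,
                              highest_peak_duration, plateau_candidate_starts)
from conftest import flat_trace

DT = 1.73


def pulse_trace(baseline=100.0, level=300.0, start=60, width=5, n=174):
    f = np.full(n, baseline)
    f[start:start + width] = level
    return flat_trace(f)


class TestGlobalPeak:
    def test_simple_max(self):
        assert find_global_peak(flat_trace([1.0, 5.0, 3.0])) == 1

    def test_tie_breaks_earliest(self):
        assert find_global_peak(flat_trace(np.full(20, 7.0))) == 0

    def test_forced_wave_peak_location(self):
        cfg = SynthConfig(noise_sd_frac=0.0, drift_slope=0.0, artifact_rate=0.0)
        trace, _ = make_trace_from_waves(cfg, [150.0], [3.0], [10.0])
        peak_t = find_global_peak(trace) * cfg.dt_s
        assert abs(peak_t - 150.0) <= 10.0 / 2  # within half a wave duration


class TestBaseline:
    def test_flat_trace_recovers_exact_baseline(self):
        est = estimate_baseline(pulse_trace(), find_global_peak(pulse_trace()))
        assert est.f0 == 100.0
        assert not est.degraded
        assert est.window_variance == 0.0

    def test_tie_breaks_toward_peak(self):
        # two zero-variance plateaus at 50 (early) and 80 (late, pre-peak)
        f = np.concatenate([np.full(20, 50.0), np.full(20, 80.0), np.full(20, 80.0)])
        f[50] = 400.0
        trace = flat_trace(f)
        est = estimate_baseline(trace, 50, plateau_len=10)
        assert est.f0 == 80.0
        assert est.window_end_idx <= 50

    def test_early_peak_falls_back_degraded(self):
        f = np.full(60, 100.0)
        f[2] = 500.0
        est = estimate_baseline(flat_trace(f), 2, plateau_len=10)
        assert est.degraded
        assert est.window_start_idx == 0

    def test_rejects_tiny_plateau(self):
        with pytest.raises(ParameterError):
            estimate_baseline(pulse_trace(), 60, plateau_len=2)

    def test_window_never_overlaps_rise(self):
        cfg = SynthConfig()
        for i in range(25):
            rng = np.random.default_rng([21, i])
            trace, _ = generate_trace(cfg, "control", "no_pmd", rng)
            peak = find_global_peak(trace)
            est = estimate_baseline(trace, peak)
            assert est.window_end_idx <= peak
            starts = plateau_candidate_starts(trace.fluorescence, peak, 10)
            if len(starts):
                assert est.window_start_idx in starts


class TestWaveDetection:
    def test_flat_trace_has_no_waves(self):
        trace = flat_trace(np.full(50, 100.0))
        est = estimate_baseline(trace, find_global_peak(trace))
        assert detect_waves(trace, est) == []

    def test_rectangular_pulse_single_wave(self):
        trace = pulse_trace(level=300.0)
        est = estimate_baseline(trace, find_global_peak(trace))
        waves = detect_waves(trace, est)
        assert len(waves) == 1
        assert waves[0].fold_change == pytest.approx(3.0)

    def test_subthreshold_pulse_not_counted(self):
        f = np.full(120, 100.0)
        f[30:35] = 250.0   # 2.5-fold: counts
        f[80:85] = 180.0   # 1.8-fold: below the 2-fold rule
        trace = flat_trace(f)
        est = estimate_baseline(trace, find_global_peak(trace))
        assert len(detect_waves(trace, est)) == 1

    def test_min_fold_must_exceed_one(self):
        trace = pulse_trace()
        est = estimate_baseline(trace, find_global_peak(trace))
        with pytest.raises(ParameterError):
            detect_waves(trace, est, min_fold=1.0)

    def test_merge_gap_joins_single_frame_dips(self):
        f = np.full(120, 100.0)
        f[30:35] = 300.0
        f[35] = 150.0      # one sub-threshold frame
        f[36:40] = 300.0
        trace = flat_trace(f)
        est = estimate_baseline(trace, find_global_peak(trace))
        assert len(detect_waves(trace, est)) == 1
        # a 3-frame dip exceeds the default 2-frame merge gap
        f2 = f.copy()
        f2[35:38] = 100.0
        f2[38:42] = 300.0
        trace2 = flat_trace(f2)
        est2 = estimate_baseline(trace2, find_global_peak(trace2))
        assert len(detect_waves(trace2, est2)) == 2

    def test_clean_synthetic_counts_match_truth(self, clean_config):
        cfg = clean_config.replace(amp_min_fold=2.5, sustained_frac=0.0,
                                   high_responder_frac_control=0.0)
        mismatch = 0
        for i in range(200):
            rng = np.random.default_rng([31, i])
            trace, truth = generate_trace(cfg, "control", "no_pmd", rng)
            m = analyze_roi(trace)
            mismatch += m.wave_count != truth.n_waves
        assert mismatch == 0


class TestDurations:
    def test_rectangular_duration_counts_intervals(self):
        # 6 frames above baseline = 5 inter-frame intervals = 8.65 s
        trace = pulse_trace(level=300.0, start=60, width=6)
        est = estimate_baseline(trace, find_global_peak(trace))
        waves = detect_waves(trace, est)
        assert highest_peak_duration(trace, est, waves) == pytest.approx(5 * DT)

    def test_whole_window_pulse_capped_at_window(self):
        n = 100
        f = np.full(n, 300.0)
        f[:10] = 100.0   # plateau so the baseline exists
        trace = flat_trace(f)
        est = estimate_baseline(trace, find_global_peak(trace))
        waves = detect_waves(trace, est)
        d = highest_peak_duration(trace, est, waves)
        assert 0 < d <= trace.duration_s

    def test_empty_wave_list_rejected(self):
        trace = flat_trace(np.full(50, 100.0))
        est = estimate_baseline(trace, find_global_peak(trace))
        with pytest.raises(InputError):
            highest_peak_duration(trace, est, [])


class TestSustained:
    def test_returning_trace_not_flagged(self):
        trace = pulse_trace()
        est = estimate_baseline(trace, find_global_peak(trace))
        assert not flag_sustained(trace, est)

    def test_tail_held_high_is_flagged(self):
        f = np.full(100, 100.0)
        f[80:] = 400.0
        trace = flat_trace(f)
        est = estimate_baseline(trace, find_global_peak(trace))
        assert flag_sustained(trace, est)

    def test_matches_generator_truth_noise_free(self, clean_config):
        cfg = clean_config.replace(sustained_frac=0.5)
        for i in range(40):
            rng = np.random.default_rng([41, i])
            trace, truth = generate_trace(cfg, "control", "no_pmd", rng)
            m = analyze_roi(trace)
            assert m.sustained == truth.is_sustained


class TestAnalyzeRoi:
    def test_flat_trace_excluded(self):
        m = analyze_roi(flat_trace(np.full(60, 100.0)))
        assert not m.included
        assert m.wave_count == 0
        assert np.isnan(m.highest_peak_duration_s)

    def test_single_pulse_included(self):
        m = analyze_roi(pulse_trace(level=300.0))
        assert m.included
        assert m.max_fold_change == pytest.approx(3.0)
        assert m.wave_count == 1
        assert 0 < m.highest_peak_duration_s <= 174 * DT

    def test_metric_invariants_on_synthetic_rois(self, default_config):
        window = default_config.window_s
        for i in range(50):
            rng = np.random.default_rng([51, i])
            trace, _ = generate_trace(default_config, "disuse", "pmd_pos", rng)
            m = analyze_roi(trace)
            if m.included:
                assert m.max_fold_change >= 2.0
                assert m.wave_count >= 1
                assert 0 < m.highest_peak_duration_s <= window
            else:
                assert m.max_fold_change < 2.0 and m.wave_count == 0


def test_preflow_frames_are_discarded():
    """Frames recorded before flow onset are dropped before analysis."""
    f = np.full(120, 100.0)
    f[:6] = 500.0          # pre-flow scaffold movement, not a calcium wave
    f[60:65] = 300.0
    trace = flat_trace(f)
    m = analyze_roi(trace, TraceParams(preflow_s=6 * DT))
    assert m.included
    assert m.max_fold_change == pytest.approx(3.0)
    assert m.wave_count == 1


@given(st.floats(min_value=0.01, max_value=100.0), st.integers(0, 10_000))
def test_scale_invariance(scale, stream):
    """Rescaling a trace by c > 0 leaves all fold-based metrics unchanged."""
    rng = np.random.default_rng([61, stream])
    trace, _ = generate_trace(SynthConfig(), "control", "no_pmd", rng)
    m1 = analyze_roi(trace)
    scaled = flat_trace(trace.fluorescence * scale)
    m2 = analyze_roi(scaled)
    assert m1.included == m2.included
    assert m1.wave_count == m2.wave_count
    assert m1.sustained == m2.sustained
    assert m2.f0 == pytest.approx(m1.f0 * scale, rel=1e-9)
    assert m2.max_fold_change == pytest.approx(m1.max_fold_change, rel=1e-9)
    if m1.included:
        assert m2.highest_peak_duration_s == pytest.approx(
            m1.highest_peak_duration_s, rel=1e-9)


@given(st.integers(0, 10_000))
def test_threshold_monotonicity(stream):
    """Raising min_fold never increases the wave count; above max F/Fo it is 0.

    Checked on noise-free traces: with smooth unimodal pulses the
    supra-threshold runs are nested, which is what the property formalizes.
    """
    rng = np.random.default_rng([71, stream])
    cfg = SynthConfig(noise_sd_frac=0.0, artifact_rate=0.0, drift_slope=0.0)
    trace, _ = generate_trace(cfg, "disuse", "no_pmd", rng)
    counts = [analyze_roi(trace, TraceParams(min_fold=mf)).wave_count
              for mf in (1.5, 2.0, 3.0, 5.0, 12.0)]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    peak = find_global_peak(trace)
    est = estimate_baseline(trace, peak)
    max_ratio = trace.fluorescence[peak] / est.f0
    assert analyze_roi(trace, TraceParams(min_fold=max_ratio * 1.01)).wave_count == 0
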