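"""Per-ROI calcium trace analysis.

The study's per-cell quantities are computed here: an adaptive baseline
(Fo) defined as the stable plateau immediately preceding the highest
calcium wave, detection of calcium waves as at-least-2-fold excursions over
baseline (F/Fo >= 2), the fold change and above-baseline duration of the
highest peak, the wave count over the observation window, a sustained-signal
screen for traces that never return to baseline, and the inclusion rule that
drops ROIs without any 2-fold response.

Because drift and local motion make a fixed pre-flow baseline unreliable,
the plateau is found automatically as the minimum-variance window among
pre-peak windows that contain no rising-phase frames.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import InputError, Trace

DEFAULT_MIN_FOLD = 2.0          # wave qualification: F/Fo >= 2 (closed threshold)
DEFAULT_PLATEAU_LEN = 10        # frames (~17.3 s at dt = 1.73 s)
DEFAULT_TAIL_FRAC = 0.1
DEFAULT_TAIL_FOLD = 2.0
DEFAULT_EXTENT_FOLD = 1.0       # duration extent: F > Fo (open threshold)
DEFAULT_EXTENT_SIGMA_K = 3.0    # extent must clear the plateau band by k baseline SDs
RISE_MEDIAN_FACTOR = 1.5        # frames above 1.5x trailing median are "rising"


class ParameterError(ValueError):
    """Raised for invalid analysis parameters."""


@dataclass
class TraceParams:
    """Tunable thresholds of the per-ROI analysis."""

    min_fold: float = DEFAULT_MIN_FOLD
    plateau_len: int = DEFAULT_PLATEAU_LEN
    merge_gap_s: float | None = None    # default 2*dt, resolved per trace
    extent_fold: float = DEFAULT_EXTENT_FOLD
    extent_sigma_k: float = DEFAULT_EXTENT_SIGMA_K
    tail_frac: float = DEFAULT_TAIL_FRAC
    tail_fold: float = DEFAULT_TAIL_FOLD
    preflow_s: float = 0.0              # leading frames to discard before analysis


@dataclass
class BaselineEstimate:
    f0: float
    window_start_idx: int
    window_end_idx: int     # inclusive
    window_variance: float
    degraded: bool = False


@dataclass
class WaveEvent:
    onset_idx: int
    peak_idx: int
    offset_idx: int
    peak_f: float
    fold_change: float
    duration_s: float


@dataclass
class RoiMetrics:
    roi_id: str
    scaffold_id: str
    condition: str
    pmd_status: str
    included: bool
    max_fold_change: float
    highest_peak_duration_s: float
    wave_count: int
    sustained: bool
    f0: float
    baseline_degraded: bool = False


def find_global_peak(trace: Trace) -> int:
    """Index of the maximum fluorescence frame (earliest on ties)."""
    return int(np.argmax(trace.fluorescence))


def plateau_candidate_starts(f: np.ndarray, peak_idx: int, plateau_len: int) -> np.ndarray:
    """Start indices of admissible plateau windows before the peak.

    A window of ``plateau_len`` frames is admissible when it ends at or
    before the peak and contains no frame exceeding ``1.5x`` the trailing
    median — i.e. no rising-phase or transient frame, so "stable plateau"
    excludes the rise of the wave itself.
    """
    if peak_idx + 1 < plateau_len:
        return np.empty(0, dtype=int)
    pre = f[:peak_idx + 1]
    padded = np.concatenate([np.full(plateau_len - 1, pre[0]), pre])
    trailing_median = np.median(sliding_window_view(padded, plateau_len), axis=1)
    active = pre > RISE_MEDIAN_FACTOR * trailing_median
    # windows [s, s+L-1] with no active frame
    bad = np.convolve(active.astype(int), np.ones(plateau_len, dtype=int), "valid")
    starts = np.nonzero(bad == 0)[0]
    return starts


def estimate_baseline(trace: Trace, peak_idx: int,
                      plateau_len: int = DEFAULT_PLATEAU_LEN) -> BaselineEstimate:
    """Minimum-variance plateau window ending at or before the highest peak.

    Among all admissible windows the one with the smallest variance is
    chosen; ties go to the window closest to the peak ("immediately
    preceding"). If the peak is too early to fit any window, the first
    ``plateau_len`` frames are used and the estimate is flagged degraded.
    """
    if plateau_len < 3:
        raise ParameterError("plateau_len must be >= 3")
    f = trace.fluorescence
    if len(f) < plateau_len:
        raise InputError(f"trace {trace.roi_id}: shorter than one plateau window")
    starts = plateau_candidate_starts(f, peak_idx, plateau_len)
    if len(starts) == 0:
        window = f[:plateau_len]
        return BaselineEstimate(float(np.mean(window)), 0, plateau_len - 1,
                                float(np.var(window)), degraded=True)
    variances = np.var(sliding_window_view(f, plateau_len)[starts], axis=1)
    # last occurrence of the minimum = admissible window closest to the peak
    best = len(variances) - 1 - int(np.argmin(variances[::-1]))
    s = int(starts[best])
    window = f[s:s + plateau_len]
    return BaselineEstimate(float(np.mean(window)), s, s + plateau_len - 1,
                            float(np.var(window)))


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, end) inclusive index pairs."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def detect_waves(trace: Trace, baseline: BaselineEstimate,
                 min_fold: float = DEFAULT_MIN_FOLD,
                 merge_gap_s: float | None = None,
                 extent_fold: float = DEFAULT_EXTENT_FOLD,
                 extent_sigma_k: float = DEFAULT_EXTENT_SIGMA_K) -> list[WaveEvent]:
    """Detect calcium waves as >= ``min_fold`` excursions over baseline.

    Qualification uses the closed threshold F/Fo >= min_fold; supra-threshold
    runs separated by less than ``merge_gap_s`` (default two frames) are
    merged. Each wave's onset/offset are then extended outward to the limits
    of the contiguous above-baseline excursion, which defines its duration.
    "Above baseline" means above ``extent_fold * Fo`` (open threshold) by
    more than ``extent_sigma_k`` standard deviations of the baseline window
    itself, so the extent stops where the signal is indistinguishable from
    the plateau band; ``extent_sigma_k = 0`` recovers the strict F > Fo
    rule, and both reduce to F > Fo on noise-free plateaus.
    """
    if min_fold <= 1.0:
        raise ParameterError("min_fold must be > 1")
    if baseline.f0 <= 0:
        raise ParameterError("baseline f0 must be > 0")
    f = trace.fluorescence
    dt = trace.dt_s
    if merge_gap_s is None:
        merge_gap_s = 2.0 * dt
    ratio = f / baseline.f0
    runs = _runs(ratio >= min_fold)
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and (start - merged[-1][1] - 1) * dt < merge_gap_s:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    band = extent_sigma_k * np.sqrt(max(baseline.window_variance, 0.0))
    above = f > extent_fold * baseline.f0 + band
    waves = []
    for start, end in merged:
        peak = start + int(np.argmax(f[start:end + 1]))
        onset = start
        while onset > 0 and above[onset - 1]:
            onset -= 1
        offset = end
        while offset < len(f) - 1 and above[offset + 1]:
            offset += 1
        duration = (offset - onset) * dt
        if duration <= 0:       # single-frame excursion: credit one frame
            duration = dt
        waves.append(WaveEvent(onset, peak, offset, float(f[peak]),
                               float(f[peak] / baseline.f0), float(duration)))
    return waves


def highest_peak_duration(trace: Trace, baseline: BaselineEstimate,
                          waves: list[WaveEvent]) -> float:
    """Above-baseline duration of the wave with the largest fold change.

    Ties go to the earliest wave (the list is onset-ordered).
    """
    if not waves:
        raise InputError("highest_peak_duration undefined for an empty wave list")
    best = max(waves, key=lambda w: (w.fold_change, -w.onset_idx))
    return best.duration_s


def flag_sustained(trace: Trace, baseline: BaselineEstimate,
                   tail_frac: float = DEFAULT_TAIL_FRAC,
                   tail_fold: float = DEFAULT_TAIL_FOLD) -> bool:
    """True when the final ``tail_frac`` of the window stays >= tail_fold x Fo.

    Flags traces whose signal never returns to baseline, a proxy for
    persistent loss of membrane integrity.
    """
    if not 0.0 < tail_frac < 1.0:
        raise ParameterError("tail_frac must be in (0, 1)")
    n_tail = max(1, math.ceil(tail_frac * trace.n_frames))
    tail = trace.fluorescence[-n_tail:]
    return bool(np.all(tail / baseline.f0 >= tail_fold))


def _strip_preflow(trace: Trace, preflow_s: float) -> Trace:
    keep = trace.times >= trace.times[0] + preflow_s
    return Trace(trace.scaffold_id, trace.condition, trace.roi_id, trace.pmd_status,
                 trace.times[keep], trace.fluorescence[keep])


def analyze_roi(trace: Trace, params: TraceParams | None = None) -> RoiMetrics:
    """Full per-ROI analysis: baseline, waves, peak metrics, screens.

    An ROI is included only when some frame reaches ``min_fold`` over
    baseline; excluded ROIs report their sub-threshold max ratio, a zero
    wave count and an undefined (NaN) peak duration.
    """
    params = params or TraceParams()
    if params.preflow_s > 0:
        trace = _strip_preflow(trace, params.preflow_s)
    peak_idx = find_global_peak(trace)
    baseline = estimate_baseline(trace, peak_idx, params.plateau_len)
    waves = detect_waves(trace, baseline, params.min_fold, params.merge_gap_s,
                         params.extent_fold, params.extent_sigma_k)
    max_ratio = float(np.max(trace.fluorescence) / baseline.f0)
    sustained = flag_sustained(trace, baseline, params.tail_frac, params.tail_fold)
    if waves:
        max_fold = max(w.fold_change for w in waves)
        duration = highest_peak_duration(trace, baseline, waves)
        included = True
    else:
        max_fold = max_ratio
        duration = float("nan")
        included = False
    return RoiMetrics(trace.roi_id, trace.scaffold_id, trace.condition,
                      trace.pmd_status, included, max_fold, duration,
                      len(waves), sustained, baseline.f0,
                      baseline_degraded=baseline.degraded)


METRICS_COLUMNS = ["roi_id", "scaffold_id", "condition", "pmd_status", "included",
                   "f0", "max_fold_change", "highest_peak_duration_s",
                   "wave_count", "sustained", "baseline_degraded"]


def metrics_to_frame(metrics: list[RoiMetrics]):
    import pandas as pd

    return pd.DataFrame([{
        "roi_id": m.roi_id,
        "scaffold_id": m.scaffold_id,
        "condition": m.condition,
        "pmd_status": m.pmd_status,
        "included": m.included,
        "f0": m.f0,
        "max_fold_change": m.max_fold_change,
        "highest_peak_duration_s": m.highest_peak_duration_s,
        "wave_count": m.wave_count,
        "sustained": m.sustained,
        "baseline_degraded": m.baseline_degraded,
    } for m in metrics], columns=METRICS_COLUMNS)
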