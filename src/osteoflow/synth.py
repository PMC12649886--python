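"""Synthetic data generators with ground truth.

Emulates the signal structure of scaffold calcium-reloading experiments:

* per-ROI fluorescence traces with baseline drift, short motion-artifact
  bumps, multiplicative photon-style noise, and stochastic asynchronous
  calcium waves whose peak fold changes are lognormally distributed;
* a condition-dependent high-amplitude subpopulation (F/Fo > 10) enriched
  under disuse, and amplitude amplification restricted to disuse x PMD+
  ROIs (the interaction structure);
* two-channel microscopy fields (nuclei + dextran) with an exact number of
  wounded cells;
* qPCR Ct tables built so that the comparative-threshold-cycle method
  recovers prescribed fold changes.

Every generator records what it drew in a truth object so downstream
metrics can be validated by recovery.

Randomness is split hierarchically: each ROI draws from
``default_rng([seed, stream, condition, scaffold, roi])`` so adding ROIs or
scaffolds never perturbs earlier draws.
"""
from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .config import ConfigError, SynthConfig
from .core import (CONDITIONS, CONTROL, DISUSE, NO_PMD, PMD_POS, PMD_STATUSES,
                   FieldTruth, Trace, TraceTruth)

# Fraction of a wave's duration spent rising; the remainder is the slower decay.
PULSE_RISE_FRAC = 0.25
# Minimum spacing between rendered waves, in frames, so events stay resolvable.
WAVE_SEP_FRAMES = 3
# A sustained wave must reach its held plateau before this fraction of the
# window, so the persistent elevation covers the final screened stretch.
SUSTAINED_PEAK_MAX_FRAC = 0.85
# Sub-streams keeping independent artifact families decorrelated under one seed.
STREAM_TRACES = 0
STREAM_IMAGES = 1
STREAM_QPCR = 2
STREAM_CROSSTAB = 3


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap."""


def pulse_shape(u, rise_frac: float = PULSE_RISE_FRAC) -> np.ndarray:
    """Unimodal calcium-wave pulse on normalized time ``u`` in (0, 1).

    Half-sine rise to the peak at ``u = rise_frac`` followed by a slower
    half-cosine decay. The pulse has compact support with nonzero edge
    slope, so the above-baseline extent of an event is well defined even on
    noisy traces.
    """
    u = np.asarray(u, dtype=float)
    s = np.zeros_like(u)
    rise = (u > 0) & (u <= rise_frac)
    s[rise] = np.sin(0.5 * np.pi * u[rise] / rise_frac)
    decay = (u > rise_frac) & (u < 1.0)
    s[decay] = np.cos(0.5 * np.pi * (u[decay] - rise_frac) / (1.0 - rise_frac))
    return s


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lower: float, tries: int = 100) -> float:
    for _ in range(tries):
        x = rng.normal(mean, sd)
        if x > lower:
            return float(x)
    return float(lower * 1.05)


def _snap_onset(onset: float, duration: float, dt: float) -> float:
    """Shift a wave onset so its peak lands exactly on a frame time.

    Keeps the rendered maximum equal to the drawn peak fold instead of an
    off-grid sample of the pulse.
    """
    peak_t = onset + PULSE_RISE_FRAC * duration
    return onset + (round(peak_t / dt) * dt - peak_t)


def _render(config: SynthConfig, onsets: np.ndarray, folds: np.ndarray,
            durations: np.ndarray, sustained_idx: int | None,
            artifacts: Sequence[tuple[float, float, float]],
            noise: np.ndarray | None) -> np.ndarray:
    n = config.n_frames
    t = np.arange(n) * config.dt_s
    rel = np.zeros(n)
    for i in range(len(onsets)):
        u = (t - onsets[i]) / durations[i]
        if sustained_idx is not None and i == sustained_idx:
            # hold the wave open at its peak level through the end of the window
            u = np.minimum(u, PULSE_RISE_FRAC)
        rel += (folds[i] - 1.0) * pulse_shape(u)
    for t0, width, amp in artifacts:
        rel += amp * np.exp(-0.5 * ((t - t0) / width) ** 2)
    base = config.baseline_level + config.drift_slope * t
    f = base * (1.0 + rel)
    if noise is not None:
        f = f * (1.0 + noise)
    return np.maximum(f, 1e-3)


def make_trace_from_waves(config: SynthConfig, onsets, folds, durations,
                          condition: str = CONTROL, pmd_status: str = NO_PMD,
                          scaffold_id: str = "S1", roi_id: str = "R1",
                          sustained_idx: int | None = None) -> tuple[Trace, TraceTruth]:
    """Deterministically render a trace from explicit wave parameters.

    No noise, drift beyond the configured slope, or artifacts are added;
    peak times are snapped to the frame grid so rendered peak folds equal
    the requested folds exactly.
    """
    config.validate()
    onsets = np.array([_snap_onset(o, d, config.dt_s)
                       for o, d in zip(np.atleast_1d(onsets), np.atleast_1d(durations))])
    folds = np.asarray(folds, dtype=float)
    durations = np.asarray(durations, dtype=float)
    f = _render(config, onsets, folds, durations, sustained_idx, [], None)
    t = np.arange(config.n_frames) * config.dt_s
    window_end = t[-1]
    truth_durations = durations.copy()
    if sustained_idx is not None and len(onsets):
        truth_durations[sustained_idx] = window_end - onsets[sustained_idx]
    order = np.argsort(onsets, kind="stable")
    trace = Trace(scaffold_id, condition, roi_id, pmd_status, t, f)
    truth = TraceTruth(roi_id, config.baseline_level, onsets[order], folds[order],
                       truth_durations[order],
                       is_sustained=sustained_idx is not None)
    return trace, truth


def _draw_wave(config: SynthConfig, rng: np.random.Generator,
               onsets: list, durations: list) -> tuple[float, float] | None:
    """Draw one wave (onset, duration) respecting the separation rule."""
    dt = config.dt_s
    window_end = (config.n_frames - 1) * dt
    dur = _truncated_normal(rng, config.wave_duration_mean_s,
                            config.wave_duration_sd_s, lower=2.0 * dt)
    lo = min(config.wave_onset_min_s, 0.2 * window_end)
    hi = window_end - dur
    if hi <= lo:
        return None
    gap = WAVE_SEP_FRAMES * dt
    for _ in range(50):
        o = _snap_onset(rng.uniform(lo, hi), dur, dt)
        ok = all(o >= oo + dd + gap or o + dur + gap <= oo
                 for oo, dd in zip(onsets, durations))
        if ok and o >= 0:
            return o, dur
    return None


def generate_trace(config: SynthConfig, condition: str, pmd_status: str,
                   rng: np.random.Generator, scaffold_id: str = "S1",
                   roi_id: str = "R1") -> tuple[Trace, TraceTruth]:
    """Generate one ROI trace plus its ground truth.

    Structure: linear baseline drift + Gaussian motion-artifact bumps
    (Poisson arrivals, sub-wave amplitude) + calcium waves (Poisson count at
    the condition's rate, lognormal peak folds, truncated-normal durations)
    + multiplicative Gaussian noise. With probability
    ``high_responder_frac_<condition>`` the largest wave fold is resampled
    above ``high_responder_amp_fc``; disuse x PMD+ ROIs have all folds
    multiplied by ``pmd_amp_multiplier``; with probability
    ``sustained_frac`` the last wave is held open to the end of the window.
    """
    config.validate()
    if condition not in CONDITIONS:
        raise ConfigError(f"unknown condition {condition!r}")
    if pmd_status not in PMD_STATUSES:
        raise ConfigError(f"unknown pmd_status {pmd_status!r}")
    dt = config.dt_s
    window_end = (config.n_frames - 1) * dt

    k = rng.poisson(config.wave_rate(condition) * config.window_s)
    onsets: list[float] = []
    durations: list[float] = []
    for _ in range(k):
        placed = _draw_wave(config, rng, onsets, durations)
        if placed is not None:
            onsets.append(placed[0])
            durations.append(placed[1])
    folds = np.maximum(rng.lognormal(config.amp_lognorm_mu, config.amp_lognorm_sigma,
                                     size=len(onsets)), config.amp_min_fold)

    is_high_responder = bool(rng.random() < config.high_responder_frac(condition))
    if is_high_responder:
        if not onsets:
            placed = _draw_wave(config, rng, onsets, durations)
            if placed is not None:
                onsets.append(placed[0])
                durations.append(placed[1])
                folds = np.append(folds, config.amp_min_fold)
        if onsets:
            i = int(np.argmax(folds))
            folds[i] = config.high_responder_amp_fc * float(
                np.exp(abs(rng.normal(0.0, 0.25))))
        else:  # pragma: no cover - window too small to place any wave
            is_high_responder = False

    if condition == DISUSE and pmd_status == PMD_POS:
        folds = folds * config.pmd_amp_multiplier

    is_sustained = bool(rng.random() < config.sustained_frac)
    sustained_idx: int | None = None
    if is_sustained:
        if not onsets:
            placed = _draw_wave(config, rng, onsets, durations)
            if placed is not None:
                onsets.append(placed[0])
                durations.append(placed[1])
                folds = np.append(folds, config.amp_min_fold)
        # hold the latest wave whose peak settles before the end-of-window
        # screen region; if every wave rises too late, the ROI simply is
        # not sustained (the elevation would not span the screened tail)
        t_max = SUSTAINED_PEAK_MAX_FRAC * window_end
        candidates = [i for i, (o, d) in enumerate(zip(onsets, durations))
                      if o + PULSE_RISE_FRAC * d <= t_max]
        if candidates:
            sustained_idx = max(candidates, key=lambda i: onsets[i])
            folds[sustained_idx] = max(folds[sustained_idx], 3.0)
            # the held wave is the terminal event: later waves would ride on
            # (and be absorbed into) the persistent plateau
            keep = [i for i in range(len(onsets))
                    if onsets[i] <= onsets[sustained_idx]]
            sustained_idx = keep.index(sustained_idx)
            onsets = [onsets[i] for i in keep]
            durations = [durations[i] for i in keep]
            folds = folds[keep]
        else:
            is_sustained = False

    n_art = rng.poisson(config.artifact_rate * config.window_s)
    artifacts = []
    for _ in range(n_art):
        t0 = rng.uniform(0.0, window_end)
        width = rng.uniform(2.0, 5.0)
        amp = config.artifact_amp_frac * rng.uniform(0.5, 1.0) * rng.choice([-1.0, 1.0])
        artifacts.append((t0, width, amp))

    noise = None
    if config.noise_sd_frac > 0:
        noise = rng.normal(0.0, config.noise_sd_frac, size=config.n_frames)

    onsets_arr = np.asarray(onsets, dtype=float)
    durations_arr = np.asarray(durations, dtype=float)
    f = _render(config, onsets_arr, folds, durations_arr, sustained_idx,
                artifacts, noise)
    truth_durations = durations_arr.copy()
    if sustained_idx is not None:
        truth_durations[sustained_idx] = window_end - onsets_arr[sustained_idx]
    order = np.argsort(onsets_arr, kind="stable")
    t = np.arange(config.n_frames) * dt
    trace = Trace(scaffold_id, condition, roi_id, pmd_status, t, f)
    truth = TraceTruth(roi_id, config.baseline_level, onsets_arr[order],
                       folds[order], truth_durations[order],
                       is_high_responder=is_high_responder,
                       is_sustained=is_sustained)
    return trace, truth


def roi_rng(config: SynthConfig, cond_idx: int, scaffold_idx: int,
            roi_idx: int, stream: int = STREAM_TRACES) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stream, cond_idx,
                                  scaffold_idx, roi_idx])


def scaffold_label(condition: str, scaffold_idx: int) -> str:
    return f"{'C' if condition == CONTROL else 'D'}{scaffold_idx + 1}"


def generate_traces(config: SynthConfig) -> Iterator[tuple[Trace, TraceTruth]]:
    """Yield every ROI of a full two-condition experiment, with truth.

    PMD status is Bernoulli(pmd_frac_<condition>) per ROI; all draws are
    deterministic functions of the config seed and the ROI's position in
    the design.
    """
    config.validate()
    for ci, condition in enumerate(CONDITIONS):
        for s in range(config.n_scaffolds_per_condition):
            sid = scaffold_label(condition, s)
            for r in range(config.n_rois_per_scaffold):
                rng = roi_rng(config, ci, s, r)
                pmd = PMD_POS if rng.random() < config.pmd_frac(condition) else NO_PMD
                rid = f"{sid}_R{r + 1:02d}"
                yield generate_trace(config, condition, pmd, rng, sid, rid)


TRACE_COLUMNS = ["scaffold_id", "condition", "roi_id", "pmd_status",
                 "frame", "time_s", "fluorescence"]
TRUTH_COLUMNS = ["roi_id", "scaffold_id", "condition", "pmd_status",
                 "true_baseline", "n_waves", "wave_onsets_s", "wave_peak_folds",
                 "wave_durations_s", "max_peak_fold", "is_high_responder",
                 "is_sustained"]


def _join(values: np.ndarray) -> str:
    return ";".join(repr(float(v)) for v in values)


def generate_experiment(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the full experiment as (trace table, truth table).

    The trace table has one row per ROI per frame with the column order
    scaffold_id, condition, roi_id, pmd_status, frame, time_s, fluorescence.
    """
    trace_parts = []
    truth_rows = []
    for trace, truth in generate_traces(config):
        n = trace.n_frames
        trace_parts.append(pd.DataFrame({
            "scaffold_id": np.repeat(trace.scaffold_id, n),
            "condition": np.repeat(trace.condition, n),
            "roi_id": np.repeat(trace.roi_id, n),
            "pmd_status": np.repeat(trace.pmd_status, n),
            "frame": np.arange(n),
            "time_s": trace.times,
            "fluorescence": trace.fluorescence,
        }))
        truth_rows.append({
            "roi_id": truth.roi_id,
            "scaffold_id": trace.scaffold_id,
            "condition": trace.condition,
            "pmd_status": trace.pmd_status,
            "true_baseline": truth.true_baseline,
            "n_waves": truth.n_waves,
            "wave_onsets_s": _join(truth.wave_onsets),
            "wave_peak_folds": _join(truth.wave_peak_folds),
            "wave_durations_s": _join(truth.wave_durations),
            "max_peak_fold": truth.max_peak_fold,
            "is_high_responder": truth.is_high_responder,
            "is_sustained": truth.is_sustained,
        })
    trace_df = pd.concat(trace_parts, ignore_index=True)[TRACE_COLUMNS]
    truth_df = pd.DataFrame(truth_rows)[TRUTH_COLUMNS]
    return trace_df, truth_df


def pmd_experiment_config(config: SynthConfig | None = None) -> SynthConfig:
    """Configuration for the PMD-tracer (condition x PMD) experiment.

    Amplitude amplification flows only through the condition x PMD
    mechanism: the free-standing high-responder fractions are zeroed, since
    in the tracer experiment the high-amplitude subpopulation is realized
    by wounded cells under disuse rather than drawn independently.
    """
    config = config or SynthConfig()
    return config.replace(high_responder_frac_control=0.0,
                          high_responder_frac_disuse=0.0,
                          sustained_frac=0.0)


def generate_crosstab_traces(config: SynthConfig, n_per_cell: int = 8,
                             max_tries: int = 25) -> Iterator[tuple[Trace, TraceTruth]]:
    """Generate the 2x2 (condition x PMD status) comparison experiment.

    Yields ``n_per_cell`` responsive ROIs (truth max fold >= 2, i.e. ROIs
    that pass the study's inclusion rule) per design cell, mirroring the
    matched n-per-group selection of the tracer experiment.
    """
    config.validate()
    for ci, condition in enumerate(CONDITIONS):
        for pi, pmd in enumerate((PMD_POS, NO_PMD)):
            sid = f"{scaffold_label(condition, 0)}X{pi}"
            for j in range(n_per_cell):
                for attempt in range(max_tries):
                    rng = np.random.default_rng([int(config.seed), STREAM_CROSSTAB,
                                                 ci, pi, j, attempt])
                    rid = f"{sid}_R{j + 1:02d}"
                    trace, truth = generate_trace(config, condition, pmd, rng, sid, rid)
                    if truth.max_peak_fold >= 2.0:
                        yield trace, truth
                        break
                else:  # pragma: no cover - vanishingly rare at defaults
                    raise RuntimeError(f"no responsive ROI found for {condition}/{pmd}")


# ---------------------------------------------------------------------------
# two-channel imaging fields
# ---------------------------------------------------------------------------

IMAGE_SHAPE = (768, 768)
IMAGE_OFFSET = 100.0        # camera-style DC offset, counts
NUCLEUS_AMP = 3000.0
NUCLEUS_SIGMA_PX = 3.0
DEXTRAN_AMP = 1500.0
DEXTRAN_RADIUS_PX = 9.0
# spacing keeps one cell's cytosolic disk clear of its neighbors' annuli
CELL_MIN_DIST_PX = 22.0
CELL_MARGIN_PX = 20
DEFAULT_IMAGE_NOISE_SD = 30.0


def _place_centers(rng: np.random.Generator, n_cells: int, shape,
                   min_dist: float, margin: int) -> np.ndarray:
    centers: list[tuple[float, float]] = []
    tries = 0
    limit = max(200 * n_cells, 1000)
    while len(centers) < n_cells:
        if tries > limit:
            raise PlacementError(
                f"could not place {n_cells} cells without overlap "
                f"(placed {len(centers)})")
        tries += 1
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - rr) ** 2 + (c - cc) ** 2 >= min_dist ** 2 for rr, cc in centers):
            centers.append((r, c))
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def _stamp(img: np.ndarray, center: tuple[float, float], radius: int, patch_fn) -> None:
    r0, c0 = center
    ri, ci = int(round(r0)), int(round(c0))
    lo_r, hi_r = max(ri - radius, 0), min(ri + radius + 1, img.shape[0])
    lo_c, hi_c = max(ci - radius, 0), min(ci + radius + 1, img.shape[1])
    rr, cc = np.meshgrid(np.arange(lo_r, hi_r), np.arange(lo_c, hi_c), indexing="ij")
    img[lo_r:hi_r, lo_c:hi_c] += patch_fn(rr - r0, cc - c0)


def generate_pmd_image(config: SynthConfig, n_cells: int, wounded_frac: float,
                       rng: np.random.Generator, field_id: str = "F1",
                       shape=IMAGE_SHAPE, noise_sd: float = 0.0,
                       ) -> tuple[np.ndarray, FieldTruth]:
    """Render a two-channel field: page 0 nuclei, page 1 dextran.

    Exactly ``round(wounded_frac * n_cells)`` randomly chosen cells receive a
    cytosolic dextran disk (exact-count semantics, so downstream counting can
    be checked exactly).
    """
    if n_cells < 0:
        raise ConfigError("n_cells must be >= 0")
    if not 0.0 <= wounded_frac <= 1.0:
        raise ConfigError("wounded_frac must be in [0, 1]")
    nuclei = np.full(shape, IMAGE_OFFSET)
    dextran = np.full(shape, IMAGE_OFFSET)
    centers = (_place_centers(rng, n_cells, shape, CELL_MIN_DIST_PX, CELL_MARGIN_PX)
               if n_cells else np.empty((0, 2)))
    n_wounded = int(round(wounded_frac * n_cells))
    wounded = (rng.choice(n_cells, size=n_wounded, replace=False)
               if n_wounded else np.empty(0, dtype=int))
    sig2 = 2.0 * NUCLEUS_SIGMA_PX ** 2
    for r, c in centers:
        _stamp(nuclei, (r, c), int(4 * NUCLEUS_SIGMA_PX),
               lambda dr, dc: NUCLEUS_AMP * np.exp(-(dr ** 2 + dc ** 2) / sig2))
    edge = 1.0  # soft disk edge, px
    for i in wounded:
        r, c = centers[i]
        _stamp(dextran, (r, c), int(DEXTRAN_RADIUS_PX + 4),
               lambda dr, dc: DEXTRAN_AMP / (1.0 + np.exp(
                   (np.sqrt(dr ** 2 + dc ** 2) - DEXTRAN_RADIUS_PX) / edge)))
    if noise_sd > 0:
        nuclei = nuclei + rng.normal(0.0, noise_sd, shape)
        dextran = dextran + rng.normal(0.0, noise_sd, shape)
    stack = np.stack([np.maximum(nuclei, 0.0), np.maximum(dextran, 0.0)])
    truth = FieldTruth(field_id, n_cells, frozenset(int(i) for i in wounded), centers)
    return stack, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------

HOUSEKEEPING_GENE = "18S"
HOUSEKEEPING_CT = 12.0
TARGET_BASE_CT = 24.0


def generate_qpcr(config: SynthConfig, genes: Sequence[str],
                  fold_changes: Sequence[float], rng: np.random.Generator,
                  n_replicates: int = 5, noise_sd: float = 0.15,
                  housekeeping: str = HOUSEKEEPING_GENE) -> pd.DataFrame:
    """Ct table (sample, condition, gene, ct) for control and disuse.

    Target Ct under disuse is shifted by -log2(fold) relative to control,
    with housekeeping Ct constant up to noise, so the 2^-ddCt method
    recovers the prescribed folds.
    """
    if len(genes) != len(fold_changes):
        raise ConfigError("one fold change per gene required")
    if any(f <= 0 for f in fold_changes):
        raise ConfigError("fold changes must be > 0")
    rows = []
    for condition in CONDITIONS:
        for rep in range(n_replicates):
            sample = f"{condition}_{rep + 1}"
            rows.append({"sample": sample, "condition": condition,
                         "gene": housekeeping,
                         "ct": HOUSEKEEPING_CT + rng.normal(0.0, noise_sd)})
            for gi, (gene, fold) in enumerate(zip(genes, fold_changes)):
                ct = TARGET_BASE_CT + gi
                if condition == DISUSE:
                    ct -= np.log2(fold)
                rows.append({"sample": sample, "condition": condition,
                             "gene": gene, "ct": ct + rng.normal(0.0, noise_sd)})
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"])
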