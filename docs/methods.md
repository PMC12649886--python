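# Methods

## The measurement problem

Osteocytes grown on 3D scaffolds and reloaded with laminar fluid shear after
simulated disuse produce stochastic, asynchronous calcium transients
recorded as per-ROI fluorescence time series (one frame every 1.73 s over a
300 s window, i.e. 174 frames). Scaffold movement under flow makes the
pre-flow signal useless as a baseline reference and superimposes drift and
local motion artifacts on the recording, so every quantity is defined
relative to an adaptive per-cell baseline Fo: the stable plateau
immediately preceding the cell's highest calcium wave. This package
operationalizes that visually-defined analysis as a deterministic,
parameterized algorithm and validates it end to end on a synthetic
generator that carries ground truth.

## Per-ROI analysis

**Baseline (Fo).** The global fluorescence maximum is located (ties to the
earliest frame). Candidate plateau windows are all `plateau_len` = 10-frame
(~17.3 s) windows ending at or before the peak that contain no "rising"
frame, where a frame is rising when it exceeds 1.5× the trailing median of
the preceding 10 frames — this keeps the wave's own rising phase out of the
plateau. Among candidates the window with minimum variance wins; exact ties
go to the window closest to the peak ("immediately preceding"). If the peak
sits too early to fit any window, the first 10 frames are used and the
estimate is flagged degraded. The search is an exhaustive scan (vectorized),
so it is checked bit-for-bit against an independent brute-force loop.

**Wave detection.** A calcium wave is a maximal run of frames with
F/Fo ≥ `min_fold` (default 2, closed threshold: "at least 2-fold" counts).
Runs separated by less than `merge_gap_s` (default two frames) merge, so a
single sub-threshold frame cannot split one event. Each wave's extent is
then grown outward to the contiguous above-baseline excursion around it.
"Above baseline" uses the open threshold F > `extent_fold`·Fo (default 1)
**plus** `extent_sigma_k` = 3 standard deviations of the baseline window:
on noisy, drifting data a strict F > Fo walk does not terminate reliably
(any residual drift leaves the post-wave signal a hair above a plateau
estimated earlier), whereas requiring the signal to clear the plateau's own
noise band recovers true event durations to within ~1–2 frames. With
`extent_sigma_k = 0` the strict rule is restored, and on noise-free
plateaus the two coincide exactly. Duration is
(offset − onset)·dt; a single-frame excursion is credited one frame.

**Metrics and screens.** Per ROI: maximum fold change over baseline,
above-baseline duration of the highest peak (ties to the earliest wave),
wave count over the window, and a sustained-signal flag (every frame in the
final 10% of the window at ≥ 2-fold — a proxy for persistent loss of
membrane integrity). ROIs with no 2-fold excursion are excluded; exclusion
is logged because it is part of the method. An optional `preflow_s`
parameter discards frames recorded before flow onset.

Open choices resolved here: waves are counted against the single per-ROI
baseline (the analysis defines one baseline per cell); duration uses
F > Fo rather than F > 2·Fo, with both available by parameter.

## Aggregation

The scaffold is the biological replicate. Per-scaffold summaries average
included ROIs with equal weight: mean and maximum max-fold, mean peak
duration, mean wave count, and the percentage of included ROIs with
F/Fo > 10 (and > 5). Fractions are per-scaffold, then averaged across
scaffolds (matching a per-scaffold-percentage design); computing them over
all ROIs instead is a flag. The condition × PMD comparison groups included
ROIs into the 2×2 design and can subsample the no-PMD arm to the PMD+ count
per condition with a seeded RNG (the matched n-per-group design). Box-plot
statistics use linear-interpolation quartiles and 1.5·IQR fences; the
quartile convention is fixed so fences are reproducible.

## Membrane-wounding quantification

A repaired plasma-membrane disruption (PMD) traps 10 kDa FITC-dextran in
the cytosol. Fields are two-channel images (nuclei, dextran). Nuclei are
local maxima of the Gaussian-smoothed channel above a background-relative
threshold; a field whose dynamic range is within 6 robust SDs of background
is treated as empty. A cell is dextran-positive when the mean intensity of
a perinuclear annulus (radii 4–9 px) exceeds 2× the channel median, making
the classification invariant to uniform intensity rescaling. Cells whose
annulus would touch the image border are excluded from both counts. The
positivity rule is this package's operationalization of "cytosolic
retention"; percent wounded = 100 · positives / nuclei.

## Statistics

Two-group comparisons use the pooled-variance Student t-test (Welch
optional). The condition × PMD analysis is a two-factor ANOVA with
interaction: classical marginal-means sums of squares on balanced designs
(where SS_A + SS_B + SS_AB + SS_err = SS_total holds to 1e-9 relative), and
Type-II sums of squares from nested least-squares fits when unbalanced
(verified against statsmodels; the matched design the pipeline produces is
balanced). Fisher's LSD computes pairwise t statistics from the ANOVA error
mean square and df, and assigns compact letters greedily over groups sorted
by mean (label as tie-break), so the display is order-stable; LSD runs
unconditionally and the omnibus interaction p is reported alongside for
gating. A zero error sum of squares marks the table degenerate rather than
producing F ratios. Relative expression uses 2^−ΔΔCt with per-sample
ΔCt = Ct_target − Ct_18S and ΔΔCt referenced to the mean control ΔCt;
group tests run on ΔΔCt values, not folds. Tail probabilities come from the
scipy t and F distributions; everything else is computed explicitly.

## Synthetic data generator

Each trace is `baseline(t) · (1 + waves + artifacts) · (1 + noise)` with
`baseline(t) = level + drift·t`.

- **Waves.** The count is Poisson(rate × 300 s); condition-specific rates
  default to 0.012/s (control) and 0.008/s (disuse) so disuse shows fewer
  events, as reloading experiments report. Onsets are uniform but
  rejection-placed with a 3-frame minimum separation (the count marginal
  stays Poisson; separation keeps distinct truth events resolvable by any
  detector). Peak folds are lognormal(μ=1.1, σ=0.35) floored at
  `amp_min_fold` (median fold ≈ 3; the floor also realizes "all folds ≥ x"
  study conditions). Durations are normal(20 s, 6 s) truncated above two
  frames. The pulse is a half-sine rise (25% of the duration) and
  half-cosine decay: smooth, unimodal, asymmetric, with compact support and
  nonzero edge slope so the above-baseline extent of an event is
  well-defined at the noise floor (an exponential tail would make "duration
  above baseline" ill-posed). Pulse peaks are snapped to the frame grid so
  the rendered maximum equals the drawn fold exactly.
- **High responders.** With condition-specific probability (0.04 control,
  0.10 disuse — disuse more than doubles the subpopulation) the ROI's
  largest fold is resampled above 10. At σ=0.35 the lognormal background
  essentially never exceeds 10-fold, so the F/Fo > 10 subpopulation is the
  high-responder mechanism alone.
- **PMD coupling.** ROI PMD status is Bernoulli (0.05 control, 0.15
  disuse). Under disuse × PMD+ all folds are multiplied by 3 — the
  interaction is present by construction. The dedicated tracer-experiment
  configuration (`pmd_experiment_config`) zeroes the free-standing
  high-responder fractions: in that experiment the high-amplitude
  subpopulation arises through wounding, not independently.
- **Sustained signals.** With probability 0.02 (matching a rare, <3%
  phenomenon) the last wave whose peak settles before 85% of the window is
  held open at its peak (fold ≥ 3) to the end; later waves are dropped
  because they would ride on the persistent plateau. A quiet 25 s
  pre-event margin guarantees the "plateau immediately preceding the
  highest wave" exists.
- **Nuisance structure.** Motion artifacts are Gaussian bumps (Poisson at
  0.01/s, width 2–5 s, amplitude ±(0.15–0.3)× baseline, either sign): they
  perturb baselining but never reach the 2-fold wave threshold. Noise is
  multiplicative Gaussian (σ = 3% of signal), the photon-limited regime
  where noise scales with intensity.
- **Images.** 768×768 fields with ≥22 px cell spacing (one cell's
  cytosolic disk stays clear of its neighbors' annuli, so noise-free counts
  are exact), Gaussian nuclei (σ=3 px), soft-edged dextran disks (r=9 px),
  a 100-count camera offset, optional additive noise (default 30 counts).
  Exactly round(frac·n) cells are wounded, so counting tests are exact.
- **qPCR.** Target Ct is shifted by −log2(fold) under disuse with constant
  housekeeping Ct up to noise, so ΔΔCt recovers the prescribed folds.
- **Determinism.** Every ROI/field draws from
  `default_rng([seed, stream, condition, scaffold, roi])`; adding ROIs or
  scaffolds never perturbs earlier draws, and equal configs give
  byte-identical serialized outputs.

None of the generator's rates, amplitude parameters or artifact magnitudes
are empirical claims; they are plausible values fixed once so the synthetic
study has the qualitative structure the analysis targets (effect
directions, subpopulation enrichment, interaction specificity). What
passing recovery tests show is that the *pipeline* measures what the
generator put in, at realistic noise; they cannot certify performance on
real microscope data, which has photobleaching, segmentation error,
non-Gaussian artifacts and 3D structure the generator does not emulate
(nor does it model shear-field physics or z-stacks).

## Problem sizes and numerical choices

Recovery studies run on 1,000 synthetic ROIs; directional power checks use
100–200 replicate experiments at the full 6×30×2 design; null calibration
uses 10,000 Monte-Carlo replicates (binomial noise on the type-I estimate
is then ~0.2%, small against the ±1% acceptance band). Exact-equality
checks (baseline search vs. brute force) compare windows and Fo
bit-for-bit, which works because both paths evaluate the identical
variance expression. Variance uses the population convention (ddof 0);
only the argmin matters, so the convention is immaterial. Degenerate
inputs are signalled, not silently patched: empty design cells, missing
housekeeping wells and zero-included-ROI scaffolds raise or flag; zero
pooled variance yields t=0/p=1 on equal means and p→0 otherwise.

## Known limitations

- The baseline search assumes a plateau exists before the highest wave; a
  cell active from the first frame gets a degraded (flagged) estimate.
- Wave counting against a single per-ROI baseline under-counts events
  riding on unresolved elevation changes.
- The threshold-monotonicity property (raising `min_fold` never increases
  the count) is guaranteed for smooth unimodal events; pathological noise
  exactly at threshold can split runs.
- ROIs nested in scaffolds are handled by per-scaffold averaging, not
  mixed models, matching the study design this pipeline reproduces.
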