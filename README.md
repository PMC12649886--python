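# osteoflow

Analysis pipeline for calcium signaling and membrane wounding in
scaffold-cultured osteocytes that are mechanically reloaded (fluid shear)
after a period of simulated disuse (rotating-wall-vessel culture).

Osteocytes respond to fluid shear stress with stochastic, asynchronous
intracellular calcium transients. On 3D scaffolds the raw fluorescence is
contaminated by signal drift and local motion, so a fixed pre-flow baseline
is unusable; instead, each cell ROI gets an adaptive baseline Fo — the
stable plateau immediately preceding its highest calcium wave — and all
metrics are expressed as fold change F/Fo. The pipeline implements:

- **Per-ROI trace metrics** (`osteoflow.traces`): minimum-variance plateau
  search for Fo; calcium-wave detection as excursions with F/Fo ≥ 2;
  maximum fold change and above-baseline duration of the highest peak; wave
  count over the 300 s observation window; a sustained-signal screen for
  traces that never return to baseline; and the inclusion rule that drops
  ROIs without any 2-fold response.
- **Scaffold aggregation** (`osteoflow.aggregate`): scaffolds are the unit
  of replication; per-scaffold means, scaffold maxima, the percentage of
  ROIs with F/Fo > 10 (and > 5), condition × PMD cross-classification with
  matched subsampling, and box-plot statistics with 1.5·IQR fences.
- **Membrane-wounding quantification** (`osteoflow.pmd`): percent of
  dextran-retaining cells per two-channel field (nuclei + dextran); a
  repaired plasma-membrane disruption (PMD) traps the tracer in the cytosol.
- **Statistics** (`osteoflow.stats`): Student/Welch t-tests, two-factor
  ANOVA with interaction (balanced closed form, Type-II when unbalanced),
  Fisher's LSD with compact letter display, and 2^−ΔΔCt relative expression
  with 18S normalization — all written out from first principles.
- **Synthetic data with ground truth** (`osteoflow.synth`): a generator
  that emulates the experiment's signal structure (drift, motion artifacts,
  multiplicative noise, lognormal wave amplitudes, a disuse-enriched
  high-amplitude subpopulation, PMD-coupled amplification, wounded-cell
  image fields, qPCR Ct tables) and records everything it draws, so every
  downstream metric is validated by recovery.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (each can also be reached through the `osteoflow` CLI):

```sh
python analysis/01_simulate.py        # traces, images, Ct tables -> results/data/
python analysis/02_trace_metrics.py   # per-ROI metrics + scaffold comparisons
python analysis/03_pmd_wounding.py    # percent wounded per field + t-test
python analysis/04_pmd_interaction.py # condition x PMD ANOVA + LSD letters
python analysis/05_qpcr.py            # ddCt folds + tests
```

`02_trace_metrics.py` prints (seed 0):

```
333/360 ROIs showed a >=2-fold calcium wave; 6 sustained signals
       comparison               metric  mean_control  mean_disuse  statistic   df      p
disuse vs control        mean_max_fold        4.6898       6.5135     2.8436 10.0 0.0174
disuse vs control    scaffold_max_fold       11.9794      18.5406     1.9631 10.0 0.0780
disuse vs control mean_peak_duration_s       20.7696      22.3927     1.1733 10.0 0.2679
disuse vs control      mean_wave_count        3.2733       2.4385    -8.0434 10.0 0.0000
disuse vs control       frac_fold_gt10        4.3619      21.8661     4.0254 10.0 0.0024
disuse vs control        frac_fold_gt5       26.3432      43.0895     2.9795 10.0 0.0138
```

Reading the table: disuse scaffolds carry a much larger subpopulation of
high-intensity responders (F/Fo > 10 in 21.9% vs 4.4% of ROIs) while
showing *fewer* calcium waves on average (2.44 vs 3.27 per 300 s) — the
amplitude of the response grows under disuse even as its frequency drops.
`04_pmd_interaction.py` then shows that amplification is specific to
wounded cells under disuse (interaction p = 0.0021; the disuse × PMD+ group
is the only one assigned LSD letter "a").

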