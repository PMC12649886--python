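"""End-to-end pipeline steps shared by the CLI and the analysis drivers.

Each step is a plain function over in-memory objects so tests, the numbered
analysis scripts, and the command line all exercise exactly the same code.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import aggregate, io, pmd, stats, synth
from .config import SynthConfig
from .core import CONDITIONS, CONTROL, DISUSE
from .traces import RoiMetrics, TraceParams, analyze_roi, metrics_to_frame

log = logging.getLogger("osteoflow")


def simulate_metrics(config: SynthConfig,
                     params: TraceParams | None = None) -> tuple[list[RoiMetrics], list]:
    """Generate a full experiment and analyze every ROI (no table detour)."""
    params = params or TraceParams()
    metrics, truths = [], []
    for trace, truth in synth.generate_traces(config):
        m = analyze_roi(trace, params)
        if not m.included:
            log.info("ROI %s excluded: no 2-fold wave (max F/Fo = %.2f)",
                     m.roi_id, m.max_fold_change)
        if m.baseline_degraded:
            log.info("ROI %s: degraded baseline estimate", m.roi_id)
        metrics.append(m)
        truths.append(truth)
    return metrics, truths


def analyze_trace_table(trace_df: pd.DataFrame,
                        params: TraceParams | None = None) -> pd.DataFrame:
    params = params or TraceParams()
    return metrics_to_frame([analyze_roi(t, params)
                             for t in io.traces_from_table(trace_df)])


SCAFFOLD_METRICS = ["mean_max_fold", "scaffold_max_fold", "mean_peak_duration_s",
                    "mean_wave_count", "frac_fold_gt10", "frac_fold_gt5"]


def condition_comparisons(summary_df: pd.DataFrame) -> pd.DataFrame:
    """Control-vs-disuse Student t-tests on every per-scaffold metric."""
    valid = summary_df[summary_df["valid"].astype(bool)]
    rows = []
    for metric in SCAFFOLD_METRICS:
        groups = {c: valid.loc[valid["condition"] == c, metric].to_numpy()
                  for c in CONDITIONS}
        if any(len(g) < 2 for g in groups.values()):
            continue
        t, df, p = stats.t_test(groups[DISUSE], groups[CONTROL])
        rows.append({"comparison": "disuse vs control", "metric": metric,
                     "mean_control": float(np.mean(groups[CONTROL])),
                     "mean_disuse": float(np.mean(groups[DISUSE])),
                     "statistic": t, "df": df, "p": p})
    return pd.DataFrame(rows)


def interaction_analysis(metrics_df: pd.DataFrame, match: bool = False,
                         rng: np.random.Generator | None = None,
                         ) -> tuple[stats.AnovaTable, pd.DataFrame, dict]:
    """Condition x PMD two-factor ANOVA with Fisher's LSD on max fold change."""
    grouped = aggregate.crosstab_by_pmd(metrics_df, match=match, rng=rng)
    values = grouped["max_fold_change"].to_numpy(dtype=float)
    table = stats.anova_2x2(values, grouped["condition"].to_numpy(),
                            grouped["pmd_status"].to_numpy())
    keys = list(zip(grouped["condition"], grouped["pmd_status"]))
    cell_means = {k: float(np.mean(values[[kk == k for kk in keys]]))
                  for k in set(keys)}
    cell_ns = {k: int(sum(kk == k for kk in keys)) for k in set(keys)}
    pairwise, letters = stats.fisher_lsd(table, cell_means, cell_ns)
    return table, pairwise, letters


def simulate_to_dir(config: SynthConfig, out_dir, images: bool = True,
                    qpcr_genes=("Sost", "Tnfsf11", "Dkk1"),
                    qpcr_folds=(2.0, 2.0, 1.5), n_fields: int = 3) -> dict:
    """Write trace/truth/image/Ct fixtures plus a seed manifest; returns manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace_df, truth_df = synth.generate_experiment(config)
    paths = {
        "traces": io.write_table(trace_df, out_dir / "traces.csv"),
        "truth": io.write_table(truth_df, out_dir / "truth_rois.csv"),
    }
    rng_q = np.random.default_rng([int(config.seed), synth.STREAM_QPCR])
    qpcr_df = synth.generate_qpcr(config, list(qpcr_genes), list(qpcr_folds), rng_q)
    paths["qpcr"] = io.write_table(qpcr_df, out_dir / "qpcr_ct.csv")
    if images:
        truth_rows = []
        for ci, condition in enumerate(CONDITIONS):
            for k in range(n_fields):
                rng = np.random.default_rng([int(config.seed), synth.STREAM_IMAGES,
                                             ci, k])
                fid = f"{condition}_{k + 1}"
                stack, ftruth = synth.generate_pmd_image(
                    config, n_cells=200, wounded_frac=config.pmd_frac(condition),
                    rng=rng, field_id=fid, noise_sd=synth.DEFAULT_IMAGE_NOISE_SD)
                io.write_image_stack(stack, out_dir / "images" / f"{fid}.tif")
                truth_rows.append({"field_id": fid, "condition": condition,
                                   "n_cells": ftruth.n_cells,
                                   "n_wounded": len(ftruth.dextran_positive_ids)})
        paths["field_truth"] = io.write_table(pd.DataFrame(truth_rows),
                                              out_dir / "truth_fields.csv")
    config.to_yaml(out_dir / "config.yaml")
    manifest = {"seed": int(config.seed),
                "files": {k: _sha256(p) for k, p in paths.items()}}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def analyze_to_dir(trace_path, out_dir, params: TraceParams | None = None,
                   seed: int = 0) -> dict:
    """Run traces -> aggregate -> stats on a trace CSV, writing all outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trace_df = io.read_trace_table(trace_path)
    metrics_df = analyze_trace_table(trace_df, params)
    summary_df = aggregate.summarize_experiment(metrics_df)
    report_df = condition_comparisons(summary_df)
    outputs = {
        "metrics": io.write_table(metrics_df, out_dir / "roi_metrics.csv"),
        "summary": io.write_table(summary_df, out_dir / "scaffold_summary.csv"),
        "report": io.write_table(report_df, out_dir / "stats_report.csv"),
    }
    try:
        rng = np.random.default_rng([int(seed), 11])
        table, pairwise, letters = interaction_analysis(metrics_df, match=True, rng=rng)
        anova_df = table.to_frame()
        anova_df["comparison"] = "condition x pmd on max_fold_change"
        letters_df = pd.DataFrame(
            [{"condition": k[0], "pmd_status": k[1], "letters": v}
             for k, v in sorted(letters.items(), key=lambda kv: kv[0])])
        outputs["anova"] = io.write_table(anova_df, out_dir / "anova_interaction.csv")
        outputs["letters"] = io.write_table(letters_df, out_dir / "lsd_letters.csv")
        outputs["pairwise"] = io.write_table(pairwise, out_dir / "lsd_pairwise.csv")
    except Exception as exc:  # design cell empty, e.g. no PMD+ ROIs present
        log.info("condition x PMD analysis skipped: %s", exc)
    return {k: str(v) for k, v in outputs.items()}


def pmd_compare(fields_df: pd.DataFrame) -> pd.DataFrame:
    """Control vs. disuse Student t-test on percent wounded per field."""
    valid = fields_df[fields_df["valid"].astype(bool)]
    groups = {c: valid.loc[valid["condition"] == c, "pct_wounded"].to_numpy()
              for c in CONDITIONS}
    if any(len(g) < 2 for g in groups.values()):
        return pd.DataFrame()
    t, df, p = stats.t_test(groups[DISUSE], groups[CONTROL])
    return pd.DataFrame([{"comparison": "disuse vs control", "metric": "pct_wounded",
                          "mean_control": float(np.mean(groups[CONTROL])),
                          "mean_disuse": float(np.mean(groups[DISUSE])),
                          "statistic": t, "df": df, "p": p}])
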