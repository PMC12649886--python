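"""Scaffold-level aggregation and subpopulation structure.

ROIs are nested in scaffolds; the study's unit of biological replication is
the scaffold, so per-ROI metrics are averaged per scaffold (equal weight over
included ROIs) before any between-condition statistics. Subpopulation
fractions report the percentage of included ROIs whose highest peak exceeded
10-fold (and 5-fold) over baseline.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import InputError, CONDITIONS, NO_PMD, PMD_POS

HIGH_FOLD_THRESHOLD = 10.0
MID_FOLD_THRESHOLD = 5.0


@dataclass
class ScaffoldSummary:
    scaffold_id: str
    condition: str
    n_rois_included: int
    n_rois_total: int
    mean_max_fold: float
    scaffold_max_fold: float
    mean_peak_duration_s: float
    mean_wave_count: float
    frac_fold_gt10: float      # percent of included ROIs
    frac_fold_gt5: float       # percent of included ROIs
    n_sustained: int
    valid: bool = True


SUMMARY_COLUMNS = ["scaffold_id", "condition", "n_rois_included", "n_rois_total",
                   "mean_max_fold", "scaffold_max_fold", "mean_peak_duration_s",
                   "mean_wave_count", "frac_fold_gt10", "frac_fold_gt5",
                   "n_sustained", "valid"]


def summarize_scaffold(metrics: pd.DataFrame,
                       fractions_over_included: bool = True) -> ScaffoldSummary:
    """Aggregate one scaffold's ROI metrics.

    Means and fractions are computed over included ROIs with equal weight;
    a scaffold with no included ROI yields an invalid summary (NaN means)
    that downstream statistics must skip.
    """
    scaffold_ids = metrics["scaffold_id"].unique()
    if len(scaffold_ids) != 1:
        raise InputError(f"metrics mix scaffolds: {sorted(scaffold_ids)}")
    condition = metrics["condition"].iloc[0]
    inc = metrics[metrics["included"].astype(bool)]
    n_sustained = int(metrics["sustained"].astype(bool).sum())
    if len(inc) == 0:
        return ScaffoldSummary(str(scaffold_ids[0]), condition, 0, len(metrics),
                               float("nan"), float("nan"), float("nan"),
                               float("nan"), float("nan"), float("nan"),
                               n_sustained, valid=False)
    folds = inc["max_fold_change"].to_numpy(dtype=float)
    frac_base = inc if fractions_over_included else metrics
    frac_folds = frac_base["max_fold_change"].to_numpy(dtype=float)
    return ScaffoldSummary(
        scaffold_id=str(scaffold_ids[0]),
        condition=condition,
        n_rois_included=len(inc),
        n_rois_total=len(metrics),
        mean_max_fold=float(np.mean(folds)),
        scaffold_max_fold=float(np.max(folds)),
        mean_peak_duration_s=float(np.mean(inc["highest_peak_duration_s"])),
        mean_wave_count=float(np.mean(inc["wave_count"])),
        frac_fold_gt10=float(100.0 * np.mean(frac_folds > HIGH_FOLD_THRESHOLD)),
        frac_fold_gt5=float(100.0 * np.mean(frac_folds > MID_FOLD_THRESHOLD)),
        n_sustained=n_sustained,
    )


def summarize_experiment(metrics: pd.DataFrame,
                         fractions_over_included: bool = True) -> pd.DataFrame:
    """Per-scaffold summaries for a whole experiment, one row per scaffold."""
    rows = []
    for _, group in metrics.groupby("scaffold_id", sort=True):
        s = summarize_scaffold(group, fractions_over_included)
        rows.append({c: getattr(s, c) for c in SUMMARY_COLUMNS})
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def crosstab_by_pmd(metrics: pd.DataFrame, match: bool = False,
                    rng: np.random.Generator | None = None,
                    included_only: bool = True) -> pd.DataFrame:
    """Group ROI metrics by condition x PMD status for the 2x2 comparison.

    With ``match=True`` the no-PMD arm of each condition is randomly
    subsampled to the PMD+ count (the matched n-per-group design); ``rng``
    must then be provided so the subsample is reproducible from the run seed.
    Raises when any design cell is empty.
    """
    df = metrics[metrics["included"].astype(bool)] if included_only else metrics
    cells = {}
    for condition in CONDITIONS:
        for pmd in (PMD_POS, NO_PMD):
            cell = df[(df["condition"] == condition) & (df["pmd_status"] == pmd)]
            if len(cell) == 0:
                raise InputError(f"empty design cell: {condition} x {pmd}")
            cells[(condition, pmd)] = cell
    if match:
        if rng is None:
            raise InputError("match=True requires a seeded rng")
        for condition in CONDITIONS:
            n_pos = len(cells[(condition, PMD_POS)])
            cell = cells[(condition, NO_PMD)]
            if len(cell) > n_pos:
                take = np.sort(rng.choice(len(cell), size=n_pos, replace=False))
                cells[(condition, NO_PMD)] = cell.iloc[take]
    return pd.concat(cells.values(), ignore_index=True)


def boxplot_stats(values) -> dict:
    """Five-number box-plot summary with 1.5*IQR outlier fences.

    Quartiles use linear interpolation between order statistics; fences are
    Q1 - 1.5*IQR and Q3 + 1.5*IQR.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise InputError("boxplot_stats requires at least one value")
    q1, med, q3 = np.percentile(arr, [25.0, 50.0, 75.0])
    iqr = q3 - q1
    return {"median": float(med), "q1": float(q1), "q3": float(q3),
            "lower_fence": float(q1 - 1.5 * iqr),
            "upper_fence": float(q3 + 1.5 * iqr)}
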