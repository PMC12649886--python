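"""Plasma-membrane-disruption (PMD) quantification from two-channel fields.

A wounded-then-repaired cell retains fluorescent dextran in its cytosol, so
the percent of wounded cells in a field is the fraction of nuclei whose
perinuclear region is dextran-bright. Nuclei are detected as smoothed local
maxima in the nuclei channel; dextran positivity compares the mean intensity
of an annulus around each nucleus with the field background (the channel
median), making the classification invariant to uniform intensity rescaling.
Cells whose annulus would touch the image border are excluded from both
counts, since truncated cytoplasm biases the intensity comparison.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max

from .core import InputError


@dataclass
class PmdParams:
    smooth_sigma: float = 2.0
    min_distance: int = 7          # px between nucleus peaks
    rel_threshold: float = 0.3     # of the background-subtracted maximum
    detect_snr: float = 6.0        # required (max - median) / robust sigma
    annulus_r_in: float = 4.0
    annulus_r_out: float = 9.0
    positive_factor: float = 2.0   # annulus mean must exceed factor * background


@dataclass
class PmdField:
    field_id: str
    condition: str
    n_nuclei: int
    n_dextran_pos: int
    pct_wounded: float
    valid: bool = True


FIELD_COLUMNS = ["field_id", "condition", "n_nuclei", "n_dextran_pos",
                 "pct_wounded", "valid"]


def detect_nuclei(nuclei_channel: np.ndarray,
                  params: PmdParams | None = None) -> np.ndarray:
    """Nucleus centers as an (n, 2) array of (row, col) pixel coordinates.

    The channel is Gaussian-smoothed and local maxima above a
    background-relative threshold are kept. A field whose dynamic range is
    within ``detect_snr`` robust sigmas of the background is treated as
    empty rather than thresholded into noise peaks.
    """
    params = params or PmdParams()
    img = np.asarray(nuclei_channel, dtype=float)
    if img.ndim != 2:
        raise InputError("nuclei channel must be a 2-D image")
    smoothed = ndimage.gaussian_filter(img, params.smooth_sigma)
    background = float(np.median(smoothed))
    peak = float(np.max(smoothed))
    mad = float(np.median(np.abs(smoothed - background)))
    robust_sigma = 1.4826 * mad
    floor = max(params.detect_snr * robust_sigma, 1e-9 * max(abs(background), 1.0))
    if peak - background < floor:
        return np.empty((0, 2), dtype=float)
    threshold = background + params.rel_threshold * (peak - background)
    coords = peak_local_max(smoothed, min_distance=params.min_distance,
                            threshold_abs=threshold, exclude_border=False)
    border = int(np.ceil(params.annulus_r_out))
    keep = ((coords[:, 0] >= border) & (coords[:, 0] < img.shape[0] - border) &
            (coords[:, 1] >= border) & (coords[:, 1] < img.shape[1] - border))
    return coords[keep].astype(float)


def classify_dextran(dextran_channel: np.ndarray, centers: np.ndarray,
                     params: PmdParams | None = None) -> np.ndarray:
    """Boolean per cell: mean perinuclear annulus intensity above background.

    Background is the channel median; a cell is positive when its annulus
    mean exceeds ``positive_factor`` times the background. Annuli are
    clipped at the image boundary if necessary.
    """
    params = params or PmdParams()
    img = np.asarray(dextran_channel, dtype=float)
    if img.ndim != 2:
        raise InputError("dextran channel must be a 2-D image")
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    background = float(np.median(img))
    r_out = int(np.ceil(params.annulus_r_out))
    flags = np.zeros(len(centers), dtype=bool)
    for i, (r0, c0) in enumerate(centers):
        lo_r = max(int(r0) - r_out, 0)
        hi_r = min(int(r0) + r_out + 1, img.shape[0])
        lo_c = max(int(c0) - r_out, 0)
        hi_c = min(int(c0) + r_out + 1, img.shape[1])
        rr, cc = np.meshgrid(np.arange(lo_r, hi_r), np.arange(lo_c, hi_c),
                             indexing="ij")
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        ring = (d2 >= params.annulus_r_in ** 2) & (d2 <= params.annulus_r_out ** 2)
        if not np.any(ring):       # fully clipped annulus
            continue
        mean_ring = float(np.mean(img[lo_r:hi_r, lo_c:hi_c][ring]))
        flags[i] = mean_ring > params.positive_factor * max(background, 1e-12)
    return flags


def count_pmd_field(nuclei_channel: np.ndarray, dextran_channel: np.ndarray,
                    field_id: str = "F1", condition: str = "control",
                    params: PmdParams | None = None) -> PmdField:
    """Detect nuclei, classify dextran retention, and report percent wounded."""
    params = params or PmdParams()
    centers = detect_nuclei(nuclei_channel, params)
    n = len(centers)
    if n == 0:
        return PmdField(field_id, condition, 0, 0, float("nan"), valid=False)
    positive = classify_dextran(dextran_channel, centers, params)
    n_pos = int(np.sum(positive))
    return PmdField(field_id, condition, n, n_pos, 100.0 * n_pos / n)


def count_pmd_table(cell_table: pd.DataFrame, condition_by_field: dict | None = None,
                    ) -> pd.DataFrame:
    """PMD percentages from a pre-extracted cell table.

    Expects columns field_id, cell_id, dextran_positive; returns one row per
    field in the PmdField schema.
    """
    required = {"field_id", "cell_id", "dextran_positive"}
    if not required.issubset(cell_table.columns):
        raise InputError(f"cell table must have columns {sorted(required)}")
    rows = []
    for field_id, sub in cell_table.groupby("field_id", sort=True):
        n = len(sub)
        n_pos = int(sub["dextran_positive"].astype(bool).sum())
        condition = (condition_by_field or {}).get(field_id, sub.get(
            "condition", pd.Series(["control"])).iloc[0])
        rows.append({"field_id": field_id, "condition": condition,
                     "n_nuclei": n, "n_dextran_pos": n_pos,
                     "pct_wounded": 100.0 * n_pos / n if n else float("nan"),
                     "valid": n > 0})
    return pd.DataFrame(rows, columns=FIELD_COLUMNS)


def fields_to_frame(fields: list[PmdField]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(f, c) for c in FIELD_COLUMNS} for f in fields],
                        columns=FIELD_COLUMNS)
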