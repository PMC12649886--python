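"""Table and image plumbing: CSV schemas, TIFF stacks, trace round-trips."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import InputError, Trace
from .synth import TRACE_COLUMNS


def write_table(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_trace_table(path) -> pd.DataFrame:
    """Read and validate a trace CSV (see TRACE_COLUMNS for the schema)."""
    try:
        # round_trip parsing keeps write -> read -> write byte-identical
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface parser context
        raise InputError(f"could not parse trace CSV {path}: {exc}") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"trace CSV {path} missing columns: {missing}")
    bad = df.index[~np.isfinite(df["fluorescence"]) | (df["fluorescence"] <= 0)]
    if len(bad):
        raise InputError(
            f"trace CSV {path}: non-positive or non-finite fluorescence "
            f"at row {int(bad[0]) + 2} (1-based, incl. header)")
    return df[TRACE_COLUMNS]


def traces_from_table(df: pd.DataFrame):
    """Yield Trace objects from a long-format trace table, ROI by ROI."""
    for roi_id, sub in df.groupby("roi_id", sort=True):
        sub = sub.sort_values("frame")
        yield Trace(str(sub["scaffold_id"].iloc[0]), str(sub["condition"].iloc[0]),
                    str(roi_id), str(sub["pmd_status"].iloc[0]),
                    sub["time_s"].to_numpy(dtype=float),
                    sub["fluorescence"].to_numpy(dtype=float))


def write_image_stack(stack: np.ndarray, path) -> Path:
    """Write a (2, H, W) field as a multi-page 16-bit grayscale TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.clip(np.round(np.asarray(stack)), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    return path


def read_image_stack(path) -> np.ndarray:
    stack = tifffile.imread(path)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise InputError(f"{path}: expected a multi-page TIFF (nuclei, dextran)")
    return stack.astype(float)
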