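"""Shared domain types for scaffold calcium-reloading experiments.

A *trace* is one ROI's fluorescence-vs-time record during fluid-shear
reloading; *truth* objects carry the generator's ground truth so that every
downstream metric can be validated by recovery.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTROL = "control"
DISUSE = "disuse"
CONDITIONS = (CONTROL, DISUSE)

PMD_POS = "pmd_pos"
NO_PMD = "no_pmd"
PMD_UNKNOWN = "unknown"
PMD_STATUSES = (PMD_POS, NO_PMD, PMD_UNKNOWN)

# maximum tolerated deviation from uniform frame spacing, in seconds
SPACING_TOL_S = 1e-9


class InputError(ValueError):
    """Raised for invalid traces, tables or images."""


@dataclass
class Trace:
    """One ROI's fluorescence time series with its experimental labels."""

    scaffold_id: str
    condition: str
    roi_id: str
    pmd_status: str
    times: np.ndarray
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise InputError(f"unknown condition {self.condition!r}")
        if self.pmd_status not in PMD_STATUSES:
            raise InputError(f"unknown pmd_status {self.pmd_status!r}")
        if self.times.ndim != 1 or self.fluorescence.ndim != 1:
            raise InputError("times and fluorescence must be 1-D")
        if len(self.times) != len(self.fluorescence):
            raise InputError("times and fluorescence length mismatch")
        if len(self.times) < 2:
            raise InputError(f"trace {self.roi_id}: needs at least 2 frames")
        steps = np.diff(self.times)
        if np.any(steps <= 0):
            raise InputError(f"trace {self.roi_id}: times not strictly increasing")
        if np.max(np.abs(steps - steps[0])) > SPACING_TOL_S:
            raise InputError(f"trace {self.roi_id}: frame spacing not uniform")
        if not np.all(np.isfinite(self.fluorescence)) or np.any(self.fluorescence <= 0):
            raise InputError(f"trace {self.roi_id}: fluorescence must be finite and > 0")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def dt_s(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class TraceTruth:
    """Generator ground truth for one ROI (all drawn event parameters)."""

    roi_id: str
    true_baseline: float
    wave_onsets: np.ndarray = field(default_factory=lambda: np.empty(0))
    wave_peak_folds: np.ndarray = field(default_factory=lambda: np.empty(0))
    wave_durations: np.ndarray = field(default_factory=lambda: np.empty(0))
    is_high_responder: bool = False
    is_sustained: bool = False

    def __post_init__(self) -> None:
        self.wave_onsets = np.asarray(self.wave_onsets, dtype=float)
        self.wave_peak_folds = np.asarray(self.wave_peak_folds, dtype=float)
        self.wave_durations = np.asarray(self.wave_durations, dtype=float)
        if not (len(self.wave_onsets) == len(self.wave_peak_folds) == len(self.wave_durations)):
            raise InputError(f"truth {self.roi_id}: wave lists have unequal length")
        if np.any(self.wave_peak_folds < 1.0):
            raise InputError(f"truth {self.roi_id}: peak folds must be >= 1")

    @property
    def n_waves(self) -> int:
        return len(self.wave_onsets)

    @property
    def max_peak_fold(self) -> float:
        if self.n_waves == 0:
            return 1.0
        return float(np.max(self.wave_peak_folds))


@dataclass
class FieldTruth:
    """Ground truth for one synthetic two-channel imaging field."""

    field_id: str
    n_cells: int
    dextran_positive_ids: frozenset
    cell_centers: np.ndarray  # (n_cells, 2) as (row, col) pixels

    def __post_init__(self) -> None:
        self.dextran_positive_ids = frozenset(int(i) for i in self.dextran_positive_ids)
        self.cell_centers = np.asarray(self.cell_centers, dtype=float).reshape(-1, 2)
        if len(self.dextran_positive_ids) > self.n_cells:
            raise InputError("more dextran-positive ids than cells")
        if self.cell_centers.shape[0] != self.n_cells:
            raise InputError("cell_centers length must equal n_cells")
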