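"""In-memory data model for volumes, series, partitions, results and cohort tables.

Axis convention: for volumetric data, array index 0 runs cranial -> caudal.
For coronal MRI frames, image row index 0 is cranial. Readers are responsible
for reorienting into this convention (see :mod:`lunghetero.io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CTVolume",
    "Section",
    "OEMRISeries",
    "PartitionScheme",
    "LavResult",
    "RerResult",
    "GroundTruth",
    "COHORT_COLUMNS",
    "COHORT_UNITS",
    "validate_cohort_table",
    "PHASES",
]

#: OEMRI acquisition phases, in order: room air, 100% oxygen, room air again.
PHASES = ("air1", "O2", "air2")


@dataclass
class CTVolume:
    """A HU-valued voxel grid with lung and trachea masks.

    Parameters
    ----------
    hu : ndarray, shape (nz, ny, nx)
        Voxel attenuation in Hounsfield units; axis 0 cranial -> caudal.
    spacing : tuple of float
        Voxel spacing in mm per axis, ordered (z, y, x).
    lung_mask, trachea_mask : ndarray of bool
        Congruent with ``hu``; the two masks are disjoint.
    calibration_shift : float or None
        Additive HU shift already applied by tracheal-air calibration,
        ``None`` if the volume is uncalibrated.
    """

    hu: np.ndarray
    spacing: tuple[float, float, float]
    lung_mask: np.ndarray
    trachea_mask: np.ndarray
    calibration_shift: float | None = None

    def __post_init__(self) -> None:
        self.hu = np.asarray(self.hu, dtype=np.float64)
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        self.trachea_mask = np.asarray(self.trachea_mask, dtype=bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.hu.ndim != 3:
            raise ValueError(f"hu must be 3-D, got shape {self.hu.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive floats, got {self.spacing}")
        for name, m in (("lung_mask", self.lung_mask), ("trachea_mask", self.trachea_mask)):
            if m.shape != self.hu.shape:
                raise ValueError(f"{name} shape {m.shape} != hu shape {self.hu.shape}")
        if np.any(self.lung_mask & self.trachea_mask):
            raise ValueError("lung_mask and trachea_mask must be disjoint")
        if int(self.lung_mask.sum()) < 12:
            raise ValueError(
                f"lung mask contains {int(self.lung_mask.sum())} voxels; "
                "at least 12 required for partitioning"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.hu.shape

    @property
    def lung_voxel_count(self) -> int:
        return int(self.lung_mask.sum())

    def shifted(self, delta_hu: float, *, calibration_shift: float | None = None) -> "CTVolume":
        """Return a copy with a constant HU shift applied everywhere."""
        return CTVolume(
            hu=self.hu + float(delta_hu),
            spacing=self.spacing,
            lung_mask=self.lung_mask.copy(),
            trachea_mask=self.trachea_mask.copy(),
            calibration_shift=calibration_shift,
        )


@dataclass
class Section:
    """One coronal OEMRI section: a frame stack over time plus geometry.

    ``frames`` has shape (n_frames, ny, nx); row index 0 is cranial.
    ``cc_coords`` gives the physical cranial-caudal coordinate (mm) of each
    image row, shared by all frames, so sections acquired at different table
    positions can be pooled on a common axis.
    """

    frames: np.ndarray
    pixel_spacing: tuple[float, float]
    cc_coords: np.ndarray
    lung_roi: np.ndarray
    location: str = "central"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        self.cc_coords = np.asarray(self.cc_coords, dtype=np.float64)
        self.lung_roi = np.asarray(self.lung_roi, dtype=bool)
        self.pixel_spacing = tuple(float(s) for s in self.pixel_spacing)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (t, ny, nx), got {self.frames.shape}")
        ny, nx = self.frames.shape[1:]
        if self.lung_roi.shape != (ny, nx):
            raise ValueError(f"lung_roi shape {self.lung_roi.shape} != frame shape {(ny, nx)}")
        if self.cc_coords.shape != (ny,):
            raise ValueError(f"cc_coords must have one entry per row ({ny}), got {self.cc_coords.shape}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class OEMRISeries:
    """A multi-section OEMRI acquisition with per-frame phase labels."""

    sections: list[Section]
    phase_labels: np.ndarray  # dtype str, one per frame, values in PHASES

    def __post_init__(self) -> None:
        self.phase_labels = np.asarray(self.phase_labels, dtype=object)
        if not self.sections:
            raise ValueError("series must contain at least one section")
        n = self.sections[0].n_frames
        for s in self.sections:
            if s.n_frames != n:
                raise ValueError("all sections must share the same frame count")
        if len(self.phase_labels) != n:
            raise ValueError(
                f"frame count ({n}) != phase-label count ({len(self.phase_labels)})"
            )
        bad = set(self.phase_labels) - set(PHASES)
        if bad:
            raise ValueError(f"unknown phase labels: {sorted(bad)}")
        for p in PHASES:
            if not np.any(self.phase_labels == p):
                raise ValueError(f"phase {p!r} is empty")

    @property
    def n_frames(self) -> int:
        return self.sections[0].n_frames

    def phase_frames(self, phase: str) -> np.ndarray:
        """Frame indices belonging to ``phase``, in acquisition order."""
        return np.flatnonzero(self.phase_labels == phase)


@dataclass
class PartitionScheme:
    """Equal-count cranial-caudal partition assignment of lung voxels.

    ``assignment`` is a full-grid int array: partition index (0-based,
    cranial = 0) for lung voxels, -1 elsewhere. ``kept`` lists the partition
    indices retained for the heterogeneity SD (ends excluded by default).
    """

    n_total: int
    kept: tuple[int, ...]
    assignment: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        if sorted(set(self.kept)) != sorted(self.kept):
            raise ValueError("kept indices must be unique")
        if any(k < 0 or k >= self.n_total for k in self.kept):
            raise ValueError("kept indices out of range")
        if self.counts.shape != (self.n_total,):
            raise ValueError("counts must have one entry per partition")
        if int(self.counts.sum()) != int((self.assignment >= 0).sum()):
            raise ValueError("counts inconsistent with assignment")


@dataclass
class LavResult:
    """CT densitometry summary: whole-lung LAV%, per-partition LAV%, SD-LAV."""

    lav_percent_whole: float
    per_partition_lav_percent: np.ndarray  # kept partitions only
    all_partition_lav_percent: np.ndarray  # every partition, cranial -> caudal
    sd_lav: float
    threshold_hu: float
    calibration_shift: float
    n_partitions: int
    kept: tuple[int, ...]

    def __post_init__(self) -> None:
        self.per_partition_lav_percent = np.asarray(self.per_partition_lav_percent, dtype=float)
        self.all_partition_lav_percent = np.asarray(self.all_partition_lav_percent, dtype=float)
        if not (0.0 <= self.lav_percent_whole <= 100.0):
            raise ValueError("whole-lung LAV% out of [0, 100]")
        if self.sd_lav < 0:
            raise ValueError("SD-LAV must be non-negative")

    def to_dict(self) -> dict:
        return {
            "lav_percent_whole": float(self.lav_percent_whole),
            "per_partition_lav_percent": [float(v) for v in self.per_partition_lav_percent],
            "all_partition_lav_percent": [float(v) for v in self.all_partition_lav_percent],
            "sd_lav": float(self.sd_lav),
            "threshold_hu": float(self.threshold_hu),
            "calibration_shift": float(self.calibration_shift),
            "n_partitions": int(self.n_partitions),
            "kept": [int(k) for k in self.kept],
        }


@dataclass
class RerResult:
    """OEMRI summary: per-section RER maps, MRER, per-partition means, SD-RER."""

    rer_maps: list[np.ndarray]  # NaN outside the effective ROI
    mrer: float
    per_partition_mean_rer: np.ndarray
    sd_rer: float
    baseline_frames: np.ndarray
    enhanced_frames: np.ndarray
    excluded_pixels: int
    n_partitions: int

    def __post_init__(self) -> None:
        self.per_partition_mean_rer = np.asarray(self.per_partition_mean_rer, dtype=float)
        if self.mrer < 0 or self.sd_rer < 0:
            raise ValueError("MRER and SD-RER are non-negative by construction")

    def to_dict(self) -> dict:
        return {
            "mrer": float(self.mrer),
            "per_partition_mean_rer": [float(v) for v in self.per_partition_mean_rer],
            "sd_rer": float(self.sd_rer),
            "baseline_frames": [int(i) for i in self.baseline_frames],
            "enhanced_frames": [int(i) for i in self.enhanced_frames],
            "excluded_pixels": int(self.excluded_pixels),
            "n_partitions": int(self.n_partitions),
        }


@dataclass
class GroundTruth:
    """Known truth emitted by the phantom generators, for recovery tests."""

    emphysema_label: np.ndarray | None = None
    lav_fraction_whole: float | None = None
    per_partition_lav_fraction: np.ndarray | None = None
    enhancement_amplitude: list[np.ndarray] | None = None  # per section, per pixel
    covariate_means: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# Cohort table schema

#: Canonical column -> unit mapping for the per-subject table.
COHORT_UNITS = {
    "subject_id": "",
    "group": "{COPD, control}",
    "age": "years",
    "bmi": "kg/m^2",
    "fev1": "L",
    "pct_fev1": "%",
    "fvc": "L",
    "vc": "L",
    "rv_tlc": "%",
    "dlco": "mL/min/mmHg",
    "pao2": "Torr",
    "paco2": "Torr",
    "lav_pct": "%",
    "sd_lav": "%",
    "mrer": "%",
    "sd_rer": "%",
}

COHORT_COLUMNS = tuple(COHORT_UNITS)

VALID_GROUPS = frozenset({"COPD", "control"})


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-subject cohort table against the canonical schema.

    Required: unique ``subject_id``, valid ``group`` labels. Unknown columns
    are tolerated (a warning is emitted by the reader); missing canonical
    columns are allowed since stages fill them in incrementally.
    """
    if "subject_id" not in table.columns or "group" not in table.columns:
        raise ValueError("cohort table requires 'subject_id' and 'group' columns")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids: {dupes}")
    bad = set(table["group"]) - VALID_GROUPS
    if bad:
        raise ValueError(f"invalid group labels: {sorted(bad)} (expected {sorted(VALID_GROUPS)})")
    return table
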