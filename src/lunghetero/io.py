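"""Readers and writers for volumes, OEMRI series and cohort tables.

Volumes are stored as NIfTI with companion mask files (``<stem>_lung_mask``,
``<stem>_trachea_mask``); the affine is used only for spacing and axis
orientation. Arrays are stored with index 0 = cranial; if a file's affine
indicates a flipped axis the reader reorients and logs the applied flip.

An OEMRI series is a directory: one NIfTI stack per section with the frame
axis last, one ROI mask per section, and a ``series.json`` sidecar carrying
phase labels, spacing, locations and the per-row cranial-caudal coordinates.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .datatypes import (
    COHORT_COLUMNS,
    CTVolume,
    OEMRISeries,
    Section,
    validate_cohort_table,
)

log = logging.getLogger("lunghetero")

__all__ = [
    "write_volume",
    "read_volume",
    "write_series",
    "read_series",
    "write_table",
    "read_table",
]


def _affine_from_spacing(spacing: tuple[float, ...]) -> np.ndarray:
    steps = (list(spacing) + [1.0, 1.0, 1.0])[:3]
    return np.diag(steps + [1.0])


def _save_nifti(arr: np.ndarray, spacing, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(arr), _affine_from_spacing(tuple(spacing)))
    nib.save(img, str(path))


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, ...]]:
    """Load array + spacing, reorienting flipped axes into the canonical
    convention (index 0 = cranial). Only diagonal affines are supported."""
    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64)
    aff = img.affine
    n = arr.ndim
    spacing = []
    for ax in range(min(n, 3)):
        step = float(aff[ax, ax])
        if step < 0:
            arr = np.flip(arr, axis=ax)
            step = -step
            log.info("reoriented axis %d of %s (flip applied)", ax, path.name)
        spacing.append(step)
    return np.ascontiguousarray(arr), tuple(spacing)


def _mask_paths(path: Path) -> tuple[Path, Path]:
    stem = path.name
    for suf in (".nii.gz", ".nii"):
        if stem.endswith(suf):
            stem = stem[: -len(suf)]
            ext = suf
            break
    else:
        ext = ".nii"
    return (
        path.with_name(f"{stem}_lung_mask{ext}"),
        path.with_name(f"{stem}_trachea_mask{ext}"),
    )


def write_volume(volume: CTVolume, path: str | Path) -> None:
    """Write a CT volume plus its companion lung and trachea mask files."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    _save_nifti(volume.hu, volume.spacing, path)
    lung_p, trach_p = _mask_paths(path)
    _save_nifti(volume.lung_mask.astype(np.uint8), volume.spacing, lung_p)
    _save_nifti(volume.trachea_mask.astype(np.uint8), volume.spacing, trach_p)


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume; raises if a companion mask file is missing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume file not found: {path}")
    lung_p, trach_p = _mask_paths(path)
    if not lung_p.exists():
        raise FileNotFoundError(f"lung mask required: missing {lung_p}")
    if not trach_p.exists():
        raise FileNotFoundError(f"trachea mask required: missing {trach_p}")
    hu, spacing = _load_nifti(path)
    lung, _ = _load_nifti(lung_p)
    trachea, _ = _load_nifti(trach_p)
    return CTVolume(
        hu=hu,
        spacing=spacing,
        lung_mask=lung > 0.5,
        trachea_mask=trachea > 0.5,
    )


# ---------------------------------------------------------------------------
# OEMRI series


def write_series(series: OEMRISeries, directory: str | Path) -> None:
    """Write an OEMRI series to a directory (one stack + ROI per section)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "phase_labels": [str(p) for p in series.phase_labels],
        "sections": [],
    }
    for i, sec in enumerate(series.sections):
        # frame axis last on disk: (ny, nx, t)
        stack = np.moveaxis(sec.frames, 0, -1)
        _save_nifti(stack, (*sec.pixel_spacing, 1.0), directory / f"section_{i}.nii")
        _save_nifti(
            sec.lung_roi.astype(np.uint8), sec.pixel_spacing, directory / f"section_{i}_roi.nii"
        )
        meta["sections"].append(
            {
                "location": sec.location,
                "pixel_spacing": list(sec.pixel_spacing),
                "cc_coords": [float(c) for c in sec.cc_coords],
            }
        )
    (directory / "series.json").write_text(json.dumps(meta, indent=1, sort_keys=True))


def read_series(directory: str | Path) -> OEMRISeries:
    directory = Path(directory)
    meta_path = directory / "series.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"series metadata required: missing {meta_path}")
    meta = json.loads(meta_path.read_text())
    sections = []
    for i, sec_meta in enumerate(meta["sections"]):
        stack, _ = _load_nifti(directory / f"section_{i}.nii")
        roi_path = directory / f"section_{i}_roi.nii"
        if not roi_path.exists():
            raise FileNotFoundError(f"lung ROI required: missing {roi_path}")
        roi, _ = _load_nifti(roi_path)
        sections.append(
            Section(
                frames=np.moveaxis(stack, -1, 0),
                pixel_spacing=tuple(sec_meta["pixel_spacing"]),
                cc_coords=np.asarray(sec_meta["cc_coords"], dtype=float),
                lung_roi=roi > 0.5,
                location=sec_meta["location"],
            )
        )
    return OEMRISeries(sections=sections, phase_labels=np.asarray(meta["phase_labels"], dtype=object))


# ---------------------------------------------------------------------------
# Cohort tables


def write_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as UTF-8 CSV with 15-significant-digit floats."""
    validate_cohort_table(table)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.15g")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV; unknown columns warn but pass through."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort table not found: {path}")
    table = pd.read_csv(path)
    unknown = [c for c in table.columns if c not in COHORT_COLUMNS]
    if unknown:
        warnings.warn(
            f"unknown cohort columns carried through untouched: {unknown}", stacklevel=2
        )
    return validate_cohort_table(table)
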