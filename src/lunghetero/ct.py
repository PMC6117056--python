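"""CT emphysema densitometry and its cranial-caudal heterogeneity index.

The analysis chain mirrors standard quantitative-CT practice for emphysema:

1. HU calibration against tracheal air (the scanner-independent reference:
   pure air should read -1000 HU);
2. low attenuation volume (LAV) thresholding at < -960 HU;
3. isovolumetric cranial-caudal partitioning of the lung into 12 parts,
   with the top and bottom parts excluded for partial-volume effects;
4. LAV% per kept partition and the sample SD of those 10 values (SD-LAV),
   the heterogeneity index: higher SD-LAV = more heterogeneous emphysema.

Whole-lung LAV% is computed over the entire lung (all 12 partitions);
only the SD uses the 10 kept partitions.
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import CTVolume, LavResult, PartitionScheme

__all__ = [
    "calibrate_hu",
    "lav_mask",
    "partition_isovolumetric",
    "lav_percent_per_partition",
    "sd_lav",
    "equal_count_quotas",
    "analyze_volume",
    "DEFAULT_LAV_THRESHOLD_HU",
]

#: Emphysema cut-off: lung voxels strictly below this HU count as LAV.
DEFAULT_LAV_THRESHOLD_HU = -960.0

TRACHEAL_AIR_HU = -1000.0


def calibrate_hu(volume: CTVolume) -> CTVolume:
    """Shift HU so the mean tracheal-air value equals -1000 HU.

    The calibration is a constant additive shift (the minimal adjustment
    that preserves threshold semantics); the applied shift is recorded on
    the returned volume. A shift beyond 100 HU in magnitude suggests a bad
    trachea mask and triggers a warning.
    """
    if not volume.trachea_mask.any():
        raise ValueError("trachea mask is empty; cannot calibrate")
    tracheal_mean = float(volume.hu[volume.trachea_mask].mean())
    shift = TRACHEAL_AIR_HU - tracheal_mean
    if abs(shift) > 100.0:
        warnings.warn(
            f"calibration shift {shift:+.1f} HU exceeds 100 HU; trachea mask suspect",
            stacklevel=2,
        )
    return volume.shifted(shift, calibration_shift=shift)


def lav_mask(volume: CTVolume, threshold_hu: float = DEFAULT_LAV_THRESHOLD_HU) -> np.ndarray:
    """Boolean mask of lung voxels strictly below the LAV threshold.

    The inequality is strict: a voxel at exactly the threshold is not LAV.
    Voxels outside the lung mask are never counted.
    """
    return volume.lung_mask & (volume.hu < threshold_hu)


def equal_count_quotas(total: int, n: int) -> np.ndarray:
    """Partition ``total`` items into ``n`` ordered quotas, remainder going
    to the earliest partitions (counts differ by at most one)."""
    base, rem = divmod(total, n)
    quotas = np.full(n, base, dtype=np.int64)
    quotas[:rem] += 1
    return quotas


def partition_isovolumetric(
    volume: CTVolume, n: int = 12, exclude_ends: bool = True
) -> PartitionScheme:
    """Assign lung voxels to ``n`` equal-volume cranial-caudal partitions.

    Lung voxels are ordered by slice (cranial first) and row-major within a
    slice; the ordered list is cut into ``n`` equal-count runs (quota
    remainder to the earliest partitions), so voxels of a boundary slice
    fill the earlier partition's quota before spilling into the next. With
    uniform z-spacing equal voxel count is equal physical volume. Partitions
    0 and n-1 are dropped from ``kept`` when ``exclude_ends`` is set.
    """
    if exclude_ends and n < 3:
        raise ValueError("exclude_ends with n < 3 leaves no kept partitions")
    total = volume.lung_voxel_count
    if total < n:
        raise ValueError(f"lung voxel count {total} < requested partitions {n}")
    lung_slices = np.flatnonzero(volume.lung_mask.any(axis=(1, 2)))
    if len(lung_slices) < n:
        raise ValueError(
            f"degenerate volume: only {len(lung_slices)} slices contain lung, need >= {n}"
        )
    # np.argwhere on a C-ordered mask yields (z, y, x) sorted lexicographically:
    # exactly the cranial-then-row-major order the assignment rule requires.
    coords = np.argwhere(volume.lung_mask)
    quotas = equal_count_quotas(total, n)
    labels = np.repeat(np.arange(n), quotas)
    assignment = np.full(volume.shape, -1, dtype=np.int64)
    assignment[tuple(coords.T)] = labels
    kept = tuple(range(1, n - 1)) if exclude_ends else tuple(range(n))
    return PartitionScheme(n_total=n, kept=kept, assignment=assignment, counts=quotas)


def lav_percent_per_partition(mask: np.ndarray, scheme: PartitionScheme) -> np.ndarray:
    """LAV% of every partition (cranial -> caudal): 100 * LAV voxels / voxels."""
    if mask.shape != scheme.assignment.shape:
        raise ValueError("mask and partition scheme come from different volumes")
    if np.any(scheme.counts == 0):
        raise ValueError("empty partition encountered")
    lav_counts = np.bincount(
        scheme.assignment[mask & (scheme.assignment >= 0)], minlength=scheme.n_total
    )
    return 100.0 * lav_counts / scheme.counts


def sd_lav(values: np.ndarray, ddof: int = 1) -> float:
    """Sample SD (n-1 denominator by default) of per-partition LAV% values."""
    values = np.asarray(values, dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two partition values for an SD")
    return float(np.std(values, ddof=ddof))


def analyze_volume(
    volume: CTVolume,
    threshold_hu: float = DEFAULT_LAV_THRESHOLD_HU,
    n_partitions: int = 12,
    exclude_ends: bool = True,
    calibrate: bool = True,
    ddof: int = 1,
) -> LavResult:
    """Full densitometry chain: calibrate, threshold, partition, summarise."""
    if calibrate:
        volume = calibrate_hu(volume)
    shift = volume.calibration_shift or 0.0
    mask = lav_mask(volume, threshold_hu)
    scheme = partition_isovolumetric(volume, n_partitions, exclude_ends)
    all_pct = lav_percent_per_partition(mask, scheme)
    kept_pct = all_pct[list(scheme.kept)]
    whole = 100.0 * float(mask.sum()) / volume.lung_voxel_count
    return LavResult(
        lav_percent_whole=whole,
        per_partition_lav_percent=kept_pct,
        all_partition_lav_percent=all_pct,
        sd_lav=sd_lav(kept_pct, ddof=ddof),
        threshold_hu=threshold_hu,
        calibration_shift=shift,
        n_partitions=n_partitions,
        kept=scheme.kept,
    )
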