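"""Oxygen-enhanced MRI oxygen-uptake mapping: RER, MRER, SD-RER.

The relative enhancement ratio (RER) of a pixel is the percent change of
signal intensity between the oxygen-enhanced and room-air baseline states,

    RER = 100 * |SI_enhanced - SI_baseline| / |SI_baseline|,

an index of regional oxygen uptake. SI_baseline and SI_enhanced are means
over steady-state windows (the tail of the first room-air phase and of the
oxygen phase respectively). MRER is the mean RER over lung-parenchyma ROI
pixels pooled across all coronal sections; SD-RER is the sample SD of the
mean RER in 10 equal-count cranial-caudal partitions of the pooled pixels,
the oxygen-uptake heterogeneity index.
"""

from __future__ import annotations

import math

import numpy as np

from .ct import equal_count_quotas
from .datatypes import OEMRISeries, RerResult

__all__ = [
    "select_phase_windows",
    "rer_map",
    "mrer",
    "sd_rer",
    "analyze_series",
]


def select_phase_windows(
    series: OEMRISeries, window_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices of the baseline and enhanced steady-state windows.

    Baseline = last ceil(f * n_air1) frames of the first room-air phase;
    enhanced = last ceil(f * n_O2) frames of the oxygen phase. Using the
    phase tails avoids the wash-in transient.
    """
    if not 0.0 < window_fraction <= 1.0:
        raise ValueError("window_fraction must lie in (0, 1]")
    air1 = series.phase_frames("air1")
    o2 = series.phase_frames("O2")
    n_base = math.ceil(window_fraction * len(air1))
    n_enh = math.ceil(window_fraction * len(o2))
    if n_base == 0 or n_enh == 0:
        raise ValueError("phase too short: empty steady-state window")
    return air1[-n_base:], o2[-n_enh:]


def rer_map(
    baseline_mean: np.ndarray,
    enhanced_mean: np.ndarray,
    roi: np.ndarray,
    floor: float,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-pixel RER map over the ROI.

    Pixels whose baseline magnitude falls below ``floor`` are excluded from
    the effective ROI (division guard) and counted. Returns
    ``(map, effective_roi, n_excluded)``; the map is NaN outside the
    effective ROI. The absolute value in the formula makes signal drops
    positive: RER measures change magnitude, not direction.
    """
    baseline_mean = np.asarray(baseline_mean, dtype=float)
    enhanced_mean = np.asarray(enhanced_mean, dtype=float)
    roi = np.asarray(roi, dtype=bool)
    if baseline_mean.shape != enhanced_mean.shape or baseline_mean.shape != roi.shape:
        raise ValueError("baseline, enhanced and ROI images must be congruent")
    if floor <= 0:
        raise ValueError("floor must be positive")
    effective = roi & (np.abs(baseline_mean) >= floor)
    n_excluded = int(roi.sum() - effective.sum())
    if not effective.any():
        raise ValueError("all ROI pixels below the baseline floor")
    out = np.full(baseline_mean.shape, np.nan)
    out[effective] = (
        100.0
        * np.abs(enhanced_mean[effective] - baseline_mean[effective])
        / np.abs(baseline_mean[effective])
    )
    return out, effective, n_excluded


def _pooled_pixels(
    maps: list[np.ndarray], rois: list[np.ndarray], cc_coords: list[np.ndarray] | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Pool ROI pixel values (and optionally their cranial-caudal coordinates)
    across sections in a deterministic order: section, then row-major."""
    vals, ccs = [], []
    for i, (m, roi) in enumerate(zip(maps, rois)):
        roi = np.asarray(roi, dtype=bool)
        vals.append(np.asarray(m, dtype=float)[roi])
        if cc_coords is not None:
            rows = np.nonzero(roi)[0]
            ccs.append(np.asarray(cc_coords[i], dtype=float)[rows])
    values = np.concatenate(vals) if vals else np.empty(0)
    coords = np.concatenate(ccs) if cc_coords is not None else None
    return values, coords


def mrer(maps: list[np.ndarray], rois: list[np.ndarray]) -> float:
    """Mean RER over pooled ROI pixels of all sections (pixel-weighted, so
    larger sections contribute proportionally)."""
    values, _ = _pooled_pixels(maps, rois)
    if values.size == 0:
        raise ValueError("pooled ROI is empty")
    return float(values.mean())


def sd_rer(
    maps: list[np.ndarray],
    rois: list[np.ndarray],
    cc_coords: list[np.ndarray],
    n: int = 10,
    exclude_ends: bool = False,
    ddof: int = 1,
) -> tuple[float, np.ndarray]:
    """Cranial-caudal heterogeneity of oxygen uptake.

    Pooled ROI pixels of all sections are ordered by their physical
    cranial-caudal coordinate (ties broken by pooling order, which is
    deterministic) and cut into ``n`` equal-count partitions using the same
    quota rule as the CT chain; SD-RER is the sample SD of the ``n``
    per-partition mean RERs. Unlike the CT scheme, no end partitions are
    excluded by default; ``exclude_ends`` mimics the CT 12-minus-2 scheme
    for sensitivity analysis.

    Returns ``(sd_rer, per_partition_means)`` with means cranial -> caudal
    (kept partitions only when ends are excluded).
    """
    values, coords = _pooled_pixels(maps, rois, cc_coords)
    if values.size < n:
        raise ValueError(f"pooled ROI has {values.size} pixels; need >= {n} partitions")
    order = np.argsort(coords, kind="stable")
    ordered = values[order]
    quotas = equal_count_quotas(ordered.size, n)
    edges = np.concatenate(([0], np.cumsum(quotas)))
    means = np.array([ordered[edges[k] : edges[k + 1]].mean() for k in range(n)])
    if exclude_ends:
        if n < 3:
            raise ValueError("exclude_ends with n < 3 leaves no kept partitions")
        means = means[1:-1]
    return float(np.std(means, ddof=ddof)), means


def analyze_series(
    series: OEMRISeries,
    window_fraction: float = 0.5,
    n_partitions: int = 10,
    floor_fraction: float = 0.05,
    exclude_ends: bool = False,
    ddof: int = 1,
) -> RerResult:
    """Full OEMRI chain: window selection, per-section RER maps, MRER, SD-RER.

    ``floor_fraction`` sets the low-baseline exclusion floor as a fraction of
    the ROI median baseline signal of each section.
    """
    base_idx, enh_idx = select_phase_windows(series, window_fraction)
    maps, eff_rois, cc = [], [], []
    excluded = 0
    for sec in series.sections:
        baseline_mean = sec.frames[base_idx].mean(axis=0)
        enhanced_mean = sec.frames[enh_idx].mean(axis=0)
        floor = floor_fraction * float(np.median(np.abs(baseline_mean[sec.lung_roi])))
        floor = max(floor, np.finfo(float).tiny)
        m, eff, n_exc = rer_map(baseline_mean, enhanced_mean, sec.lung_roi, floor)
        maps.append(m)
        eff_rois.append(eff)
        cc.append(sec.cc_coords)
        excluded += n_exc
    sd, part_means = sd_rer(
        maps, eff_rois, cc, n=n_partitions, exclude_ends=exclude_ends, ddof=ddof
    )
    return RerResult(
        rer_maps=maps,
        mrer=mrer(maps, eff_rois),
        per_partition_mean_rer=part_means,
        sd_rer=sd,
        baseline_frames=base_idx,
        enhanced_frames=enh_idx,
        excluded_pixels=excluded,
        n_partitions=n_partitions,
    )
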