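"""CT densitometry: calibration, thresholding, partitioning, SD-LAV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lunghetero.ct import (
    analyze_volume,
    calibrate_hu,
    equal_count_quotas,
    lav_mask,
    lav_percent_per_partition,
    partition_isovolumetric,
    sd_lav,
)
from lunghetero.datatypes import CTVolume


def test_calibration_shifts_tracheal_mean_to_minus_1000(tiny_volume):
    vol = tiny_volume
    vol.hu[vol.trachea_mask] = -990.0  # miscalibrated air
    cal = calibrate_hu(vol)
    assert cal.calibration_shift == pytest.approx(-10.0)
    assert cal.hu[cal.trachea_mask].mean() == pytest.approx(-1000.0)
    # a voxel at -950 becomes -960
    assert cal.hu[vol.hu == -950.0].size == 0  # none in this phantom; check arithmetic directly
    assert -950.0 + cal.calibration_shift == pytest.approx(-960.0)


def test_calibration_is_identity_at_exact_air(tiny_volume):
    cal = calibrate_hu(tiny_volume)
    assert cal.calibration_shift == pytest.approx(0.0)
    np.testing.assert_allclose(cal.hu, tiny_volume.hu)


def test_calibration_warns_on_large_shift(tiny_volume):
    tiny_volume.hu[tiny_volume.trachea_mask] = -850.0
    with pytest.warns(UserWarning, match="trachea mask suspect"):
        calibrate_hu(tiny_volume)


def test_empty_trachea_mask_is_an_error(tiny_volume):
    vol = CTVolume(
        hu=tiny_volume.hu,
        spacing=tiny_volume.spacing,
        lung_mask=tiny_volume.lung_mask,
        trachea_mask=np.zeros_like(tiny_volume.trachea_mask),
    )
    with pytest.raises(ValueError, match="trachea mask is empty"):
        calibrate_hu(vol)


def test_lav_threshold_is_strict(tiny_volume):
    vol = tiny_volume
    lung_idx = np.argwhere(vol.lung_mask)
    z0, y0, x0 = lung_idx[0]
    z1, y1, x1 = lung_idx[1]
    vol.hu[z0, y0, x0] = -960.0  # exactly at threshold: not LAV
    vol.hu[z1, y1, x1] = -960.5  # below: LAV
    vol.hu[0, 0, 1] = -1000.0  # outside the lung: never counted
    mask = lav_mask(vol)
    assert not mask[z0, y0, x0]
    assert mask[z1, y1, x1]
    assert not mask[0, 0, 1]


def test_exact_divisibility_gives_equal_partitions(tiny_volume):
    # 16 slices x 4 lung voxels = 64 voxels; n=4 -> 16 voxels / 4 slices each
    scheme = partition_isovolumetric(tiny_volume, n=4, exclude_ends=True)
    np.testing.assert_array_equal(scheme.counts, [16, 16, 16, 16])
    assert scheme.kept == (1, 2)
    for k in range(4):
        zs = np.unique(np.argwhere(scheme.assignment == k)[:, 0])
        np.testing.assert_array_equal(zs, np.arange(4 * k, 4 * k + 4))


def test_quota_remainder_goes_to_earliest_partitions():
    np.testing.assert_array_equal(
        equal_count_quotas(1201, 12), [101] + [100] * 11
    )
    np.testing.assert_array_equal(equal_count_quotas(1200, 12), [100] * 12)


def test_partition_counts_differ_by_at_most_one(small_phantom):
    vol, _ = small_phantom
    scheme = partition_isovolumetric(vol, n=12)
    assert scheme.counts.max() - scheme.counts.min() <= 1
    assert scheme.counts.sum() == vol.lung_voxel_count


def test_partitioning_matches_naive_per_voxel_loop(small_phantom):
    """Oracle: re-derive every voxel's partition by walking lung voxels in
    cranial-then-row-major order and filling quotas one by one."""
    vol, _ = small_phantom
    n = 12
    scheme = partition_isovolumetric(vol, n=n, exclude_ends=True)
    quotas = list(equal_count_quotas(vol.lung_voxel_count, n))
    expected = np.full(vol.shape, -1, dtype=int)
    part, filled = 0, 0
    nz, ny, nx = vol.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not vol.lung_mask[z, y, x]:
                    continue
                if filled == quotas[part]:
                    part += 1
                    filled = 0
                expected[z, y, x] = part
                filled += 1
    np.testing.assert_array_equal(scheme.assignment, expected)


def test_lav_percent_conservation(small_phantom):
    vol, _ = small_phantom
    cal = calibrate_hu(vol)
    mask = lav_mask(cal)
    scheme = partition_isovolumetric(cal, n=12)
    per = lav_percent_per_partition(mask, scheme)
    # per-partition LAV voxel counts sum to the whole-lung LAV count
    counts = per / 100.0 * scheme.counts
    assert int(round(counts.sum())) == int(mask.sum())
    # whole-lung LAV% equals the voxel-count-weighted mean of all partitions
    whole = 100.0 * mask.sum() / vol.lung_voxel_count
    weighted = float(np.average(per, weights=scheme.counts))
    assert abs(whole - weighted) < 1e-9


def test_n_below_3_with_exclusion_rejected(tiny_volume):
    with pytest.raises(ValueError, match="no kept partitions"):
        partition_isovolumetric(tiny_volume, n=2, exclude_ends=True)


def test_sd_lav_hand_values():
    assert sd_lav(np.full(10, 10.0)) == 0.0
    values = np.array([0.0] * 5 + [20.0] * 5)
    assert sd_lav(values) == pytest.approx(np.sqrt(1000.0 / 9.0), abs=1e-9)
    assert sd_lav(values) == pytest.approx(10.540925533894598, abs=1e-9)


def test_calibration_shift_invariance(noiseless_ct_config):
    """Adding any constant HU offset leaves the calibrated result identical."""
    from dataclasses import replace

    from lunghetero.synth import generate_ct_phantom

    import warnings as _warnings

    ref = analyze_volume(generate_ct_phantom(noiseless_ct_config)[0])
    for offset in (-50.0, 15.0, 100.0):
        vol, _ = generate_ct_phantom(replace(noiseless_ct_config, global_hu_offset=offset))
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # near-100 HU shifts may warn
            res = analyze_volume(vol)
        assert res.lav_percent_whole == ref.lav_percent_whole
        np.testing.assert_array_equal(
            res.all_partition_lav_percent, ref.all_partition_lav_percent
        )
        assert res.sd_lav == ref.sd_lav


def test_noiseless_recovery_of_target_fraction(noiseless_ct_phantom):
    vol, _ = noiseless_ct_phantom
    res = analyze_volume(vol)
    assert res.lav_percent_whole == pytest.approx(30.0, abs=0.5)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(total=st.integers(12, 5000), n=st.integers(2, 12))
def test_quota_invariants(total, n):
    q = equal_count_quotas(total, n)
    assert q.sum() == total
    assert q.max() - q.min() <= 1
    assert np.all(np.diff(q) <= 0)  # remainder at the front
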