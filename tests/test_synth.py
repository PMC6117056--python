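"""Determinism, ground-truth consistency and cohort structure of the generators."""

from dataclasses import replace

import numpy as np
import pytest

from lunghetero.config import CohortConfig, CTPhantomConfig, OEMRIPhantomConfig
from lunghetero.datatypes import GroundTruth
from lunghetero.stats import correlate
from lunghetero.synth import (
    generate_cohort,
    generate_ct_phantom,
    generate_oemri_phantom,
    washin_weights,
)


def test_zero_target_places_no_emphysema():
    cfg = CTPhantomConfig(lav_fraction_target=0.0, gradient_strength=0.5, seed=1)
    _, gt = generate_ct_phantom(cfg)
    assert gt.emphysema_label.sum() == 0
    assert gt.lav_fraction_whole == 0.0


def test_same_seed_reproduces_different_seed_differs():
    cfg = CTPhantomConfig(lav_fraction_target=0.2, seed=7)
    v1, g1 = generate_ct_phantom(cfg)
    v2, g2 = generate_ct_phantom(cfg)
    np.testing.assert_array_equal(v1.hu, v2.hu)
    np.testing.assert_array_equal(g1.emphysema_label, g2.emphysema_label)
    v3, g3 = generate_ct_phantom(replace(cfg, seed=8))
    assert not np.array_equal(g1.emphysema_label, g3.emphysema_label)


def test_ground_truth_fraction_is_a_recount(small_phantom):
    vol, gt = small_phantom
    labelled_in_lung = int((gt.emphysema_label & vol.lung_mask).sum())
    assert gt.lav_fraction_whole == labelled_in_lung / vol.lung_voxel_count
    # every labelled voxel lies inside the lung
    assert not np.any(gt.emphysema_label & ~vol.lung_mask)


def test_target_fraction_hit_within_half_point(small_phantom):
    _, gt = small_phantom
    assert abs(gt.lav_fraction_whole - 0.2) <= 0.005


def test_noiseless_threshold_mask_equals_label(noiseless_ct_phantom):
    vol, gt = noiseless_ct_phantom
    from lunghetero.ct import lav_mask

    np.testing.assert_array_equal(lav_mask(vol), gt.emphysema_label)


def test_degenerate_grid_rejected():
    cfg = CTPhantomConfig(grid_shape=(10, 24, 24), seed=0)
    with pytest.raises(ValueError, match="degenerate grid"):
        generate_ct_phantom(cfg)


def test_unreachable_target_raises_diagnostic():
    # gradient 1.0 zeroes the sampling density on the most cranial lung slice;
    # single-voxel clusters can then never label it, so a 100% target stalls
    cfg = CTPhantomConfig(
        grid_shape=(20, 16, 16),
        lav_fraction_target=1.0,
        gradient_strength=1.0,
        cluster_radius_mm=1.0,
        voxel_spacing=(8.0, 8.0, 8.0),
        seed=0,
    )
    with pytest.raises(RuntimeError, match="unreachable target fraction"):
        generate_ct_phantom(cfg)


def test_oemri_determinism_and_phase_structure():
    cfg = OEMRIPhantomConfig(frame_shape=(16, 12), frames_per_phase=5, noise_sd=1.0, seed=4)
    s1 = generate_oemri_phantom(cfg, GroundTruth())
    s2 = generate_oemri_phantom(cfg, GroundTruth())
    for a, b in zip(s1.sections, s2.sections):
        np.testing.assert_array_equal(a.frames, b.frames)
    assert list(s1.phase_labels) == ["air1"] * 5 + ["O2"] * 5 + ["air2"] * 5
    assert len(s1.sections) == 3


def test_washin_curve_shape():
    labels = np.array(["air1"] * 4 + ["O2"] * 4 + ["air2"] * 4, dtype=object)
    w = washin_weights(labels, tau=2.0)
    np.testing.assert_array_equal(w[:4], 0.0)
    np.testing.assert_allclose(w[4:8], 1.0 - np.exp(-np.arange(1, 5) / 2.0))
    np.testing.assert_allclose(w[8:], w[7] * np.exp(-np.arange(1, 5) / 2.0))
    assert np.all(np.diff(w[4:8]) > 0)  # monotone wash-in


def test_amplitude_reduced_in_emphysema_dense_rows():
    gt_hi = GroundTruth(per_partition_lav_fraction=np.full(12, 0.5))
    gt_lo = GroundTruth(per_partition_lav_fraction=np.zeros(12))
    cfg = OEMRIPhantomConfig(frame_shape=(16, 12), frames_per_phase=3, noise_sd=0.0, seed=0)
    hi = generate_oemri_phantom(cfg, gt_hi)
    lo = generate_oemri_phantom(cfg, gt_lo)
    assert gt_hi.enhancement_amplitude[0].max() < gt_lo.enhancement_amplitude[0].max()
    # enhanced-phase signal is depressed accordingly
    assert hi.sections[0].frames[-4].sum() < lo.sections[0].frames[-4].sum()


def test_cohort_noise_free_covariates_equal_linear_predictors():
    cfg = CohortConfig(
        n_copd=5,
        n_control=3,
        copd_lav_sd=0.0,
        control_lav_sd=0.0,
        copd_gradient_range=(0.4, 0.4),
        control_gradient_range=(0.0, 0.0),
        fev1_noise_sd=0.0,
        dlco_noise_sd=0.0,
        pao2_noise_sd=0.0,
        seed=2,
    )
    table, _, ground = generate_cohort(cfg)
    copd = table[table.group == "COPD"]
    f, g = cfg.copd_lav_mean, 0.4
    np.testing.assert_allclose(copd.fev1, cfg.fev1_base + cfg.fev1_slope * f)
    np.testing.assert_allclose(copd.dlco, cfg.dlco_base + cfg.dlco_slope * f)
    np.testing.assert_allclose(copd.pao2, cfg.pao2_base + cfg.pao2_slope * f * g)


def test_cohort_structure_mirrors_default_design():
    table, specs, _ = generate_cohort(CohortConfig(seed=0))
    assert (table.group == "COPD").sum() == 40
    assert (table.group == "control").sum() == 9
    assert len(specs) == 49
    copd, ctrl = table[table.group == "COPD"], table[table.group == "control"]
    assert copd.lav_pct.mean() > ctrl.lav_pct.mean()
    assert copd.mrer.mean() < ctrl.mrer.mean()


def test_negative_link_forces_negative_lav_dlco_correlation():
    table, _, _ = generate_cohort(CohortConfig(seed=11))
    res = correlate(table[table.group == "COPD"], "lav_pct", "dlco")
    assert res.r < 0


def test_subject_specs_realise_truth():
    cfg = CohortConfig(n_copd=3, n_control=2, seed=5)
    _, specs, _ = generate_cohort(cfg)
    for s in specs:
        assert s.ct_config.lav_fraction_target == s.true_lav_fraction
        assert s.oemri_config.enhancement_amplitude_mean == s.true_amplitude
        assert 0 <= s.ct_config.seed < 2**31
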