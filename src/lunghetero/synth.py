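"""Synthetic phantoms and cohorts with known ground truth.

Three generators drive every downstream stage without any external data:

* :func:`generate_ct_phantom` — an ellipsoid-pair lung with a cylindrical
  trachea, emphysema placed as spherical low-attenuation clusters whose
  cranial-caudal placement density is tilted by a single gradient parameter;
* :func:`generate_oemri_phantom` — coronal signal-intensity time series
  following an exponential oxygen wash-in, with regional amplitude
  modulation tied to the CT ground truth;
* :func:`generate_cohort` — a study population (default 40 COPD / 9
  controls) whose clinical covariates are generated from the imaging ground
  truth through stated linear links plus Gaussian noise.

All randomness flows from one seeded generator per call; identical
(config, seed) reproduces bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .config import CohortConfig, CTPhantomConfig, OEMRIPhantomConfig
from .ct import lav_percent_per_partition, partition_isovolumetric
from .datatypes import PHASES, CTVolume, GroundTruth, OEMRISeries, Section

log = logging.getLogger("lunghetero")

__all__ = [
    "generate_ct_phantom",
    "generate_oemri_phantom",
    "generate_cohort",
    "washin_weights",
    "SubjectSpec",
    "PARTITION_RAMP",
]

SECTION_LOCATIONS = ("anterior", "central", "posterior")

#: Centred cranial-caudal ramp over k partitions: -1+1/k ... 1-1/k.
def _ramp(k: int) -> np.ndarray:
    return (2.0 * np.arange(k) + 1.0) / k - 1.0


PARTITION_RAMP = _ramp(10)


# ---------------------------------------------------------------------------
# CT phantom


def _lung_and_trachea(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Ellipsoid-pair lung mask plus a cylindrical trachea of the grid."""
    nz, ny, nx = shape
    z, y, x = np.indices(shape, dtype=float)
    lung = np.zeros(shape, dtype=bool)
    az, ay, ax = 0.44 * nz, 0.38 * ny, 0.21 * nx
    for cx in (0.29 * nx, 0.71 * nx):
        r2 = (
            ((z - 0.5 * nz) / az) ** 2
            + ((y - 0.5 * ny) / ay) ** 2
            + ((x - cx) / ax) ** 2
        )
        lung |= r2 <= 1.0
    # trachea: cylinder down the midline, upper half of the grid
    rad = max(1.2, 0.05 * nx)
    trachea = (
        ((y - 0.45 * ny) ** 2 + (x - 0.5 * nx) ** 2 <= rad**2)
        & (z >= 0.06 * nz)
        & (z <= 0.52 * nz)
    )
    # keep the masks disjoint with a one-voxel moat around the airway
    lung &= ~ndimage.binary_dilation(trachea, iterations=1)
    return lung, trachea


def generate_ct_phantom(config: CTPhantomConfig) -> tuple[CTVolume, GroundTruth]:
    """Generate a CT phantom and its voxel-level ground truth.

    Cluster centres are sampled from a cranial-caudal density proportional
    to ``max(0, 1 + gradient * ramp(z))`` (inverse-CDF sampling, so the same
    seed yields comparable layouts across gradient values); clusters overlap
    freely (union counted once) and placement stops when the labelled
    fraction of lung voxels is within 0.5 percentage points of target — the
    final cluster is trimmed (nearest voxels first) to land on the target
    exactly.
    """
    rng = np.random.default_rng(config.seed)
    lung, trachea = _lung_and_trachea(config.grid_shape)
    lung_slices = np.flatnonzero(lung.any(axis=(1, 2)))
    if len(lung_slices) < 12:
        raise ValueError(
            f"degenerate grid: only {len(lung_slices)} slices contain lung (need >= 12)"
        )
    lung_n = int(lung.sum())

    label = np.zeros(config.grid_shape, dtype=bool)
    target_n = int(round(config.lav_fraction_target * lung_n))
    if target_n > 0:
        _place_clusters(rng, config, lung, lung_slices, label, target_n)

    sz, sy, sx = config.voxel_spacing
    hu = np.full(config.grid_shape, 40.0)  # soft-tissue background
    parenchyma = lung & ~label
    hu[parenchyma] = config.parenchyma_hu_mean + config.parenchyma_hu_sd * rng.standard_normal(
        int(parenchyma.sum())
    )
    hu[label] = config.emphysema_hu_mean + config.emphysema_hu_sd * rng.standard_normal(
        int(label.sum())
    )
    hu[trachea] = -1000.0 + 2.0 * rng.standard_normal(int(trachea.sum()))
    hu += config.global_hu_offset

    volume = CTVolume(hu=hu, spacing=config.voxel_spacing, lung_mask=lung, trachea_mask=trachea)
    scheme = partition_isovolumetric(volume, n=12, exclude_ends=True)
    per_part = lav_percent_per_partition(label, scheme) / 100.0
    ground = GroundTruth(
        emphysema_label=label,
        lav_fraction_whole=float(label[lung].sum()) / lung_n,
        per_partition_lav_fraction=per_part,
    )
    return volume, ground


def _place_clusters(rng, config, lung, lung_slices, label, target_n) -> None:
    """Rejection-free cluster placement until the labelled count hits target."""
    sz, sy, sx = config.voxel_spacing
    r = config.cluster_radius_mm
    dz = int(r // sz)
    dy = int(r // sy)
    dx = int(r // sx)
    oz, oy, ox = np.mgrid[-dz : dz + 1, -dy : dy + 1, -dx : dx + 1]
    inside = (oz * sz) ** 2 + (oy * sy) ** 2 + (ox * sx) ** 2 <= r**2
    offsets = np.stack([oz[inside], oy[inside], ox[inside]], axis=1)  # includes (0,0,0)

    # slice-level sampling density: lung cross-section x clipped linear tilt
    zmin, zmax = lung_slices[0], lung_slices[-1]
    span = max(zmax - zmin, 1)
    tilt = 1.0 + config.gradient_strength * (2.0 * (lung_slices - zmin) / span - 1.0)
    weights = np.clip(tilt, 0.0, None) * lung.sum(axis=(1, 2))[lung_slices]
    if weights.sum() <= 0:
        raise RuntimeError("cluster-centre density is zero everywhere; check gradient")
    cdf = np.cumsum(weights) / weights.sum()
    in_slice = {int(zi): np.argwhere(lung[zi]) for zi in lung_slices}

    shape = np.array(label.shape)
    current = 0
    stale = 0
    max_stale = 2000
    while current < target_n:
        zi = int(lung_slices[np.searchsorted(cdf, rng.uniform())])
        yx = in_slice[zi]
        cy, cx = yx[int(rng.uniform() * len(yx)) % len(yx)]
        pts = offsets + np.array([zi, cy, cx])
        ok = np.all((pts >= 0) & (pts < shape), axis=1)
        pts = pts[ok]
        zz, yy, xx = pts.T
        fresh = lung[zz, yy, xx] & ~label[zz, yy, xx]
        if not fresh.any():
            stale += 1
            if stale > max_stale:
                raise RuntimeError(
                    f"unreachable target fraction {config.lav_fraction_target}: "
                    f"{max_stale} consecutive clusters added no new lung voxels "
                    f"(cluster radius {config.cluster_radius_mm} mm, "
                    f"labelled {current}/{target_n})"
                )
            continue
        stale = 0
        pts = pts[fresh]
        need = target_n - current
        if len(pts) > need:
            # trim the final cluster: keep the voxels nearest the centre
            d2 = np.sum(
                ((pts - [zi, cy, cx]) * [sz, sy, sx]) ** 2, axis=1
            )
            pts = pts[np.argsort(d2, kind="stable")[:need]]
        zz, yy, xx = pts.T
        label[zz, yy, xx] = True
        current += len(pts)


# ---------------------------------------------------------------------------
# OEMRI phantom


def washin_weights(phase_labels: np.ndarray, tau: float) -> np.ndarray:
    """Oxygen wash-in/out weight w(t) per frame.

    Zero during the first room-air phase; during oxygen frame j (1-based
    within the phase) w = 1 - exp(-j/tau); during the final room-air phase
    it decays from its end-of-oxygen value as w_end * exp(-j/tau).
    """
    phase_labels = np.asarray(phase_labels, dtype=object)
    w = np.zeros(len(phase_labels))
    o2 = np.flatnonzero(phase_labels == "O2")
    air2 = np.flatnonzero(phase_labels == "air2")
    j = np.arange(1, len(o2) + 1)
    w[o2] = 1.0 - np.exp(-j / tau)
    w_end = w[o2[-1]] if len(o2) else 0.0
    k = np.arange(1, len(air2) + 1)
    w[air2] = w_end * np.exp(-k / tau)
    return w


def _coronal_roi(shape: tuple[int, int]) -> np.ndarray:
    ny, nx = shape
    y, x = np.indices(shape, dtype=float)
    roi = np.zeros(shape, dtype=bool)
    ay, ax = 0.42 * ny, 0.20 * nx
    for cx in (0.29 * nx, 0.71 * nx):
        roi |= ((y - 0.5 * ny) / ay) ** 2 + ((x - cx) / ax) ** 2 <= 1.0
    return roi


def _amplitude_field(
    config: OEMRIPhantomConfig, roi: np.ndarray, ground: GroundTruth | None
) -> np.ndarray:
    """Per-pixel true enhancement amplitude: mean level, cranial-caudal tilt,
    and reduction inside emphysema-dense regions (from the CT ground truth's
    per-partition fractions mapped onto the ROI row extent)."""
    ny, nx = roi.shape
    rows = np.nonzero(roi.any(axis=1))[0]
    r0, r1 = rows[0], max(rows[-1], rows[0] + 1)
    r = np.arange(ny, dtype=float)
    u = np.clip((r - r0) / (r1 - r0), 0.0, 1.0)
    tilt = 1.0 + config.enhancement_gradient * (2.0 * u - 1.0)
    local_f = np.zeros(ny)
    if ground is not None and ground.per_partition_lav_fraction is not None:
        parts = np.asarray(ground.per_partition_lav_fraction, dtype=float)
        idx = np.minimum((u * len(parts)).astype(int), len(parts) - 1)
        local_f = parts[idx]
    a_row = config.enhancement_amplitude_mean * tilt * (
        1.0 - config.emphysema_coupling * local_f
    )
    a = np.clip(np.repeat(a_row[:, None], nx, axis=1), 0.0, None)
    a[~roi] = 0.0
    return a


def generate_oemri_phantom(
    config: OEMRIPhantomConfig, ground: GroundTruth | None = None
) -> OEMRISeries:
    """Generate a multi-section OEMRI series.

    Per-pixel signal S(t) = baseline * (1 + a * w(t)) + N(0, noise_sd), with
    the pixel amplitude field from :func:`_amplitude_field`. Negative noisy
    signals are clipped at zero with a logged count. The true amplitude
    fields are recorded on ``ground.enhancement_amplitude`` when a ground
    truth object is supplied.
    """
    rng = np.random.default_rng(config.seed)
    m = config.frames_per_phase
    phase_labels = np.asarray(
        ["air1"] * m + ["O2"] * m + ["air2"] * m, dtype=object
    )
    w = washin_weights(phase_labels, config.washin_time_constant)
    roi = _coronal_roi(config.frame_shape)
    cc = np.arange(config.frame_shape[0], dtype=float) * config.pixel_spacing[0]

    sections = []
    amplitudes = []
    clipped_total = 0
    for s in range(config.section_count):
        a = _amplitude_field(config, roi, ground)
        amplitudes.append(a)
        frames = config.baseline_signal * (1.0 + a[None] * w[:, None, None])
        if config.noise_sd > 0:
            frames = frames + config.noise_sd * rng.standard_normal(frames.shape)
        clipped = int((frames < 0).sum())
        if clipped:
            clipped_total += clipped
            frames = np.clip(frames, 0.0, None)
        loc = SECTION_LOCATIONS[s % len(SECTION_LOCATIONS)]
        sections.append(
            Section(
                frames=frames,
                pixel_spacing=config.pixel_spacing,
                cc_coords=cc,
                lung_roi=roi.copy(),
                location=loc,
            )
        )
    if clipped_total:
        log.info("clipped %d negative signal samples at zero", clipped_total)
    if ground is not None:
        ground.enhancement_amplitude = amplitudes
    return OEMRISeries(sections=sections, phase_labels=phase_labels)


# ---------------------------------------------------------------------------
# Cohort


@dataclass
class SubjectSpec:
    """Per-subject ground truth plus the image configs that realise it."""

    subject_id: str
    group: str
    true_lav_fraction: float
    true_gradient: float
    true_amplitude: float
    true_enh_gradient: float
    ct_config: CTPhantomConfig
    oemri_config: OEMRIPhantomConfig


def _truncnorm(rng, mean, sd, lo, hi, size):
    return np.clip(mean + sd * rng.standard_normal(size), lo, hi)


def generate_cohort(
    config: CohortConfig,
    ct_template: CTPhantomConfig | None = None,
    oemri_template: OEMRIPhantomConfig | None = None,
) -> tuple[pd.DataFrame, list[SubjectSpec], GroundTruth]:
    """Generate a cohort table, per-subject image configs, and ground truth.

    The table's imaging columns (lav_pct, sd_lav, mrer, sd_rer) are the
    analytic ground-truth indices implied by each subject's true parameters
    (10-partition linear profile; MRER on the plateau scale 100*a). The
    pipeline overwrites them with values measured from generated images.
    ``GroundTruth.covariate_means`` carries the noise-free linear predictors
    for recovery tests.
    """
    rng = np.random.default_rng(config.seed)
    ct_template = ct_template or CTPhantomConfig()
    oemri_template = oemri_template or OEMRIPhantomConfig()
    children = np.random.SeedSequence(config.seed).spawn(config.n_copd + config.n_control)

    rows, specs, truths = [], [], []
    groups = ["COPD"] * config.n_copd + ["control"] * config.n_control
    ramp = PARTITION_RAMP
    for i, group in enumerate(groups):
        copd = group == "COPD"
        f = float(
            _truncnorm(
                rng,
                config.copd_lav_mean if copd else config.control_lav_mean,
                config.copd_lav_sd if copd else config.control_lav_sd,
                *config.lav_bounds,
                size=(),
            )
        )
        g_lo, g_hi = config.copd_gradient_range if copd else config.control_gradient_range
        g = float(rng.uniform(g_lo, g_hi))
        amp_sd = config.copd_amp_noise_sd if copd else config.control_amp_noise_sd
        a = float(
            np.clip(
                config.amp_base - config.amp_slope * f + amp_sd * rng.standard_normal(),
                *config.amp_bounds,
            )
        )
        # enhancement gradient opposes the emphysema gradient (caudal-dominant
        # destruction depresses caudal oxygen uptake)
        ga = float(np.clip(-0.6 * g + 0.05 * rng.standard_normal(), -1.0, 1.0))

        # analytic 10-partition profiles -> heterogeneity indices. Partition
        # noise ~ 0.10*sqrt(f) matches the cluster-granularity scatter the CT
        # phantom generator itself produces at the default cluster size.
        lav_noise = 0.10 * np.sqrt(max(f, 0.0))
        lav_profile = np.clip(
            f * (1.0 + g * ramp) + lav_noise * rng.standard_normal(10), 0.0, 1.0
        )
        rer_profile = np.clip(
            100.0 * a * (1.0 + ga * ramp) + 0.5 * rng.standard_normal(10), 0.0, None
        )
        lav_pct = 100.0 * f
        sd_lav_true = float(np.std(100.0 * lav_profile, ddof=1))
        mrer_true = 100.0 * a
        sd_rer_true = float(np.std(rer_profile, ddof=1))

        fev1_mean = config.fev1_base + config.fev1_slope * f
        dlco_mean = config.dlco_base + config.dlco_slope * f
        pao2_mean = config.pao2_base + config.pao2_slope * (f * g)
        fev1 = max(fev1_mean + config.fev1_noise_sd * rng.standard_normal(), 0.3)
        dlco = max(dlco_mean + config.dlco_noise_sd * rng.standard_normal(), 1.0)
        pao2 = float(pao2_mean + config.pao2_noise_sd * rng.standard_normal())
        age = float(
            rng.normal(
                config.copd_age_mean if copd else config.control_age_mean,
                config.copd_age_sd if copd else config.control_age_sd,
            )
        )
        bmi = float(rng.normal(config.bmi_mean, config.bmi_sd))
        fev1_pred = 2.9 if copd else 3.95
        ratio = 0.55 if copd else 0.85
        fvc = fev1 / ratio
        vc = fvc * float(rng.normal(1.0, 0.02))
        rv_tlc = 27.0 + 40.0 * f + float(rng.normal(0.0, 2.0))
        paco2 = float(rng.normal(39.5 if copd else 40.0, 2.0))

        sid = f"{'copd' if copd else 'ctrl'}{i:03d}"
        rows.append(
            {
                "subject_id": sid,
                "group": group,
                "age": age,
                "bmi": bmi,
                "fev1": fev1,
                "pct_fev1": 100.0 * fev1 / fev1_pred,
                "fvc": fvc,
                "vc": vc,
                "rv_tlc": rv_tlc,
                "dlco": dlco,
                "pao2": pao2,
                "paco2": paco2,
                "lav_pct": lav_pct,
                "sd_lav": sd_lav_true,
                "mrer": mrer_true,
                "sd_rer": sd_rer_true,
            }
        )
        truths.append(
            {
                "subject_id": sid,
                "true_lav_fraction": f,
                "true_gradient": g,
                "true_amplitude": a,
                "true_enh_gradient": ga,
                "fev1_mean": fev1_mean,
                "dlco_mean": dlco_mean,
                "pao2_mean": pao2_mean,
            }
        )
        seed_i = int(children[i].generate_state(1)[0] % (2**31))
        specs.append(
            SubjectSpec(
                subject_id=sid,
                group=group,
                true_lav_fraction=f,
                true_gradient=g,
                true_amplitude=a,
                true_enh_gradient=ga,
                ct_config=replace(
                    ct_template,
                    lav_fraction_target=f,
                    gradient_strength=float(np.clip(g, -1.0, 1.0)),
                    seed=seed_i,
                ),
                oemri_config=replace(
                    oemri_template,
                    enhancement_amplitude_mean=a,
                    enhancement_gradient=ga,
                    seed=seed_i,
                ),
            )
        )

    table = pd.DataFrame(rows)
    ground = GroundTruth(covariate_means=pd.DataFrame(truths))
    return table, specs, ground
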