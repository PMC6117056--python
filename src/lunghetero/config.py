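"""Configuration dataclasses for the phantom generators and the pipeline.

Defaults encode the study conditions emulated by the synthetic cohort:
40 COPD patients and 9 controls, 5-min air / 5-min oxygen / 5-min air
OEMRI phases over three coronal sections, a -960 HU emphysema cut-off.
All randomness is governed by per-config integer seeds.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "CTPhantomConfig",
    "OEMRIPhantomConfig",
    "CohortConfig",
    "RunConfig",
    "load_config",
    "save_config",
]


@dataclass
class CTPhantomConfig:
    """Parameters of the synthetic chest-CT phantom.

    The phantom is an ellipsoid-pair lung with a cylindrical trachea;
    emphysema is placed as spherical low-attenuation clusters whose centres
    are sampled from a cranial-caudal density tilted by ``gradient_strength``
    (positive = caudal-dominant) until the labelled fraction of lung voxels
    hits ``lav_fraction_target`` to within half a percentage point.
    """

    grid_shape: tuple[int, int, int] = (36, 28, 28)  # (z, y, x); z cranial -> caudal
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)  # mm
    lav_fraction_target: float = 0.25
    gradient_strength: float = 0.0  # in [-1, 1]; 0 homogeneous, >0 caudal-dominant
    cluster_radius_mm: float = 4.0
    parenchyma_hu_mean: float = -870.0
    parenchyma_hu_sd: float = 25.0
    emphysema_hu_mean: float = -985.0
    emphysema_hu_sd: float = 8.0
    global_hu_offset: float = 0.0  # simulated scanner miscalibration
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(v) for v in self.grid_shape)
        self.voxel_spacing = tuple(float(v) for v in self.voxel_spacing)
        if not 0.0 <= self.lav_fraction_target <= 1.0:
            raise ValueError("lav_fraction_target must lie in [0, 1]")
        if not -1.0 <= self.gradient_strength <= 1.0:
            raise ValueError("gradient_strength must lie in [-1, 1]")
        if not self.emphysema_hu_mean < -960.0 < self.parenchyma_hu_mean:
            raise ValueError(
                "require emphysema_hu_mean < -960 < parenchyma_hu_mean "
                f"(got {self.emphysema_hu_mean}, {self.parenchyma_hu_mean})"
            )
        if self.parenchyma_hu_sd < 0 or self.emphysema_hu_sd < 0:
            raise ValueError("HU standard deviations must be non-negative")
        if self.cluster_radius_mm <= 0:
            raise ValueError("cluster_radius_mm must be positive")


@dataclass
class OEMRIPhantomConfig:
    """Parameters of the synthetic oxygen-enhanced MRI acquisition.

    Per-pixel signal follows S(t) = baseline * (1 + a * w(t)) + noise where
    ``a`` is the pixel's enhancement amplitude and w(t) is zero on room air,
    rises exponentially (time constant ``washin_time_constant`` frames)
    during oxygen, and decays back during the final room-air phase.
    """

    section_count: int = 3
    frame_shape: tuple[int, int] = (32, 26)  # (rows=cranial-caudal, cols)
    frames_per_phase: int = 20
    phase_durations: tuple[float, float, float] = (5.0, 5.0, 5.0)  # minutes: air1, O2, air2
    enhancement_amplitude_mean: float = 0.22  # fractional signal rise at plateau
    enhancement_gradient: float = 0.0  # in [-1, 1] along cranial-caudal axis
    washin_time_constant: float = 3.0  # frames
    noise_sd: float = 0.0  # signal units
    baseline_signal: float = 100.0
    pixel_spacing: tuple[float, float] = (9.0, 9.0)  # mm (row, col)
    emphysema_coupling: float = 1.0  # amplitude reduction per unit local emphysema fraction
    seed: int = 0

    def __post_init__(self) -> None:
        self.frame_shape = tuple(int(v) for v in self.frame_shape)
        self.phase_durations = tuple(float(v) for v in self.phase_durations)
        self.pixel_spacing = tuple(float(v) for v in self.pixel_spacing)
        if self.section_count < 1:
            raise ValueError("section_count must be >= 1")
        if self.frames_per_phase < 1:
            raise ValueError("frames_per_phase must be >= 1")
        if not -1.0 <= self.enhancement_gradient <= 1.0:
            raise ValueError("enhancement_gradient must lie in [-1, 1]")
        if self.enhancement_amplitude_mean < 0:
            raise ValueError("enhancement_amplitude_mean must be >= 0")
        if self.washin_time_constant <= 0:
            raise ValueError("washin_time_constant must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.baseline_signal <= 0:
            raise ValueError("baseline_signal must be positive")


@dataclass
class CohortConfig:
    """Cohort structure and covariate link model.

    Covariates are generated from the subject's imaging ground truth
    (true LAV fraction ``f``, true cranial-caudal gradient ``g``, true
    enhancement amplitude ``a``) through linear links plus Gaussian noise:

    * amplitude  a   = amp_base - amp_slope * f + N(0, amp_noise_sd[group])
    * FEV1           = fev1_base + fev1_slope * f + N(0, fev1_noise_sd)
    * DLCO           = dlco_base + dlco_slope * f + N(0, dlco_noise_sd)
    * PaO2           = pao2_base + pao2_slope * (f * g) + N(0, pao2_noise_sd)

    Slopes for FEV1/DLCO/PaO2 are negative by default: more emphysema means
    worse airflow and gas transfer. PaO2 is driven by the absolute
    cranial-caudal slope of the emphysema profile, f * g (the heterogeneous
    destruction burden, to which ventilation-perfusion mismatch is
    attributed), not by whole-lung severity f alone.
    """

    n_copd: int = 40
    n_control: int = 9
    # true emphysema burden per group (truncated normal on the LAV fraction)
    copd_lav_mean: float = 0.25
    copd_lav_sd: float = 0.10
    control_lav_mean: float = 0.02
    control_lav_sd: float = 0.01
    lav_bounds: tuple[float, float] = (0.0, 0.60)
    # true cranial-caudal gradient (uniform) per group
    copd_gradient_range: tuple[float, float] = (0.0, 0.7)
    control_gradient_range: tuple[float, float] = (0.0, 0.1)
    # amplitude link (MRER ~ 100 * amplitude at plateau)
    amp_base: float = 0.228
    amp_slope: float = 0.40
    copd_amp_noise_sd: float = 0.025
    control_amp_noise_sd: float = 0.034
    amp_bounds: tuple[float, float] = (0.01, 0.40)
    # covariate links
    fev1_base: float = 3.9
    fev1_slope: float = -8.0
    fev1_noise_sd: float = 0.5
    dlco_base: float = 31.0
    dlco_slope: float = -70.0
    dlco_noise_sd: float = 6.0
    pao2_base: float = 88.0
    pao2_slope: float = -90.0
    pao2_noise_sd: float = 4.0
    # demographics (not linked to imaging truth)
    copd_age_mean: float = 70.0
    copd_age_sd: float = 6.0
    control_age_mean: float = 34.0
    control_age_sd: float = 3.0
    bmi_mean: float = 21.5
    bmi_sd: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_copd < 2 or self.n_control < 2:
            raise ValueError("n_copd and n_control must both be >= 2")
        for name in (
            "copd_lav_sd", "control_lav_sd", "copd_amp_noise_sd", "control_amp_noise_sd",
            "fev1_noise_sd", "dlco_noise_sd", "pao2_noise_sd",
            "copd_age_sd", "control_age_sd", "bmi_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RunConfig:
    """End-to-end pipeline configuration: one seed governs the whole run."""

    out_dir: str = "run_output"
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ct: CTPhantomConfig = field(default_factory=CTPhantomConfig)
    oemri: OEMRIPhantomConfig = field(default_factory=OEMRIPhantomConfig)
    lav_threshold_hu: float = -960.0
    ct_partitions: int = 12
    oemri_partitions: int = 10
    window_fraction: float = 0.5
    verbosity: int = 1


_CONFIG_TYPES = {
    "ct": CTPhantomConfig,
    "oemri": OEMRIPhantomConfig,
    "cohort": CohortConfig,
}


def _to_plain(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    return obj


def save_config(config: Any, path: str | Path) -> None:
    """Serialise any config dataclass to YAML."""
    Path(path).write_text(yaml.safe_dump(_to_plain(config), sort_keys=True))


def load_config(path: str | Path, cls: type = RunConfig) -> Any:
    """Load a config dataclass from YAML; nested RunConfig sections recurse."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return _from_plain(raw, cls)


def _from_plain(raw: dict, cls: type) -> Any:
    kwargs = {}
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(raw) - set(names)
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    for key, value in raw.items():
        if cls is RunConfig and key in _CONFIG_TYPES and isinstance(value, dict):
            kwargs[key] = _from_plain(value, _CONFIG_TYPES[key])
        elif isinstance(value, list):
            kwargs[key] = tuple(value)
        else:
            kwargs[key] = value
    return cls(**kwargs)
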