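import numpy as np
import pytest

from lunghetero.config import (
    CohortConfig,
    CTPhantomConfig,
    OEMRIPhantomConfig,
    RunConfig,
)
from lunghetero.datatypes import CTVolume, GroundTruth
from lunghetero.synth import generate_ct_phantom, generate_oemri_phantom


@pytest.fixture(scope="session")
def noiseless_ct_config():
    """Noiseless HU, no miscalibration: threshold mask == emphysema label."""
    return CTPhantomConfig(
        lav_fraction_target=0.30,
        parenchyma_hu_sd=0.0,
        emphysema_hu_sd=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def noiseless_ct_phantom(noiseless_ct_config):
    return generate_ct_phantom(noiseless_ct_config)


@pytest.fixture(scope="session")
def small_phantom():
    """A <= 32^3 phantom with HU noise, for oracle cross-checks."""
    cfg = CTPhantomConfig(
        grid_shape=(30, 24, 24),
        voxel_spacing=(2.5, 2.5, 2.5),
        lav_fraction_target=0.2,
        gradient_strength=0.3,
        seed=21,
    )
    return generate_ct_phantom(cfg)


@pytest.fixture(scope="session")
def noiseless_oemri():
    cfg = OEMRIPhantomConfig(
        enhancement_amplitude_mean=0.22, noise_sd=0.0, enhancement_gradient=0.0, seed=3
    )
    series = generate_oemri_phantom(cfg, GroundTruth())
    return cfg, series


@pytest.fixture
def demo_run_config(tmp_path):
    """Small end-to-end pipeline configuration (8 COPD + 3 controls)."""

    def make(sub="run", seed=5):
        return RunConfig(
            out_dir=str(tmp_path / sub),
            seed=seed,
            cohort=CohortConfig(n_copd=8, n_control=3),
            ct=CTPhantomConfig(
                grid_shape=(24, 20, 20), voxel_spacing=(3.0, 3.0, 3.0), cluster_radius_mm=4.0
            ),
            oemri=OEMRIPhantomConfig(frame_shape=(24, 20), frames_per_phase=8, noise_sd=1.0),
        )

    return make


@pytest.fixture
def tiny_volume():
    """Hand-built volume: 16 slices, 2x2 lung per slice, trachea strip."""
    shape = (16, 4, 4)
    hu = np.full(shape, 40.0)
    lung = np.zeros(shape, dtype=bool)
    lung[:, 1:3, 1:3] = True
    trachea = np.zeros(shape, dtype=bool)
    trachea[:8, 0, 0] = True
    hu[lung] = -880.0
    hu[trachea] = -1000.0
    return CTVolume(hu=hu, spacing=(1.0, 1.0, 1.0), lung_mask=lung, trachea_mask=trachea)
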