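import numpy as np
import pytest

from choroseg import phantom, pipeline
from choroseg.config import RunConfig, default_phantom_config


@pytest.fixture(scope="session")
def study_cfg() -> RunConfig:
    """The standard synthetic study conditions."""
    return default_phantom_config()


@pytest.fixture(scope="session")
def small_cfg() -> RunConfig:
    """A small, fast phantom for unit tests (same voxel pitches)."""
    return default_phantom_config().replace(
        n_depth=160, n_fast=64, n_slow=64,
        field_deg_x=2.75, field_deg_y=2.75,
        rbc_mean_depth=40.0, csi_mean_depth=120.0,
        n_sattler=12, n_haller=5, etdrs_central_mm=0.5)


@pytest.fixture(scope="session")
def speckled_run(study_cfg):
    """Full pipeline on the standard speckled phantom (seed 1)."""
    vol, truth = phantom.generate_phantom(study_cfg, 1)
    result = pipeline.analyze_volume(vol, study_cfg)
    return study_cfg, vol, truth, result


@pytest.fixture(scope="session")
def noisefree_run(study_cfg):
    """Full pipeline on the speckle-free phantom (attenuation kept)."""
    cfg = study_cfg.replace(speckle_shape=0.0)
    vol, truth = phantom.generate_phantom(cfg, 11)
    result = pipeline.analyze_volume(vol, cfg)
    return cfg, vol, truth, result


@pytest.fixture(scope="session")
def small_noisefree(small_cfg):
    """Small phantom without speckle or attenuation (exact intensities)."""
    cfg = small_cfg.replace(speckle_shape=0.0, attenuation_tau_voxels=0.0)
    vol, truth = phantom.generate_phantom(cfg, 5)
    return cfg, vol, truth


def true_region(truth):
    """Choroid region built from the phantom's true surfaces."""
    from choroseg.core import ChoroidRegion
    start = np.ceil(truth.rbc_surface.depth).astype(np.int64)
    stop = np.floor(truth.csi_surface.depth).astype(np.int64)
    return ChoroidRegion(start, stop, np.ones_like(start, dtype=bool))
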