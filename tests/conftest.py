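import numpy as np
import pytest

from radarcough.config import DatasetSpec, ModelConfig, RadarConfig, TrainConfig
from radarcough.simulate import MotionProfile, Scatterer, synthesize_cube


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_radar():
    """Short recording (fewer chirps) for cheap spectral tests."""
    return RadarConfig(num_chirps=250)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    """Narrow trunk / small feature dim so CPU tests stay fast."""
    return ModelConfig(spatial_backbone="resnet18", base_channels=4,
                       feature_dim=64, ffn_hidden_dim=128)


@pytest.fixture(scope="session")
def tiny_dataset_spec():
    return DatasetSpec(num_subjects=5, bed_cough=2, bed_noncough=2,
                       sitting_cough=2, sitting_noncough=2, snr_db=20.0,
                       master_seed=11)


def static_cube(range_m=1.0, cfg=None, velocity=0.0, snr_db=None, seed=0):
    profile = MotionProfile(
        [Scatterer(base_range=range_m, radial_velocity=velocity)],
        activity_class="breathing", scene="bed",
    )
    return synthesize_cube(profile, cfg, snr_db=snr_db, rng=seed)
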