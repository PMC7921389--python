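import numpy as np
import pytest

from lungpatterns.cae_fc import CAEFCConfig, CAEFCModel, train_cae_fc
from lungpatterns.preprocessing import ROI, DualChannelVolume
from lungpatterns.synthetic import CohortConfig, TextureClassSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def small_cohort_config(n_subjects=6, shape=24, seed=0, **kw):
    """Small-volume cohort for unit tests (generate with min_volume_vox=16)."""
    return CohortConfig(n_subjects=n_subjects, volume_shape_vox=(shape,) * 3,
                        n_blobs_per_subject=6, seed=seed, **kw)


@pytest.fixture(scope="session")
def small_cohort():
    cfg = small_cohort_config()
    return cfg, generate_cohort(cfg, min_volume_vox=16)


@pytest.fixture(scope="session")
def tiny_cae_config():
    """8^3 ROIs, two conv stages: fast enough for unit-level training."""
    return CAEFCConfig(embedding_size=4, encoder_channels=(4,), roi_size_vox=8,
                       gate_keep_k=1, batch_size=4, epochs=3, learning_rate=3e-3,
                       seed=0)


def tiny_rois(rng, n=12, size=8):
    """Random nonnegative dual-channel patches in the rescaled value range."""
    return [ROI(values=rng.uniform(0.0, 1.0, (2, size, size, size)).astype(np.float32),
                origin_vox=(0, 0, 0), subject_id=f"S{i % 3}") for i in range(n)]


@pytest.fixture(scope="session")
def tiny_trained_model(tiny_cae_config, rng):
    rois = tiny_rois(np.random.default_rng(7), n=16)
    return train_cae_fc(rois, tiny_cae_config), rois


@pytest.fixture()
def all_lung_volume():
    """36^3 dual-channel volume whose mask covers everything."""
    gen = np.random.default_rng(3)
    shape = (36, 36, 36)
    return DualChannelVolume(
        intensity_fraction=gen.uniform(0, 0.4, shape),
        jacobian=gen.uniform(0.5, 1.1, shape),
        spacing_mm=(0.625, 0.625, 0.625),
        lung_mask=np.ones(shape, np.uint8),
    )
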