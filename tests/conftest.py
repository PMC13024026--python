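import numpy as np
import pytest

from brainage import BackboneConfig, FusionConfig, SimulationParams, generate_cohort


@pytest.fixture(scope="session")
def tiny_backbone_cfg():
    """Narrow backbone for fast functional tests (full-width checks are separate)."""
    return BackboneConfig(stem_channels=16, stage_channels=(16, 32, 64),
                          blocks_per_stage=(1, 1, 1))


@pytest.fixture(scope="session")
def tiny_fusion_cfg():
    return FusionConfig(small_embed_dim=24, large_embed_dim=40)


@pytest.fixture(scope="session")
def micro_cohort():
    """Twelve scans on a 20^3 grid — the smallest grid the fusion head accepts."""
    params = SimulationParams(grid_shape=(20, 20, 20), n_subjects=12, seed=42)
    return generate_cohort(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
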