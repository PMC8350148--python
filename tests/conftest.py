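import numpy as np
import pytest

import pairconn as pc


@pytest.fixture(scope="session")
def tiny_model_config():
    """A minimal but fully structural network configuration."""
    return pc.ModelConfig(
        n_regions=4, n_timepoints=16, embed_dim=3, head_size=3,
        conv_filters=(2, 3, 3, 4, 4, 4), similarity_hidden=(5, 4),
        classifier_hidden=(100, 6), dropout=0.0,
    )


@pytest.fixture(scope="session")
def tiny_batch():
    rng = np.random.default_rng(7)
    return rng.normal(size=(3, 4, 16))


@pytest.fixture(scope="session")
def small_cohort():
    """60-subject cohort with study-like prevalences and dropout."""
    cfg = pc.CohortConfig(
        n_subjects=60, n_regions=6, n_timepoints_signal=32,
        planted_pairs=[(0, 1), (2, 3)], effect_strength=2.0, seed=42,
    )
    return pc.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    return small_cohort.to_dataset()
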