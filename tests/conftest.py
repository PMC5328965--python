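import numpy as np
import pytest

from connmvpa import (
    PlantedEffect,
    RoiTimeSeries,
    generate_feature_dataset,
    generate_paired_study,
    study_to_labeled,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series(rng):
    """Non-degenerate 40-frame x 5-region series at TR = 2 s."""
    return RoiTimeSeries(
        data=rng.standard_normal((40, 5)), tr=2.0, region_ids=np.arange(1, 6)
    )


@pytest.fixture(scope="session")
def planted_feature_study():
    """Feature-level study with 5 strongly informative features of 50."""
    return generate_feature_dataset(
        n_per_class=25, n_features=50, informative_idx=(3, 9, 21, 30, 44),
        effect_size=3.0, seed=42,
    )


@pytest.fixture(scope="session")
def small_paired_study():
    """6 subjects x 10 regions with one strongly planted edge; cheap."""
    effect = PlantedEffect(edges=[(2, 7)], delta_r=0.5)
    return generate_paired_study(
        n_subjects=6, n_regions=10, n_frames=60, effect=effect, seed=7
    )


@pytest.fixture(scope="session")
def small_labeled(small_paired_study):
    return study_to_labeled(small_paired_study)
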