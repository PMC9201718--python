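import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sparnet import CohortSpec, RegionMap, make_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


SMALL_MONTAGE = tuple(f"E{i}" for i in range(1, 11))
SMALL_REGIONS = {
    "C": ["E1", "E2"],
    "F": ["E3", "E4"],
    "O": ["E5", "E6"],
    "P": ["E7", "E8"],
    "T": ["E9", "E10"],
}


@pytest.fixture(scope="session")
def small_region_map():
    """A 10-channel map with two channels per region, for fast pipeline tests."""
    return RegionMap(variant="custom", regions=SMALL_REGIONS)


@pytest.fixture(scope="session")
def small_cohort():
    """4+4 subjects, 300 s, 10 channels, strong frontal theta effect."""
    spec = CohortSpec(
        n_mdd=4, n_control=4, duration_s=300.0, seed=5,
        channel_names=SMALL_MONTAGE, region_channels=SMALL_REGIONS,
        effect={"F": {"theta": 3.0}},
    )
    return make_cohort(spec)


@pytest.fixture(scope="session")
def small_report(small_cohort, small_region_map):
    """A complete reduced LOSO run shared by the report-structure tests."""
    from sparnet import run_experiment

    return run_experiment(
        small_cohort, region_map=small_region_map, denoise=False,
        n_folds=3, seed=3,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
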