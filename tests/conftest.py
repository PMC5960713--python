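import numpy as np
import pytest

from honfc import (
    ROITimeSeries,
    build_level_feature_sets,
    build_multilevel,
)
from honfc.simulate import SyntheticCohortSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def toy_timeseries(rng):
    """A well-behaved 30x6 subject."""
    return ROITimeSeries("toy", rng.standard_normal((30, 6)))


def make_cohort_features(spec: SyntheticCohortSpec, t: int = 1):
    """Generate a cohort and vectorize its network hierarchy."""
    cohort, labels = generate_cohort(spec)
    hierarchies = [build_multilevel(ts, t) for ts in cohort]
    ids = [ts.subject_id for ts in cohort]
    return build_level_feature_sets(hierarchies, labels, subject_ids=ids)


@pytest.fixture(scope="session")
def small_cohort_features():
    """A small planted-effect cohort shared across tests (16 ROIs keeps
    every downstream fit fast)."""
    spec = SyntheticCohortSpec(
        n_pos=20, n_neg=20, R=16, T=60, n_modules=4,
        loworder_edges=((5, 1, 0.35), (9, 2, 0.35)), seed=7,
    )
    return make_cohort_features(spec, t=1)
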