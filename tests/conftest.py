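import numpy as np
import pytest

from apvpipe.phantom import make_cohort, phantom_region_table, study_spec
from apvpipe.radiomics import default_catalogue
from apvpipe.workflow import cohort_feature_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_cohort_matrix():
    """A small strong-signal cohort with original-channel features, shared by
    the cascade/workflow tests (12 subjects per group, 48^3 grid)."""
    spec = study_spec(shape=(48, 48, 48))
    cohort = make_cohort(spec, n_per_group=12, seed=11)
    table = phantom_region_table(spec.n_regions)
    cat = default_catalogue(channels=("original",))
    fm = cohort_feature_matrix(cohort, table, cat, region_set="WM45")
    return spec, fm
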