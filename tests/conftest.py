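import numpy as np
import pytest

from autoaspects.atlas import ASPECTSRegion
from autoaspects.phantom import PhantomSpec, generate_cohort, generate_subject, make_atlas


@pytest.fixture(scope="session")
def atlas():
    return make_atlas()


@pytest.fixture(scope="session")
def lesioned_subject(atlas):
    spec = PhantomSpec(lesion_regions=(ASPECTSRegion("M1", "left"),
                                       ASPECTSRegion("insula", "left")),
                       seed=42)
    return generate_subject(spec, atlas=atlas, subject_id="fixture-sub")


@pytest.fixture(scope="session")
def small_cohort():
    spec = PhantomSpec(lesion_delta_hu=-30.0)
    return generate_cohort(12, stroke_prevalence=0.7, spec=spec, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
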