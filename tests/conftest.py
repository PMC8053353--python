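import numpy as np
import pytest

from ftdebm.data_model import BiomarkerSpec, CohortTable, SubjectRecord
from ftdebm.synthetic_data import GeneratorConfig, generate_cohort

FULL_AVAILABILITY = {
    mod: {g: 1.0 for g in ("symptomatic", "presymptomatic", "noncarrier")}
    for mod in ("fluid", "cognitive", "grey_matter", "white_matter")
}


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (35/56/35, 22 biomarkers) with truth."""
    return generate_cohort(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def clean_cohort():
    """Fully observed cohort without confounder effects (seed 11)."""
    gc = GeneratorConfig(seed=11, availability=FULL_AVAILABILITY,
                         confounder_scale=0.0)
    return generate_cohort(gc)


def make_toy_cohort():
    """3 subjects x 2 biomarkers with one missing NfL cell."""
    specs = [
        BiomarkerSpec("nfl", "fluid", "increase", confounders=()),
        BiomarkerSpec("mmse", "cognitive", "decrease", confounders=()),
    ]
    subjects = [
        SubjectRecord("a", "noncarrier", covariates={"age": 50.0}),
        SubjectRecord("b", "presymptomatic", covariates={"age": 55.0}),
        SubjectRecord("c", "symptomatic", phenotype="bvFTD",
                      covariates={"age": 60.0}, years_since_onset=2.0),
    ]
    values = np.array([[10.0, 29.0], [12.0, 28.0], [np.nan, 21.0]])
    observed = ~np.isnan(values)
    return CohortTable(subjects, specs, values, observed)


@pytest.fixture
def toy_cohort():
    return make_toy_cohort()
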