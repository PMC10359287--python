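import numpy as np
import pytest

import seatherm as st


@pytest.fixture(scope="session")
def default_niches():
    return st.default_niches()


@pytest.fixture(scope="session")
def sim_catalog(default_niches):
    return st.catalog_from_niches(default_niches)


@pytest.fixture(scope="session")
def sim_survey(default_niches):
    """One default warming survey (2 x 3 x 5 x 6 = 180 quadrats)."""
    samples, truth = st.simulate_community(
        default_niches, st.ScenarioSpec(delta_t=1.0, seed=101)
    )
    return samples, truth


@pytest.fixture
def toy_catalog():
    return st.TaxonCatalog.from_records(
        [
            ("A", "species", "turf", 16.0),
            ("B", "species", "canopy", 12.0),
            ("C", "genus", "turf", None),
            ("D", "species", "encrusting", 14.0),
        ]
    )


def make_sample(sample_id="s1", year="2012", region="VIA", reef="r1", quadrat=1,
                biomass=None):
    return st.CommunitySample(
        sample_id=sample_id, year=year, region=region, reef=reef,
        quadrat=quadrat, biomass=biomass or {},
    )


@pytest.fixture
def sample_factory():
    return make_sample
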