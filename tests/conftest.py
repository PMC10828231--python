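import numpy as np
import pandas as pd
import pytest

from dogaging import breeds as breed_meta
from dogaging.config import DEFAULT_LOADINGS, default_config
from dogaging.factors import implied_correlation


@pytest.fixture(scope="session")
def breed_metadata():
    return {
        "standards": breed_meta.breed_standards(),
        "lifespans": breed_meta.breed_lifespans(),
        "cephalic": breed_meta.breed_cephalic_indices(),
    }


@pytest.fixture(scope="session")
def reference_loadings_8():
    """The eight-item reference loading pattern (weak owner item excluded)."""
    keep = [0, 1, 2, 3, 4, 5, 7, 8]
    return DEFAULT_LOADINGS[keep]


@pytest.fixture(scope="session")
def implied_R8(reference_loadings_8):
    """Population correlation matrix implied by the reference pattern."""
    return implied_correlation(reference_loadings_8)


@pytest.fixture(scope="session")
def small_survey():
    """A small full-sample synthetic survey shared across tests."""
    from dogaging.simulate import make_raw_survey

    return make_raw_survey(default_config(n_dogs=4000, seed=123))


@pytest.fixture(scope="session")
def small_clean(small_survey, breed_metadata):
    from dogaging.cleaning import clean_survey

    clean, log = clean_survey(
        small_survey,
        breed_metadata["standards"],
        breed_metadata["lifespans"],
        breed_metadata["cephalic"],
    )
    return clean
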