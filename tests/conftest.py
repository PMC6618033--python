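import numpy as np
import pandas as pd
import pytest

from taxometrics.io import IndicatorMatrix, ResponseSheet
from taxometrics.simulate import anbp_scenario, bn_scenario, make_dimensional, make_taxonic


@pytest.fixture
def toy_matrix():
    """Small labeled two-group matrix with a clean separation."""
    rng = np.random.default_rng(42)
    n_c, n_t = 80, 20
    comp = rng.normal(0.0, 1.0, size=(n_c, 3))
    tax = rng.normal(2.5, 1.0, size=(n_t, 3))
    group = np.array(["complement_putative"] * n_c + ["taxon_putative"] * n_t,
                     dtype=object)
    return IndicatorMatrix(np.vstack([comp, tax]), ["a", "b", "c"], group=group)


@pytest.fixture
def response_sheet():
    items = {"i1": "bulimia", "i2": "bulimia", "i3": "bulimia",
             "i4": "drive_thin", "i5": "drive_thin"}
    responses = pd.DataFrame({
        "i1": ["always", "never", "sometimes"],
        "i2": ["sometimes", "never", "usually"],
        "i3": ["occasionally", "never", "often"],
        "i4": ["never", "usually", "never"],
        "i5": ["never", "always", "occasionally"],
    })
    return ResponseSheet(["c1", "c2", "c3"], responses, items)


@pytest.fixture(scope="session")
def anbp_taxonic():
    return make_taxonic(anbp_scenario(), seed=1)


@pytest.fixture(scope="session")
def anbp_dimensional():
    return make_dimensional(anbp_scenario(), seed=1)


@pytest.fixture(scope="session")
def bn_taxonic():
    return make_taxonic(bn_scenario(), seed=1)
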