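import numpy as np
import pytest
from hypothesis import settings

import dustrisk as dr

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def panel():
    return dr.load_reference_panel()


@pytest.fixture(scope="session")
def exposure():
    return dr.load_exposure_parameters()


@pytest.fixture(scope="session")
def toxicity():
    return dr.load_toxicity_table()


@pytest.fixture(scope="session")
def study_means():
    return dr.load_study_means()


@pytest.fixture(scope="session")
def study31():
    """Default synthetic 31-residence survey, fixed seed."""
    return dr.simulate_study(dr.default_config(seed=20210101))


def make_study(values_by_element, *, county="Harris", lons=None, lats=None):
    """Small hand-built StudyTable from {element: [v1..vn]} (equal lengths)."""
    elements = list(values_by_element)
    n = len(values_by_element[elements[0]])
    rng = np.random.default_rng(7)
    lons = lons if lons is not None else rng.uniform(-95.8, -95.1, n)
    lats = lats if lats is not None else rng.uniform(29.5, 30.1, n)
    samples = [
        dr.DustSample(
            sample_id=f"S{i + 1}",
            county=county,
            lon=float(lons[i]),
            lat=float(lats[i]),
            concentrations={e: float(values_by_element[e][i]) for e in elements},
        )
        for i in range(n)
    ]
    return dr.StudyTable(samples, elements=elements)
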