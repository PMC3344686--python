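import pytest

import angiodyn as ad


@pytest.fixture(scope="session")
def fixed():
    return ad.load_preset("fixed")


@pytest.fixture(scope="session")
def alternative():
    return ad.load_preset("alternative")


@pytest.fixture(scope="session")
def fixed_points(fixed):
    """(small, big) non-trivial equilibria of the fixed preset."""
    pts = ad.find_cancer_equilibria(fixed)
    small = next(pt for pt in pts if pt.label == "small")
    big = next(pt for pt in pts if pt.label == "big")
    return small, big
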