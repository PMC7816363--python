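import pytest

from gutdx import make_fixture


@pytest.fixture(scope="session")
def paper_shape():
    return make_fixture("paper-shape")


@pytest.fixture(scope="session")
def tiny_separable():
    return make_fixture("tiny-separable")


@pytest.fixture(scope="session")
def tiny_null():
    return make_fixture("tiny-null")


@pytest.fixture(scope="session")
def planted_markers():
    return make_fixture("planted-markers")


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_fixture("tiny-cohort")
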