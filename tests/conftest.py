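import numpy as np
import pytest

from shapeforge.synthetic_mandible import (
    make_reference_half_mandible,
    make_reference_mandible,
)
from shapeforge.template_fit import make_template


@pytest.fixture(scope="session")
def reference0():
    """Level-0 reference mandible (mesh, TM20 landmarks, HM12 landmarks)."""
    return make_reference_mandible(0)


@pytest.fixture(scope="session")
def reference1():
    return make_reference_mandible(1)


@pytest.fixture(scope="session")
def half_reference1():
    return make_reference_half_mandible(1)


@pytest.fixture(scope="session")
def tm_template(reference1):
    mesh, tm, _ = reference1
    return make_template(mesh, tm, "tm-ref")


@pytest.fixture(scope="session")
def hm_template(half_reference1):
    mesh, hm = half_reference1
    return make_template(mesh, hm, "hm-ref")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
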