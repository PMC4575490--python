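import pytest

from titrabench.annotation import generate_annotation
from titrabench.design import canonical_design
from titrabench.simulate import pattern_demo


@pytest.fixture(scope="session")
def demo():
    """Hand-built five-transcript gene with planted cross-platform patterns."""
    return pattern_demo()


@pytest.fixture(scope="session")
def small_annotation():
    return generate_annotation(30, seed=7)


@pytest.fixture()
def design():
    return canonical_design({"arr": 2, "seq": 1})
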