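import numpy as np
import pytest

from iceatt.attsite import AttSiteCore
from iceatt.synth import DEFAULT_REFERENCE_CORE


@pytest.fixture
def reference() -> AttSiteCore:
    return DEFAULT_REFERENCE_CORE


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130718)


def random_core(rng: np.random.Generator) -> AttSiteCore:
    return AttSiteCore("".join(rng.choice(list("ACGT"), size=17)))
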