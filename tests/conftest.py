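import numpy as np
import pytest

from thickfil.geometry import build_half_filament
from thickfil.sarcomere import KineticParams, ModelVariant


@pytest.fixture(scope="session")
def geom():
    return build_half_filament()


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def variants():
    return {n: ModelVariant.from_name(n) for n in ("A", "B", "C", "none")}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
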