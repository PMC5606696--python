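import numpy as np
import pytest

from paok import REFERENCE_PARAMS, KineticParams
from paok.synthetic import SynthSpec, make_reference_panel


@pytest.fixture(scope="session")
def type_i() -> KineticParams:
    return REFERENCE_PARAMS[0]


@pytest.fixture(scope="session")
def type_ii() -> KineticParams:
    return REFERENCE_PARAMS[1]


@pytest.fixture(scope="session")
def reference_pair():
    return list(REFERENCE_PARAMS)


@pytest.fixture(scope="session")
def panel():
    return make_reference_panel()


@pytest.fixture()
def synth_spec():
    return SynthSpec(seed=1234)


def random_params(rng: np.random.Generator, label: str) -> KineticParams:
    """A random but physically plausible Haldane parameter set."""
    return KineticParams(
        label,
        vmax=float(rng.uniform(0.5, 2.0)),
        km=float(rng.uniform(0.1, 5.0)),
        ki=float(rng.uniform(50.0, 5000.0)),
    )
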