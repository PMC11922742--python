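import numpy as np
import pytest

from necell.energetics import IonEnvironment


@pytest.fixture(scope="session")
def env() -> IonEnvironment:
    return IonEnvironment()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240101)
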