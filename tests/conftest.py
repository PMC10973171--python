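import numpy as np
import pytest

from mrnaquant import load_registry


@pytest.fixture(scope="session")
def registry():
    return load_registry()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240311)


def random_rna(rng, length, p_u=0.25):
    """Random A/C/G/U string with uridine fraction ~p_u."""
    rest = (1.0 - p_u) / 3.0
    return "".join(
        rng.choice(list("ACGU"), size=length, p=[rest, rest, rest, p_u])
    )
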