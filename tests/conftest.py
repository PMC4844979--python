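import pytest

from micromet.model import ModelParameters
from micromet.screen import run_screen


@pytest.fixture(scope="session")
def nominal() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def small_screen():
    """A small seeded virtual cohort shared across module tests."""
    return run_screen(n=300, seed=11)
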