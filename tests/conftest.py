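import pytest

from abtau.model import (assemble_full_model, build_base_model,
                         build_immunotherapy_extension, build_model)


@pytest.fixture(scope="session")
def extension():
    return build_immunotherapy_extension()


@pytest.fixture(scope="session")
def base_model():
    return build_base_model()


@pytest.fixture(scope="session")
def full_model():
    """The assembled disease model (AD clearance rate, no immunisation)."""
    return build_model()


@pytest.fixture(scope="session")
def assembled(base_model, extension):
    return assemble_full_model(base_model.copy(), extension.copy())
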