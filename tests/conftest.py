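import pytest

from coldrisk import (
    REFERENCE_BODY,
    ControllerParams,
    build_body_model,
    bundled_ensemble,
    run_paper_tables,
)


@pytest.fixture(scope="session")
def body_model():
    return build_body_model(REFERENCE_BODY)


@pytest.fixture(scope="session")
def low_protection():
    return bundled_ensemble("low_protection")


@pytest.fixture(scope="session")
def high_protection():
    return bundled_ensemble("high_protection")


@pytest.fixture(scope="session")
def calibrated():
    return ControllerParams.defaults()


@pytest.fixture(scope="session")
def paper_tables():
    """The ten reference scenarios run at the reporting time step (1 s)."""
    return run_paper_tables(dt=1.0)
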