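import pytest

from inductsim import LabourInductionModel, load_basecase


@pytest.fixture(scope="session")
def basecase_config():
    return load_basecase()


@pytest.fixture(scope="session")
def fitted(basecase_config):
    """Fitted base-case results, shared across the suite (read-only)."""
    return LabourInductionModel(basecase_config).fit()


@pytest.fixture(scope="session")
def traces(fitted):
    return fitted.traces


def trace_for(fitted, arm, parity):
    return next(t for t in fitted.traces[arm] if t.profile.parity == parity)
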