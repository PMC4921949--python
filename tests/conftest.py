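import pytest

from genevalidity import fixed_point_assess, worked_examples


@pytest.fixture(scope="session")
def worked():
    """(bundle, expected-outcome table) for the cardiac worked examples."""
    return worked_examples()


@pytest.fixture(scope="session")
def worked_bundle(worked):
    return worked[0]


@pytest.fixture(scope="session")
def worked_expected(worked):
    return worked[1]


@pytest.fixture(scope="session")
def worked_result(worked_bundle):
    """Converged fixed-point assessment of the worked-example bundle."""
    return fixed_point_assess(worked_bundle)
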