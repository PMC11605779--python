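import pytest

from silycat.synthetic_data import CohortDesign, build_reference_fixture, simulate_cohort


@pytest.fixture(scope="session")
def reference_fixture():
    """Deterministic noise-free cohort reproducing the known catabolite table."""
    return build_reference_fixture()


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort (seed 11) shared across read-only tests."""
    return simulate_cohort(CohortDesign(seed=11))
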