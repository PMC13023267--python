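import pytest

from snpcatalog.genome import default_layout
from snpcatalog.simulate import StudyConfig, simulate_study, simulate_truth


@pytest.fixture(scope="session")
def layout():
    return default_layout()


@pytest.fixture(scope="session")
def small_truth(layout):
    return simulate_truth(layout, 400, seed=11)


@pytest.fixture(scope="session")
def study():
    """One mid-size synthetic study shared by read-only tests."""
    return simulate_study(StudyConfig(n_variants=1200), seed=7)
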