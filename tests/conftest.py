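import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracle helpers

from consnet.synthetic import demo_instance


@pytest.fixture(scope="session")
def demo():
    """5-gene path with 3 samples; every expectation oracle-confirmed."""
    return demo_instance()


@pytest.fixture()
def demo_network(demo):
    return demo[0]


@pytest.fixture()
def demo_cohort(demo):
    return demo[1]
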