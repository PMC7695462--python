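import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from dloopmap import build_donor, load_substrate


@pytest.fixture(scope="session")
def donor_931():
    """Synthetic ~2.9 kb donor with the 931 nt homology between 1 kb flanks."""
    return build_donor("ds98-931")


@pytest.fixture(scope="session")
def substrate_931():
    return load_substrate("ds98-931")
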