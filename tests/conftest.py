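import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "census",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("census")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def fasta_file(tmp_path):
    """Write FASTA text to a temp file and return its path."""

    def _write(text, name="test.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path

    return _write
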