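import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def fasta_factory(tmp_path):
    """Write sequences to a temporary FASTA and return its path."""

    def _write(records, name="seqs.fasta"):
        path = tmp_path / name
        with open(path, "w") as fh:
            for sid, letters in records:
                fh.write(f">{sid}\n{letters}\n")
        return path

    return _write
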