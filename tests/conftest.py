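import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_matrix_tsv(tmp_path):
    path = tmp_path / "expr.tsv"
    path.write_text(
        "gene_id\tc1\tc2\n"
        "g1\t1.5\t2.5\n"
        "g2\t0.0\t3.0\n"
        "g3\t10.0\t0.5\n"
    )
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(42)
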