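import numpy as np
import pytest

from syntevo.types import Genome


@pytest.fixture
def toy_genome() -> Genome:
    """Two chromosomes, five genes, mixed strands."""
    return Genome(
        "toy",
        [
            ("g1", "chr1", 0, 100, "+", 0),
            ("g2", "chr1", 200, 300, "-", 0),
            ("g3", "chr1", 400, 500, "+", 0),
            ("g4", "chr2", 0, 90, "+", 0),
            ("g5", "chr2", 100, 190, "-", 0),
        ],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
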