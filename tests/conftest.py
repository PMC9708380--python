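import numpy as np
import pytest

from hgtflow.genome_io import CodonUsage


@pytest.fixture
def usage():
    """Factory for CodonUsage over the sense61 alphabet from a codon dict."""

    def make(counts: dict[str, int], alphabet_id: str = "sense61") -> CodonUsage:
        return CodonUsage.from_counts(counts, alphabet_id)

    return make


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
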