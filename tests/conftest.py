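import numpy as np
import pytest

from phageome.io import ContigRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_contig(rng, contig_id: str, length: int) -> ContigRecord:
    bases = np.array(list("ACGT"))
    return ContigRecord(contig_id, "".join(rng.choice(bases, size=length)))


@pytest.fixture
def make_contig(rng):
    def _make(contig_id: str, length: int) -> ContigRecord:
        return random_contig(rng, contig_id, length)

    return _make
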