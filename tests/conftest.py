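import pytest

from dmdkit.gene_model import make_model
from dmdkit.simulate import dmd_like_transcript
from dmdkit.splice import default_library

TOY_LENGTHS = (90, 120, 91, 92, 120)


def build_toy_cds() -> str:
    """513-nt CDS with hand-placed codons for annotation tests.

    codon 2 = CAA (c.4C>T -> TAA nonsense), codon 3 = TGG (c.8G>A -> TAG),
    codon 4 = ACG (CpG context across codons 4-5: ...A[C]G...), rest alanine.
    """
    codons = ["ATG", "CAA", "TGG", "ACG"] + ["GCT"] * 166 + ["TAA"]
    cds = "".join(codons)
    assert len(cds) == sum(TOY_LENGTHS)
    return cds


@pytest.fixture(scope="session")
def toy_model():
    return make_model("TOY5", TOY_LENGTHS, build_toy_cds())


@pytest.fixture(scope="session")
def gene79():
    """Synthetic 79-exon transcript with the dystrophin domain layout."""
    return dmd_like_transcript(seed=1)


@pytest.fixture(scope="session")
def motif_lib():
    return default_library()
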