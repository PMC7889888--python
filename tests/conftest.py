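import numpy as np
import pytest

from uorfevolve.models import TranscriptModel


@pytest.fixture
def toy_models():
    """Three hand-checkable transcripts covering nORF, oORF, NTE."""
    return [
        TranscriptModel("t1", "g1", "ACCATGAAATAAGC", "ATGCCCTGA", ""),
        TranscriptModel("t2", "g2", "CAATGGC", "ATGTTAACC", ""),
        TranscriptModel("t3", "g3", "ATGCCC", "ATGAAATGA", ""),
    ]


@pytest.fixture
def four_taxon_tree():
    return "((A:1,B:1):1,(C:1,D:1):1);"


def random_transcript(rng: np.random.Generator, utr5_len=None) -> TranscriptModel:
    """A random transcript with a clean CDS (no internal in-frame stop)."""
    bases = "ACGT"
    stops = {"TAA", "TAG", "TGA"}
    sense = [a + b + c for a in bases for b in bases for c in bases
             if a + b + c not in stops]
    n5 = int(rng.integers(0, 60)) if utr5_len is None else utr5_len
    utr5 = "".join(bases[i] for i in rng.integers(4, size=n5))
    n_codons = int(rng.integers(2, 40))
    cds = "ATG" + "".join(
        sense[i] for i in rng.integers(len(sense), size=n_codons)
    ) + ("TAA", "TAG", "TGA")[rng.integers(3)]
    n3 = int(rng.integers(0, 60))
    utr3 = "".join(bases[i] for i in rng.integers(4, size=n3))
    return TranscriptModel("t", "g", utr5, cds, utr3)
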