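import numpy as np
import pytest

from metpool.core_io import Barcode, BarcodeLibrary, SampleMeta

NT = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(NT), size=length))


def make_library(rng: np.random.Generator, n: int, length: int) -> BarcodeLibrary:
    seqs = set()
    while len(seqs) < n:
        seqs.add(random_seq(rng, length))
    return BarcodeLibrary.from_barcodes(
        Barcode(id=f"B{i}", sequence=s, cell_line=f"line{i}")
        for i, s in enumerate(sorted(seqs))
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_library():
    return BarcodeLibrary.from_barcodes(
        [
            Barcode(id="A", sequence="ACGTACGTACGTACGTACGTACGTAC", cell_line="lineA"),
            Barcode(id="B", sequence="TTGGCCAATTGGCCAATTGGCCAATT", cell_line="lineB"),
            Barcode(id="C", sequence="GACGACGACGACTTCTTCTTCAAGAA", cell_line="lineC"),
        ]
    )


@pytest.fixture
def sample():
    return SampleMeta(sample_id="s1", mouse_id="m1", organ="brain")
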