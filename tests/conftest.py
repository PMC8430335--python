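import numpy as np
import pytest

from lrmine.io_core import SequenceRecord
from lrmine.synthetic_community import GenomeSpec, build_community

BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, length)])


@pytest.fixture(scope="session")
def small_community():
    """Two-genome community shared by read-level tests."""
    specs = [
        GenomeSpec(
            id="cA", length=80_000, gc_target=0.40,
            n_single_copy_markers=5, taxon_path=("Bacteria", "PhylumA"),
        ),
        GenomeSpec(
            id="cB", length=80_000, gc_target=0.60,
            n_single_copy_markers=5, taxon_path=("Bacteria", "PhylumB"),
        ),
    ]
    return build_community(specs, seed=424242)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def make_record(seq: str, rid: str = "r", source: str = "contig") -> SequenceRecord:
    return SequenceRecord(id=rid, seq=seq, source=source)
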