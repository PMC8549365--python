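import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from crisprtyper.arrays import Spacer, SpacerCatalog
from crisprtyper.matching import revcomp

REPEAT = "GTGTTCCCCGCGCCAGCGGGGATAAACCG"  # 29 nt, CRISPR-like direct repeat
PRIMER_F = "ACGTACCGGTTGACCTGAAGCTAG"
PRIMER_R = "TTGGCACCTAGGATCCTGAACGTC"


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def catalog():
    """Five well-separated spacers with the ancestral order 1..5."""
    seqs = [
        "ATCGGATTACCTGAAGGTCCATAGCTTGACAGTAG",
        "CCGTTAGGCATCAAGTCGTACGGATTTGCACCAAT",
        "GGATCCTTAGCACGTTAAGCCTGATCGGAATCTAC",
        "TTACGGAACCGTTAGATCCGATGGCTTAACGTCGA",
        "CAATGCCTAGGTTACGGATCATCGGTTAGCCATGA",
    ]
    spacers = [Spacer(id=i + 1, sequence=s) for i, s in enumerate(seqs)]
    return SpacerCatalog(spacers, REPEAT, reference_order=[1, 2, 3, 4, 5])


@pytest.fixture
def primers():
    return PRIMER_F, PRIMER_R


def build_read(catalog, primers, spacer_ids, reverse=False):
    """An error-free amplicon read for the given spacer order."""
    rep = catalog.repeat_sequence
    body = rep + "".join(catalog[i].sequence + rep for i in spacer_ids)
    seq = primers[0] + body + revcomp(primers[1])
    return revcomp(seq) if reverse else seq


@pytest.fixture
def make_read(catalog, primers):
    def _make(spacer_ids, reverse=False):
        return build_read(catalog, primers, spacer_ids, reverse=reverse)

    return _make
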