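import numpy as np
import pytest

from estmir.folding import FoldResult, ViennaBackend
from estmir.seqio import reverse_complement


@pytest.fixture(scope="session")
def backend():
    return ViennaBackend()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def perfect_hairpin(mature: str, loop: str) -> FoldResult:
    """Handcrafted perfect stem-loop: mature + loop + revcomp(mature).

    The structure is written directly (every mature position paired to
    its reverse-complement partner), bypassing any folding backend, so
    fixtures built from it are fully deterministic.
    """
    star = reverse_complement(mature, "rna")
    seq = mature + loop + star
    structure = "(" * len(mature) + "." * len(loop) + ")" * len(mature)
    return FoldResult(sequence=seq, structure=structure, mfe=-30.0)
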