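import numpy as np
import pytest

from tachseq import GenomeSequence, TagLibrary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_genome():
    return GenomeSequence(
        {
            "c1": "ACGTACGTAC" * 100,  # 1 kb
            "c2": "GGGCCC" * 100,  # 600 bp, pure GC
        }
    )


def make_library(contig, cuts_plus=(), cuts_minus=(), width=36, label="toy"):
    """Build a tag library from explicit cut-site positions."""
    contigs, starts, ends, strands = [], [], [], []
    for c in cuts_plus:
        contigs.append(contig); starts.append(c); ends.append(c + width); strands.append("+")
    for c in cuts_minus:
        contigs.append(contig); starts.append(c - width); ends.append(c); strands.append("-")
    return TagLibrary.from_arrays(contigs, starts, ends, strands, label=label)


@pytest.fixture
def make_lib():
    return make_library
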