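import numpy as np
import pytest

from wavecall.genome_io import GeneModel, IntronSignal


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def plus_gene():
    """30 Kb plus-strand gene: 0.5 Kb exons at both ends, intron between."""
    return GeneModel(
        "GPLUS", "chr1", "+", tss=0, tes=30_000,
        exons=((0, 500), (29_500, 30_000)),
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        "GMINUS", "chr1", "-", tss=30_000, tes=0,
        exons=((0, 500), (29_500, 30_000)),
    )


def make_signal(gene_id="G", n_bins=400, values=None, start_kb=0.0):
    offs = start_kb + np.arange(n_bins) * 0.1
    if values is None:
        values = np.zeros(n_bins)
    return IntronSignal(gene_id, offs, np.asarray(values, dtype=float))
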