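import numpy as np
import pytest

from mamlin.iofmt import CountMatrix


@pytest.fixture
def tiny_counts() -> CountMatrix:
    """3 genes x 2 cells with known entries."""
    return CountMatrix(
        counts=np.array([[0, 0], [7, 0], [1, 2]]),
        gene_ids=["g1", "g2", "g3"],
        sample_ids=["c1", "c2"],
        gene_symbols=["Krt14", "Acta2", "Elf5"],
    )


def make_counts(counts, gene_prefix="g", sample_prefix="s", **kw) -> CountMatrix:
    counts = np.asarray(counts)
    return CountMatrix(
        counts=counts,
        gene_ids=[f"{gene_prefix}{i}" for i in range(counts.shape[0])],
        sample_ids=[f"{sample_prefix}{j}" for j in range(counts.shape[1])],
        **kw,
    )


@pytest.fixture
def counts_factory():
    return make_counts
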