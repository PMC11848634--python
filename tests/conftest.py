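import numpy as np
import pytest

from contactseer.io_formats import ContactStack, ExpressionMatrix, GenomicFeature
import scipy.sparse as sp


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_expr():
    genes = [
        GenomicFeature("gA", "chr1", 0, 10_000),
        GenomicFeature("gB", "chr1", 20_000, 35_000),
        GenomicFeature("gC", "chr1", 50_000, 120_000),
    ]
    counts = np.array([[5, 0, 2], [1, 3, 0], [0, 2, 4], [2, 2, 2]], dtype=float)
    return ExpressionMatrix(counts, genes, [f"c{i}" for i in range(4)],
                            ["t0", "t0", "t1", "t1"])


def make_stack(maps, binsize=10_000, chrom="chr1", labels=None):
    maps = [np.asarray(m, dtype=float) for m in maps]
    k = maps[0].shape[0]
    bins = [GenomicFeature(f"bin{i}", chrom, i * binsize, (i + 1) * binsize)
            for i in range(k)]
    return ContactStack(binsize, bins, [sp.csr_matrix(m) for m in maps],
                        [f"h{i}" for i in range(len(maps))],
                        labels or ["unknown"] * len(maps))


@pytest.fixture
def stack_factory():
    return make_stack
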