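import numpy as np
import pandas as pd
import pytest

from epicrosstalk.io import ExpressionMatrix, MethylationTable, PeakSet, SampleInfo


@pytest.fixture
def rna_samples():
    return [SampleInfo(f"s{i}", 30 * (i + 1), 1, "rna") for i in range(6)]


@pytest.fixture
def small_matrix(rna_samples):
    rng = np.random.default_rng(42)
    values = rng.uniform(0.0, 50.0, size=(10, 6))
    return ExpressionMatrix([f"g{i}" for i in range(10)], rna_samples, values)


@pytest.fixture
def toy_peaks():
    df = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [100, 500, 50],
        "end": [200, 900, 150],
        "strand": ["+", "-", "."],
        "gene_id": ["gA", "gB", None],
        "peak_id": ["p1", "p2", "p3"],
    })
    return PeakSet(df)


def make_methylation(sample_id, chrom, positions, levels, coverage=10):
    n = len(positions)
    return MethylationTable(pd.DataFrame({
        "sample_id": sample_id, "chrom": chrom,
        "pos": list(positions), "meth_level": list(levels),
        "coverage": [coverage] * n,
    }))
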