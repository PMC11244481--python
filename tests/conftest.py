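import numpy as np
import pytest

from ginfunnel.data_io import ExpressionMatrix, GenotypeMatrix, SnpRecord
from ginfunnel.simulate import SimConfig, simulate_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """12 samples x 6 SNPs, fixed calls, no missing data."""
    calls = np.array(
        [
            [0, 1, 2, 0, 1, 2],
            [1, 1, 0, 2, 0, 1],
            [2, 0, 1, 1, 2, 0],
            [0, 2, 2, 0, 1, 1],
            [1, 0, 0, 1, 0, 2],
            [2, 1, 1, 2, 2, 0],
            [0, 0, 2, 1, 1, 1],
            [1, 2, 0, 0, 2, 2],
            [2, 1, 1, 2, 0, 0],
            [0, 0, 2, 1, 1, 1],
            [1, 2, 0, 0, 2, 2],
            [2, 1, 1, 2, 0, 0],
        ],
        dtype=np.int8,
    )
    snps = [SnpRecord(f"s{j}", "chr1" if j < 3 else "chr2", 1000 * (j % 3 + 1), "A", "G") for j in range(6)]
    return GenotypeMatrix(samples=[f"S{i:02d}" for i in range(12)], snps=snps, calls=calls)


@pytest.fixture
def desk_genotypes() -> GenotypeMatrix:
    """Simulated 120 x 400 panel without structure, deterministic."""
    cfg = SimConfig(n_samples=120, n_snps=400, n_chrom=4, n_subpops=1, seed=7)
    return simulate_genotypes(cfg)


def expr_from_values(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(genes=genes, samples=samples, values=values)
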