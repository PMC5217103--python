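import numpy as np
import pytest

from regulonscope.core import GeneModel, GenomeAnnotation
from regulonscope.simulate import SimConfig


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Hand-built annotation with a divergent pair (g2-, g3+) 3 kb apart."""
    genes = [
        GeneModel("g1", "chrI", "+", 10_000, 12_000),
        GeneModel("g2", "chrI", "-", 30_000, 32_000),   # TSS at 31_999
        GeneModel("g3", "chrI", "+", 35_000, 37_000),   # TSS at 35_000
        GeneModel("g4", "chrII", "-", 5_000, 8_000),
    ]
    return GenomeAnnotation(genes=genes, chrom_sizes={"chrI": 100_000, "chrII": 50_000})


@pytest.fixture
def sim_cfg() -> SimConfig:
    return SimConfig(seed=7)


def flat_annotation(n_genes: int, gene_len: int = 300, gap: int = 200) -> GenomeAnnotation:
    """A dense, packing-free annotation for DE-table tests."""
    step = gene_len + gap
    genes = [
        GeneModel(f"g{i:05d}", "chrI", "+", i * step, i * step + gene_len)
        for i in range(n_genes)
    ]
    return GenomeAnnotation(genes=genes, chrom_sizes={"chrI": n_genes * step + gap})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
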