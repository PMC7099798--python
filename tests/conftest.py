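import numpy as np
import pandas as pd
import pytest

from imprintscape.genome_io import GeneSet, GenomeAnnotation


@pytest.fixture
def tiny_genome() -> GenomeAnnotation:
    """Two chromosomes, six hand-placed genes."""
    genes = pd.DataFrame(
        {
            "gene_id": ["g1", "g2", "g3", "g4", "g5", "g6"],
            "symbol": ["A1", "A2", "B1", "B2", "C1", "C2"],
            "chrom": ["chr1", "chr1", "chr1", "chr2", "chr2", "chr2"],
            "start": [10, 999_999, 1_000_000, 100, 600_000, 1_400_000],
            "end": [500, 1_000_300, 1_000_900, 900, 601_000, 1_401_000],
            "strand": ["+", "-", "+", "+", "-", "+"],
        }
    )
    return GenomeAnnotation(
        chromosomes=[("chr1", 3_000_000), ("chr2", 2_500_000)], genes=genes
    )


@pytest.fixture
def random_genome() -> GenomeAnnotation:
    """50 uniformly placed genes on one 10 Mb chromosome (fixed seed)."""
    rng = np.random.default_rng(42)
    starts = np.sort(rng.integers(0, 9_990_000, 50))
    genes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(50)],
            "symbol": [f"S{i}" for i in range(50)],
            "chrom": "chr1",
            "start": starts,
            "end": starts + 1000,
            "strand": "+",
        }
    )
    return GenomeAnnotation(chromosomes=[("chr1", 10_000_000)], genes=genes)


@pytest.fixture
def gene_set_factory():
    def make(name, symbols):
        return GeneSet(name=name, members=frozenset(s.upper() for s in symbols))

    return make
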