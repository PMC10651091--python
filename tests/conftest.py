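import numpy as np
import pytest

from enhancerscan.intervals import GeneModel, GenomeAnnotation, GenomicInterval


@pytest.fixture
def toy_annotation():
    """Four well-separated genes on two chromosomes."""
    genes = [
        GeneModel("geneA", GenomicInterval("chr1", 10_000, 20_000, "+")),
        GeneModel("geneB", GenomicInterval("chr1", 40_000, 50_000, "-")),
        GeneModel("geneC", GenomicInterval("chr1", 80_000, 90_000, "+")),
        GeneModel("geneD", GenomicInterval("chr2", 30_000, 45_000, "+")),
    ]
    return GenomeAnnotation(genes, chrom_sizes={"chr1": 120_000, "chr2": 100_000})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_annotation(rng, n_genes=20, chrom="chr1", size=500_000, min_gap=100):
    """Non-overlapping random genes on one chromosome (test helper)."""
    genes = []
    pos = 0
    for i in range(n_genes):
        pos += min_gap + int(rng.integers(0, size // (4 * n_genes)))
        length = int(rng.integers(500, size // (2 * n_genes)))
        end = min(pos + length, size - 1)
        if end <= pos:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneModel(f"g{i:03d}", GenomicInterval(chrom, pos, end, strand)))
        pos = end
    return GenomeAnnotation(genes, chrom_sizes={chrom: size})
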