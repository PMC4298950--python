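import numpy as np
import pandas as pd
import pytest

from stemqtl.annotation import FeatureAnnotation
from stemqtl.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def default_dataset():
    """One full synthetic study at the default conditions, shared read-only."""
    return simulate_dataset(SimulationConfig(seed=11))


@pytest.fixture()
def tiny_annotation():
    """Hand-built two-gene annotation with known intron structure.

    geneA (chr1, 1000-9000): txA1 spans the gene with exons
    [1000,2000), [3000,4000), [6000,9000); geneB (chr2, 500-1500) is a
    single-exon gene.
    """
    genes = pd.DataFrame(
        [("geneA", "chr1", 1000, 9000), ("geneB", "chr2", 500, 1500)],
        columns=["gene_id", "chrom", "start", "end"],
    )
    txs = pd.DataFrame(
        [("txA1", "geneA", "chr1", 1000, 9000), ("txB1", "geneB", "chr2", 500, 1500)],
        columns=["transcript_id", "gene_id", "chrom", "start", "end"],
    )
    exons = pd.DataFrame(
        [
            ("exA1", "txA1", "geneA", "chr1", 1000, 2000),
            ("exA2", "txA1", "geneA", "chr1", 3000, 4000),
            ("exA3", "txA1", "geneA", "chr1", 6000, 9000),
            ("exB1", "txB1", "geneB", "chr2", 500, 1500),
        ],
        columns=["exon_id", "transcript_id", "gene_id", "chrom", "start", "end"],
    )
    return FeatureAnnotation(genes=genes, transcripts=txs, exons=exons)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
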