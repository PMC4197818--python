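import numpy as np
import pandas as pd
import pytest

from capmeth.genome_model import GeneModel, GenomicInterval
from capmeth.synthetic_data import SimulationConfig, make_toy_genome


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(
        chrom_sizes={"chr1": 2_000_000, "chr2": 1_000_000},
        n_genes=60,
        n_cgis=30,
        n_enhancers=20,
        n_fragments=100_000,
        seed=7,
        write_fasta=False,
    )


@pytest.fixture(scope="session")
def small_toy(small_config):
    return make_toy_genome(small_config)


@pytest.fixture
def plus_gene():
    return GeneModel(
        gene_id="gA", chrom="chr1", strand="+", start=10_000, end=20_000,
        cds_start=10_500, cds_end=19_500,
        exons=[(10_000, 11_000), (12_000, 13_000), (18_000, 20_000)],
    )


@pytest.fixture
def minus_gene():
    return GeneModel(
        gene_id="gB", chrom="chr1", strand="-", start=10_000, end=20_000,
        cds_start=10_500, cds_end=19_500,
        exons=[(10_000, 11_000), (12_000, 13_000), (18_000, 20_000)],
    )


def make_reads(rows):
    """rows: iterable of (chrom, start, end, strand)."""
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"]).astype(
        {"start": np.int64, "end": np.int64}
    )
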