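import numpy as np
import pytest

import nifregulon as nr
from nifregulon.io_formats import GeneRecord, GenomeAnnotation
from nifregulon.synthetic_data import IslandSpec, SimulationSpec, generate_genome


@pytest.fixture(scope="session")
def table1_path():
    return nr.data_path("table1_nif_island.tsv")


@pytest.fixture(scope="session")
def table1(table1_path):
    return nr.read_table1(table1_path)


@pytest.fixture(scope="session")
def table3_path():
    return nr.data_path("table3_core_genome.tsv")


@pytest.fixture(scope="session")
def small_spec():
    """A 120-gene genome with a 20-gene island: 5 operons of 17 genes total."""
    return SimulationSpec(
        n_genes=120,
        island=IslandSpec(
            start_index=30,
            n_island_genes=20,
            n_regulon_in_island=17,
            operon_structure=(4, 2, 5, 1, 5),
        ),
        island_span_bp=None,
        n_regulon_outside=20,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_genome(small_spec)


def make_annotation(strands, gene_len=500, gap=100, start=1000):
    """Uniformly spaced genes for tests that only care about order/strand."""
    genes = []
    pos = start
    for i, strand in enumerate(strands):
        genes.append(
            GeneRecord(locus_id=f"G{i:04d}", start=pos, end=pos + gene_len, strand=strand)
        )
        pos += gene_len + gap
    return GenomeAnnotation("test", genes, pos + 1000)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
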