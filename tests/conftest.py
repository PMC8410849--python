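import numpy as np
import pytest

from strepfold.conservation import OrthologTable
from strepfold.genome import CompartmentPartition, GeneRecord


@pytest.fixture
def printed_partition():
    """Partition with the printed rDNA coordinates on an ~6.7 Mb chromosome."""
    return CompartmentPartition(
        chrom_length=6_700_000,
        first_rdna_start=1_469_670,
        last_rdna_end=5_807_629,
        oriC_pos=3_600_000,
    )


@pytest.fixture
def toy_genes():
    """Ten 1-kb genes spaced every 2 kb."""
    return [
        GeneRecord(f"g{i}", 2000 * i + 1, 2000 * i + 1000, "+" if i % 2 else "-")
        for i in range(10)
    ]


def make_ortholog_table(mappings: dict[str, dict[int, int]], n_genes: int):
    table = OrthologTable(gene_ids=[f"g{i}" for i in range(n_genes)])
    for name, mapping in mappings.items():
        table.add_genome(name, mapping)
    return table


@pytest.fixture
def colinear_table():
    """Reference vs one fully co-linear target of 10 genes."""
    return make_ortholog_table({"t": {i: i for i in range(10)}}, 10)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
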