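import numpy as np
import pandas as pd
import pytest

from xci_scstruct.contacts import ContactRecord, ContactTable, informative_contacts
from xci_scstruct.cdp import compute_cdp_table
from xci_scstruct.genome import ChromSizes
from xci_scstruct.simulate import ContactGeneratorSpec, simulate_population


@pytest.fixture(scope="session")
def genome() -> ChromSizes:
    return ChromSizes.default()


@pytest.fixture()
def tiny_table(genome) -> ContactTable:
    """Ten hand-placed contacts across two cells, both chromosomes, all alleles."""
    recs = [
        ContactRecord("c1", "chr1", 100, "chr1", 600_000, "hap1"),
        ContactRecord("c1", "chr1", 100, "chr1", 600_000, "hap1"),   # duplicate
        ContactRecord("c1", "chr1", 5_000, "chr1", 5_900, "hap2"),   # distance 900
        ContactRecord("c1", "chr1", 0, "chrX", 1_000, "ambiguous"),  # trans
        ContactRecord("c1", "chrX", 10_000, "chrX", 2_010_000, "hap1"),
        ContactRecord("c2", "chr1", 1_000_000, "chr1", 9_000_000, "hap2"),
        ContactRecord("c2", "chrX", 0, "chrX", 1_024, "hap1"),       # distance 1024
        ContactRecord("c2", "chrX", 50, "chrX", 2_098, "hap2"),      # distance 2048
        ContactRecord("c2", "chr1", 42, "chr1", 1_542, "ambiguous"), # distance 1500
        ContactRecord("c2", "chr1", 7, "chr1", 1_006, "hap1"),       # distance 999
    ]
    return ContactTable.from_records(recs, genome)


@pytest.fixture(scope="session")
def null_population():
    """300 synthetic null cells: both alleles of chr1 and chrX drawn from the
    same power-law decay (no bipartite structure, no mitotic cells)."""
    spec = ContactGeneratorSpec(n_min=200, n_max=2000, mitotic_fraction=0.0, seed=11)
    table, truth = simulate_population(spec, 300, bipartite_fraction=0.0)
    return spec, table, truth


@pytest.fixture(scope="session")
def null_cdp_table(null_population) -> pd.DataFrame:
    _, table, _ = null_population
    return compute_cdp_table(informative_contacts(table))
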