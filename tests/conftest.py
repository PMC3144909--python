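import numpy as np
import pytest

from orthoscreen.mirna_targets import NnParameterTable
from orthoscreen.seqio import GeneRecord, reverse_complement


@pytest.fixture(scope="session")
def nn_params() -> NnParameterTable:
    return NnParameterTable.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20110727)


def make_record(oriented: str, cds_start: int, cds_end: int,
                strand: str = "+", gene: str = "GENE",
                species: str = "panda",
                protein: str | None = None) -> GeneRecord:
    """Build a GeneRecord from a strand-oriented locus; for minus strand the
    stored contig is the reverse complement, as on disk."""
    contig = oriented if strand == "+" else reverse_complement(oriented)
    return GeneRecord(gene_symbol=gene, species=species, protein_seq=protein,
                      contig_seq=contig, cds_start=cds_start,
                      cds_end=cds_end, strand=strand)
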