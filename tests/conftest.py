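import pytest

from toltrace.formats_io import DomainHit, GeneRecord
from toltrace.role_catalog import RoleAssignment


@pytest.fixture
def make_gene():
    """Factory for GeneRecords with compact defaults."""

    def _make(gene_id, start, end=None, replicon="rep1", genome="gtest",
              strand="+", rank=0, product="", protein_length=0, protein_seq=None):
        if end is None:
            end = start + 899
        return GeneRecord(
            gene_id=gene_id, genome_id=genome, replicon_id=replicon,
            start=start, end=end, strand=strand, rank=rank, product=product,
            protein_length=protein_length, protein_seq=protein_seq,
        )

    return _make


@pytest.fixture
def make_role():
    """Factory for RoleAssignments backed by a dummy supporting hit."""

    def _make(gene_id, role):
        if role == "none":
            return RoleAssignment(gene_id=gene_id, role="none")
        hit = DomainHit(
            gene_id=gene_id, pfam_acc="PF00000", bitscore=100.0,
            evalue=1e-20, env_start=1, env_end=50,
        )
        return RoleAssignment(gene_id=gene_id, role=role, supporting_hits=(hit,))

    return _make
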