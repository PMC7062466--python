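import pytest

from dualguide import (
    FixtureSpec,
    GeneModel,
    GenomeSequence,
    TranscriptModel,
    annotate_positions,
    enumerate_guides,
    make_fixture_genome,
)


@pytest.fixture(scope="session")
def fixture_genome():
    """Small deterministic synthetic genome: 3 genes, one planted duplication."""
    spec = FixtureSpec(n_genes=3, n_duplications=1)
    return make_fixture_genome(spec, seed=11)


@pytest.fixture(scope="session")
def annotated_candidates(fixture_genome):
    genome, genes, _ = fixture_genome
    out = {}
    for model in genes:
        cands = enumerate_guides(genome, model)
        annotate_positions(cands, model)
        out[model.gene_id] = cands
    return out


def single_exon_gene(seq: str, gene_id: str = "g1", contig: str = "c1",
                     strand: str = "+", cds: tuple[int, int] | None = None):
    """One-transcript, one-exon gene spanning the whole sequence by default."""
    if cds is None:
        cds = (0, len(seq) - len(seq) % 3)
    tx = TranscriptModel(f"{gene_id}.t1", contig, strand, [cds], start=0, end=len(seq))
    model = GeneModel(gene_id, contig, strand, [tx])
    return GenomeSequence({contig: seq}), model
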