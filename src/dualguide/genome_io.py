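"""Genome and annotation I/O, stranded gene models, and synthetic fixture genomes.

Internal coordinates are 0-based half-open throughout; GFF3 I/O converts
from/to the 1-based closed convention of the format. A gene model carries one
or more transcripts, each a list of CDS exons ordered 5'->3' in *transcript*
orientation (descending genomic start on the minus strand), plus gene-level
anchors used by guide scoring: the transcription start site (5'-most
transcript start over all isoforms) and the start codon of the 5'-most CDS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (duplicate ids, illegal characters)."""


class AnnotationError(ValueError):
    """Raised when GFF3 features are inconsistent with the genome."""


@dataclass(frozen=True)
class GenomeSequence:
    """A genome as a mapping contig-id -> uppercase nucleotide string."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not cid:
                raise FastaFormatError("empty contig id")
            bad = set(seq) - VALID_BASES
            if bad:
                raise FastaFormatError(
                    f"contig {cid!r} contains illegal characters {sorted(bad)}"
                )

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


NOT_IN_CDS = None  # sentinel returned by spliced_cds_offset for non-coding positions


@dataclass
class TranscriptModel:
    """One transcript: CDS exons in transcript 5'->3' order plus genomic extent."""

    transcript_id: str
    contig: str
    strand: str
    cds_exons: list[tuple[int, int]]  # genomic half-open, ordered 5'->3' in tx orientation
    start: int = 0  # genomic transcript extent (includes UTRs when annotated)
    end: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise AnnotationError(f"{self.transcript_id}: bad strand {self.strand!r}")
        genomic = sorted(self.cds_exons)
        for (a0, a1), (b0, b1) in zip(genomic, genomic[1:]):
            if b0 < a1:
                raise AnnotationError(f"{self.transcript_id}: overlapping CDS exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if list(self.cds_exons) != expected:
            raise AnnotationError(
                f"{self.transcript_id}: CDS exons not in transcript 5'->3' order"
            )
        if not self.end:
            self.end = max(e for _, e in genomic) if genomic else 0
            self.start = min(s for s, _ in genomic) if genomic else 0

    @property
    def spliced_cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_exons)

    @property
    def start_codon(self) -> tuple[int, int]:
        """Genomic half-open interval of the first 3 coding bases (may span exons)."""
        positions = []
        for s, e in self.cds_exons:
            exon = range(s, e) if self.strand == "+" else range(e - 1, s - 1, -1)
            for p in exon:
                positions.append(p)
                if len(positions) == 3:
                    return (min(positions), max(positions) + 1)
        raise AnnotationError(f"{self.transcript_id}: CDS shorter than a codon")


def spliced_cds_offset(model: TranscriptModel, genomic_pos: int) -> int | None:
    """Coding offset (bp from the CDS start, 0-based) of a genomic position.

    Returns ``NOT_IN_CDS`` (None) for positions in introns, UTRs or outside the
    transcript. Strand-aware: on the minus strand the first CDS base is the
    highest genomic coordinate of the 5'-most exon.
    """
    acc = 0
    for s, e in model.cds_exons:
        if s <= genomic_pos < e:
            if model.strand == "+":
                return acc + (genomic_pos - s)
            return acc + (e - 1 - genomic_pos)
        acc += e - s
    return NOT_IN_CDS


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    transcripts: list[TranscriptModel]

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: gene without transcripts")
        for t in self.transcripts:
            if t.contig != self.contig or t.strand != self.strand:
                raise AnnotationError(
                    f"{self.gene_id}: transcript {t.transcript_id} on a different "
                    "contig or strand"
                )

    @property
    def tss(self) -> int:
        """5'-most transcript start across isoforms (genomic position)."""
        if self.strand == "+":
            return min(t.start for t in self.transcripts)
        return max(t.end for t in self.transcripts) - 1

    @property
    def start_codon(self) -> tuple[int, int]:
        """Start codon of the 5'-most CDS start over all isoforms."""
        codons = [t.start_codon for t in self.transcripts]
        if self.strand == "+":
            return min(codons)
        return max(codons, key=lambda iv: iv[1])

    @property
    def start_codons(self) -> list[tuple[int, int]]:
        """Distinct isoform start-codon intervals (used by the start-codon filter)."""
        return sorted({t.start_codon for t in self.transcripts})

    @property
    def reference_transcript(self) -> TranscriptModel:
        """Longest spliced CDS; ties broken by transcript id."""
        return max(self.transcripts, key=lambda t: (t.spliced_cds_length, t.transcript_id))

    @property
    def reference_cds_length(self) -> int:
        return self.reference_transcript.spliced_cds_length

    @property
    def span(self) -> tuple[int, int]:
        """Genomic extent over all transcripts."""
        return (min(t.start for t in self.transcripts), max(t.end for t in self.transcripts))


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> GenomeSequence:
    """Read a (multi-record) FASTA file into a GenomeSequence.

    Sequences are canonicalized to uppercase; duplicate record ids and
    characters outside {A,C,G,T,N} raise :class:`FastaFormatError` naming the
    offending line.
    """
    path = Path(path)
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in contigs:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - VALID_BASES
        if bad:
            lineno = _find_bad_line(path, bad)
            raise FastaFormatError(
                f"{path}:{lineno}: illegal characters {sorted(bad)} in record {rec.id!r}"
            )
        contigs[rec.id] = seq
    if not contigs:
        logger.warning("FASTA file %s contains no records", path)
    return GenomeSequence(contigs)


def _find_bad_line(path: Path, bad: set[str]) -> int:
    badset = {c for b in bad for c in (b.upper(), b.lower())}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">"):
                continue
            if set(line.strip()) & badset:
                return i
    return 0


def write_fasta(genome: GenomeSequence, path: str | Path) -> None:
    with open(path, "w") as fh:
        for cid, seq in genome.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, genome: GenomeSequence) -> list[GeneModel]:
    """Parse gene/mRNA/CDS features from GFF3 into GeneModels.

    1-based closed GFF3 coordinates become 0-based half-open. Genes without any
    CDS-bearing transcript are skipped with a warning; transcripts whose
    spliced CDS length is not divisible by 3 are kept with a warning. CDS
    features on unknown contigs or outside contig bounds raise
    :class:`AnnotationError`.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        transcripts: list[TranscriptModel] = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons: list[tuple[int, int]] = []
            for cds in db.children(mrna, featuretype="CDS", order_by="start"):
                if cds.seqid not in genome:
                    raise AnnotationError(
                        f"CDS of {mrna.id} references unknown contig {cds.seqid!r}"
                    )
                s, e = cds.start - 1, cds.end
                if s < 0 or e > len(genome[cds.seqid]):
                    raise AnnotationError(
                        f"CDS of {mrna.id} out of bounds on contig {cds.seqid}"
                    )
                exons.append((s, e))
            if not exons:
                continue
            if gene.strand == "-":
                exons = sorted(exons)[::-1]
            else:
                exons = sorted(exons)
            tx = TranscriptModel(
                transcript_id=mrna.id,
                contig=mrna.seqid,
                strand=gene.strand,
                cds_exons=exons,
                start=mrna.start - 1,
                end=mrna.end,
            )
            if tx.spliced_cds_length % 3 != 0:
                logger.warning(
                    "transcript %s: spliced CDS length %d not divisible by 3",
                    tx.transcript_id,
                    tx.spliced_cds_length,
                )
            transcripts.append(tx)
        if not transcripts:
            logger.warning("gene %s has no CDS-bearing transcript; skipped", gene.id)
            continue
        genes.append(
            GeneModel(
                gene_id=gene.id,
                contig=gene.seqid,
                strand=gene.strand,
                transcripts=transcripts,
            )
        )
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    """Write gene/mRNA/CDS features (0-based half-open -> 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span
            fh.write(
                f"{g.contig}\tdualguide\tgene\t{gs + 1}\t{ge}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for t in g.transcripts:
                fh.write(
                    f"{g.contig}\tdualguide\tmRNA\t{t.start + 1}\t{t.end}\t.\t"
                    f"{g.strand}\t.\tID={t.transcript_id};Parent={g.gene_id}\n"
                )
                for i, (s, e) in enumerate(sorted(t.cds_exons)):
                    fh.write(
                        f"{g.contig}\tdualguide\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t"
                        f"ID={t.transcript_id}.cds{i};Parent={t.transcript_id}\n"
                    )


# ---------------------------------------------------------------------------
# Synthetic fixture genomes
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Parameters of a synthetic genome with known ground truth.

    Genes are laid out on one contig, alternating strand, each with
    ``exons_per_gene`` CDS exons separated by introns and flanked by short
    UTRs. Total CDS length per gene is kept divisible by 3 and starts with
    ATG. ``n_duplications`` protospacer+PAM 23-mers from coding sequence are
    copied into intergenic space (planted off-targets); ``n_restriction_sites``
    BbsI/BsaI recognition sites are embedded into coding sequence.
    """

    n_genes: int = 5
    exons_per_gene: int = 3
    exon_length: int = 300
    intron_length: int = 120
    utr_length: int = 60
    intergenic: int = 400
    gc: float = 0.43
    n_duplications: int = 0
    n_restriction_sites: int = 0
    contig_id: str = "chr_sim"
    contig_length: int | None = None  # fixed contig size; error if genes do not fit

    def validate(self) -> None:
        for name in ("n_genes", "exons_per_gene", "exon_length", "intron_length",
                     "utr_length", "intergenic"):
            if getattr(self, name) <= 0:
                raise ValueError(f"fixture parameter {name} must be positive")
        if not 0.0 < self.gc < 1.0:
            raise ValueError("fixture GC content must be in (0, 1)")


@dataclass
class FixtureTruth:
    """Ground truth planted into a fixture genome."""

    duplications: list[dict] = field(default_factory=list)  # {kmer, source, copy}
    restriction_sites: list[dict] = field(default_factory=list)  # {enzyme, motif, pos}
    gene_cds: dict[str, str] = field(default_factory=dict)  # spliced CDS per gene


_RESTRICTION_MOTIFS = [("BbsI", "GAAGAC"), ("BsaI", "GGTCTC")]


def make_fixture_genome(
    spec: FixtureSpec, seed: int
) -> tuple[GenomeSequence, list[GeneModel], FixtureTruth]:
    """Generate a deterministic synthetic genome + annotation + ground truth."""
    spec.validate()
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2]
    )
    bases = np.array(list("ACGT"))

    def rand_seq(n: int) -> str:
        return "".join(bases[rng.choice(4, size=n, p=p)])

    chunks: list[str] = []
    pos = 0
    genes: list[GeneModel] = []
    truth = FixtureTruth()

    def emit(seq: str) -> tuple[int, int]:
        nonlocal pos
        chunks.append(seq)
        iv = (pos, pos + len(seq))
        pos += len(seq)
        return iv

    for gi in range(spec.n_genes):
        emit(rand_seq(spec.intergenic))
        strand = "+" if gi % 2 == 0 else "-"
        gene_id = f"gene{gi + 1:02d}"
        # exon lengths: jitter around exon_length, total divisible by 3
        lens = [
            int(spec.exon_length + rng.integers(-spec.exon_length // 4,
                                                spec.exon_length // 4 + 1))
            for _ in range(spec.exons_per_gene)
        ]
        lens = [max(9, L) for L in lens]
        excess = sum(lens) % 3
        lens[-1] -= excess
        cds = "ATG" + rand_seq(sum(lens) - 3)
        if strand == "-":
            cds_genomic = revcomp(cds)
        else:
            cds_genomic = cds
        # split genomic-strand CDS into exons (genomic order)
        glens = lens if strand == "+" else lens[::-1]
        tx_start, _ = emit(rand_seq(spec.utr_length))
        exon_ivs: list[tuple[int, int]] = []
        off = 0
        for i, L in enumerate(glens):
            if i > 0:
                emit(rand_seq(spec.intron_length))
            exon_ivs.append(emit(cds_genomic[off : off + L]))
            off += L
        _, tx_end = emit(rand_seq(spec.utr_length))
        ordered = exon_ivs if strand == "+" else exon_ivs[::-1]
        tx = TranscriptModel(
            transcript_id=f"{gene_id}.t1",
            contig=spec.contig_id,
            strand=strand,
            cds_exons=ordered,
            start=tx_start,
            end=tx_end,
        )
        genes.append(
            GeneModel(gene_id=gene_id, contig=spec.contig_id, strand=strand,
                      transcripts=[tx])
        )
        truth.gene_cds[gene_id] = cds
    emit(rand_seq(spec.intergenic))
    contig = "".join(chunks)

    # plant restriction sites inside coding sequence (overwrites CDS bases)
    seq = list(contig)
    for i in range(spec.n_restriction_sites):
        enzyme, motif = _RESTRICTION_MOTIFS[i % len(_RESTRICTION_MOTIFS)]
        g = genes[int(rng.integers(0, len(genes)))]
        exon = g.transcripts[0].cds_exons[0]
        lo, hi = exon[0] + 6, exon[1] - len(motif) - 3  # keep ATG intact
        if hi <= lo:
            continue
        at = int(rng.integers(lo, hi))
        seq[at : at + len(motif)] = motif
        truth.restriction_sites.append({"enzyme": enzyme, "motif": motif, "pos": at})
    contig = "".join(seq)

    # plant duplications: copy a coding protospacer+PAM 23-mer into intergenic space
    seq = list(contig)
    used: list[tuple[int, int]] = []
    for i in range(spec.n_duplications):
        src = _find_protospacer_window(contig, genes, rng)
        if src is None:
            break
        kmer = contig[src : src + 23]
        copy_at = None
        for _ in range(50):
            at = int(rng.integers(5, spec.intergenic - 30))
            if i % 2 == 1:
                at += len(contig) - spec.intergenic
            if all(at + 23 <= u0 or at >= u1 for u0, u1 in used):
                copy_at = at
                break
        if copy_at is None:
            break
        used.append((copy_at, copy_at + 23))
        seq[copy_at : copy_at + 23] = kmer
        truth.duplications.append({"kmer": kmer, "source": src, "copy": copy_at})
    contig = "".join(seq)

    if spec.contig_length is not None:
        if len(contig) > spec.contig_length:
            raise ValueError(
                f"infeasible fixture: genes need {len(contig)} bp but contig_length "
                f"is {spec.contig_length}"
            )
        contig += rand_seq(spec.contig_length - len(contig))
    genome = GenomeSequence({spec.contig_id: contig})
    return genome, genes, truth


def _find_protospacer_window(contig: str, genes: list[GeneModel], rng) -> int | None:
    """Genomic start of a plus-strand N20+NGG window fully inside a CDS exon."""
    order = rng.permutation(len(genes))
    for gi in order:
        for s, e in genes[int(gi)].transcripts[0].cds_exons:
            starts = list(range(s + 3, e - 23))  # avoid the ATG
            rng.shuffle(starts)
            for st in starts:
                if contig[st + 21 : st + 23] == "GG":
                    return st
    return None
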