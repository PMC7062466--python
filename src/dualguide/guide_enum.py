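"""Enumeration of SpCas9 candidate protospacers cutting inside coding sequence.

A candidate is a 20-nt protospacer immediately 5' of an NGG PAM, on either
strand, whose predicted blunt cut site (between protospacer bases 17 and 18,
3 bp 5' of the PAM) falls inside a CDS exon of at least one transcript of the
gene. CDS membership is decided by the cut site alone: protospacers that
overhang into introns or UTRs are legitimate candidates as long as the cut is
coding. Windows containing N are excluded.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .genome_io import GeneModel, GenomeSequence, revcomp, spliced_cds_offset

PROTOSPACER_LEN = 20
PAM_LEN = 3
CUT_OFFSET = 17  # cut between protospacer bases 17 and 18 (1-based)


@dataclass
class GuideCandidate:
    gene_id: str
    protospacer: str  # 5'->3' on the targeted strand
    pam: str  # NGG, 5'->3' on the targeted strand
    strand: str
    contig: str
    proto_start: int  # genomic half-open interval of the 20-mer
    proto_end: int
    cut_site: int  # genomic coordinate of the base 3' of the blunt cut
    cds_offset: int | None = None  # spliced-CDS coordinate on the reference CDS
    orf_fraction: float | None = None
    tss_distance: int | None = None
    transcripts_hit: frozenset[str] = field(default_factory=frozenset)
    offtarget_count: int | None = None

    def __post_init__(self) -> None:
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise ValueError("protospacer must be 20 nt")
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"PAM {self.pam!r} does not match NGG")
        if not (self.proto_start <= self.cut_site < self.proto_end):
            raise ValueError("cut site must lie inside the protospacer interval")

    @property
    def key(self) -> tuple[int, int, str]:
        return (self.proto_start, self.proto_end, self.strand)


def enumerate_guides(genome: GenomeSequence, model: GeneModel) -> list[GuideCandidate]:
    """All candidates whose cut site is coding in >=1 transcript of ``model``.

    Returned sorted by (cut_site, strand) and unique by (interval, strand).
    """
    seq = genome[model.contig]
    gs, ge = model.span
    lo = max(0, gs - PROTOSPACER_LEN - PAM_LEN)
    hi = min(len(seq), ge + PROTOSPACER_LEN + PAM_LEN)

    out: list[GuideCandidate] = []
    seen: set[tuple[int, int, str]] = set()

    def coding(cut: int) -> bool:
        return any(
            spliced_cds_offset(t, cut) is not None for t in model.transcripts
        )

    # plus strand: [s, s+20) protospacer, PAM [s+20, s+23)
    for s in range(lo, hi - 23 + 1):
        if seq[s + 21 : s + 23] != "GG":
            continue
        window = seq[s : s + 23]
        if "N" in window:
            continue
        cut = s + CUT_OFFSET
        if not coding(cut):
            continue
        cand = GuideCandidate(
            gene_id=model.gene_id,
            protospacer=window[:20],
            pam=window[20:],
            strand="+",
            contig=model.contig,
            proto_start=s,
            proto_end=s + 20,
            cut_site=cut,
        )
        if cand.key not in seen:
            seen.add(cand.key)
            out.append(cand)

    # minus strand: top-strand CCN at [p-3, p), protospacer occupies [p, p+20)
    for p in range(lo + 3, hi - 20 + 1):
        if seq[p - 3 : p - 1] != "CC":
            continue
        window = seq[p - 3 : p + 20]
        if "N" in window:
            continue
        cut = p + PROTOSPACER_LEN - CUT_OFFSET - 1  # base 18 of the minus protospacer
        if not coding(cut):
            continue
        cand = GuideCandidate(
            gene_id=model.gene_id,
            protospacer=revcomp(seq[p : p + 20]),
            pam=revcomp(seq[p - 3 : p]),
            strand="-",
            contig=model.contig,
            proto_start=p,
            proto_end=p + 20,
            cut_site=cut,
        )
        if cand.key not in seen:
            seen.add(cand.key)
            out.append(cand)

    out.sort(key=lambda c: (c.cut_site, c.strand))
    return out


def annotate_positions(
    candidates: list[GuideCandidate], model: GeneModel
) -> list[GuideCandidate]:
    """Fill cds_offset, orf_fraction, tss_distance and transcripts_hit in place.

    The spliced-CDS offset is measured on the longest CDS; for cut sites that
    this reference isoform skips, the longest transcript among those actually
    hit is used instead (its own length normalises orf_fraction).
    """
    ref = model.reference_transcript
    by_len = sorted(
        model.transcripts, key=lambda t: (-t.spliced_cds_length, t.transcript_id)
    )
    for c in candidates:
        if c.contig != model.contig or c.proto_start < 0:
            raise ValueError(f"candidate {c.protospacer} off the gene's contig")
        hit = frozenset(
            t.transcript_id
            for t in model.transcripts
            if spliced_cds_offset(t, c.cut_site) is not None
        )
        c.transcripts_hit = hit
        off = spliced_cds_offset(ref, c.cut_site)
        length = ref.spliced_cds_length
        if off is None:
            for t in by_len:
                if t.transcript_id in hit:
                    off = spliced_cds_offset(t, c.cut_site)
                    length = t.spliced_cds_length
                    break
        c.cds_offset = off
        c.orf_fraction = None if off is None else off / length
        c.tss_distance = abs(c.cut_site - model.tss)
    return candidates


CANDIDATE_COLUMNS = [
    "gene", "protospacer", "pam", "strand", "contig", "proto_start", "proto_end",
    "cut_site", "cds_offset", "orf_fraction", "tss_distance", "transcripts_hit",
    "offtarget_count",
]


def write_candidate_table(candidates: list[GuideCandidate], path: str | Path) -> None:
    """TSV with one row per candidate."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CANDIDATE_COLUMNS)
        for c in candidates:
            w.writerow([
                c.gene_id, c.protospacer, c.pam, c.strand, c.contig,
                c.proto_start, c.proto_end, c.cut_site,
                "" if c.cds_offset is None else c.cds_offset,
                "" if c.orf_fraction is None else f"{c.orf_fraction:.6f}",
                "" if c.tss_distance is None else c.tss_distance,
                ",".join(sorted(c.transcripts_hit)),
                "" if c.offtarget_count is None else c.offtarget_count,
            ])


def write_candidate_bed(candidates: list[GuideCandidate], path: str | Path) -> None:
    """BED6 export of protospacer intervals (score column carries off-targets)."""
    with open(path, "w") as fh:
        for c in candidates:
            score = 0 if c.offtarget_count is None else c.offtarget_count
            name = f"{c.gene_id}:{c.protospacer}"
            fh.write(
                f"{c.contig}\t{c.proto_start}\t{c.proto_end}\t{name}\t{score}\t{c.strand}\n"
            )
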