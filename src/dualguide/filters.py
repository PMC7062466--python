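"""Hard exclusion filters and genome-wide off-target counting.

Four independent predicates mirror the library's exclusion rules:

* genome-wide off-target uniqueness under a configurable mismatch policy
  (total mismatches, PAM-proximal seed mismatches, permissive PAM set);
* BbsI/BsaI recognition sites anywhere in the 20-mer (either orientation),
  which would break Golden-Gate cloning;
* homopolymer runs of >=4 identical nucleotides, which impair synthesis and
  Pol III transcription;
* overlap of the protospacer+PAM with any isoform's start codon.

Because the filters are independent predicates of a single candidate, the
composed filter is order-invariant and idempotent.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GeneModel, GenomeSequence, revcomp
from .guide_enum import PAM_LEN, PROTOSPACER_LEN, GuideCandidate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OffTargetPolicy:
    """Mismatch policy for the genome-wide off-target scan.

    A genomic site counts as an off-target when its 20-mer matches the
    protospacer with at most ``max_mismatches_total`` mismatches, of which at
    most ``max_mismatches_seed`` fall in the PAM-proximal ``seed_length``
    bases, and the site is adjacent to a PAM in ``pams_considered``
    (N expands over A/C/G/T). The on-target locus itself is excluded.
    """

    max_mismatches_total: int = 3
    max_mismatches_seed: int = 0
    seed_length: int = 12
    pams_considered: frozenset[str] = frozenset({"NGG", "NAG"})
    reject_if_any_site: bool = True

    def __post_init__(self) -> None:
        if self.seed_length > PROTOSPACER_LEN:
            raise ValueError("seed_length must be <= 20")
        if self.max_mismatches_seed > self.max_mismatches_total:
            raise ValueError("seed mismatches cannot exceed total mismatches")

    def expanded_pams(self) -> frozenset[str]:
        out: set[str] = set()
        for pam in self.pams_considered:
            seqs = [""]
            for ch in pam:
                alts = "ACGT" if ch == "N" else ch
                seqs = [s + a for s in seqs for a in alts]
            out.update(seqs)
        return frozenset(out)


_ENC = np.zeros(128, dtype=np.uint8)
for _i, _b in enumerate("ACGTN"):
    _ENC[ord(_b)] = _i + 1


def _encode(seq: str) -> np.ndarray:
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class PamSiteIndex:
    """All PAM-adjacent 20-mer windows of a genome, as a matrix for fast Hamming scans.

    Rows are protospacer-orientation 20-mers (5'->3' on the strand carrying the
    PAM); windows containing N are kept and simply never match (N compares
    unequal to every base).
    """

    def __init__(self, genome: GenomeSequence, policy: OffTargetPolicy) -> None:
        pams = policy.expanded_pams()
        mats: list[np.ndarray] = []
        keys: list[tuple[str, int, str]] = []
        for contig, seq in genome.contigs.items():
            n = len(seq)
            rc = revcomp(seq)
            for strand, s in (("+", seq), ("-", rc)):
                for i in range(0, n - PROTOSPACER_LEN - PAM_LEN + 1):
                    if s[i + 20 : i + 23] in pams:
                        window = s[i : i + 20]
                        mats.append(_encode(window))
                        if strand == "+":
                            keys.append((contig, i, "+"))
                        else:
                            # position of the 20-mer on the forward strand
                            keys.append((contig, n - (i + 20), "-"))
        self.keys = keys
        self.matrix = (
            np.vstack(mats) if mats else np.empty((0, PROTOSPACER_LEN), dtype=np.uint8)
        )
        self.seed_cols = slice(PROTOSPACER_LEN - policy.seed_length, PROTOSPACER_LEN)
        self.policy = policy

    def count(self, candidate: GuideCandidate) -> int:
        if self.matrix.shape[0] == 0:
            return 0
        q = _encode(candidate.protospacer)
        diff = self.matrix != q
        total = diff.sum(axis=1)
        seed = diff[:, self.seed_cols].sum(axis=1)
        ok = (total <= self.policy.max_mismatches_total) & (
            seed <= self.policy.max_mismatches_seed
        )
        on_target = (candidate.contig, candidate.proto_start, candidate.strand)
        hits = int(ok.sum())
        if hits and on_target in self.keys:
            idx = np.flatnonzero(ok)
            hits -= sum(1 for i in idx if self.keys[i] == on_target)
        return hits


def count_offtargets(
    candidate: GuideCandidate,
    genome: GenomeSequence,
    policy: OffTargetPolicy,
    index: PamSiteIndex | None = None,
) -> int:
    """Number of genomic off-target sites for one candidate under ``policy``.

    Pass a prebuilt :class:`PamSiteIndex` when scanning many candidates
    against the same genome.
    """
    if index is None:
        index = PamSiteIndex(genome, policy)
    return index.count(candidate)


# ---------------------------------------------------------------------------
# Filter predicates
# ---------------------------------------------------------------------------

BBSI_MOTIFS = ("GAAGAC", "GTCTTC")
BSAI_MOTIFS = ("GGTCTC", "GAGACC")
_SITE_RE = re.compile("|".join(BBSI_MOTIFS + BSAI_MOTIFS))
_HOMOPOLYMER_RE = re.compile(r"(A{4,}|C{4,}|G{4,}|T{4,})")


def has_restriction_site(protospacer: str) -> bool:
    return _SITE_RE.search(protospacer) is not None


def has_homopolymer(protospacer: str) -> bool:
    return _HOMOPOLYMER_RE.search(protospacer) is not None


def overlaps_start_codon(candidate: GuideCandidate, model: GeneModel) -> bool:
    """True if the protospacer+PAM interval overlaps any isoform start codon."""
    if candidate.strand == "+":
        lo, hi = candidate.proto_start, candidate.proto_end + PAM_LEN
    else:
        lo, hi = candidate.proto_start - PAM_LEN, candidate.proto_end
    return any(lo < e and s < hi for s, e in model.start_codons)


def filter_restriction_sites(candidates: list[GuideCandidate]) -> list[GuideCandidate]:
    return [c for c in candidates if not has_restriction_site(c.protospacer)]


def filter_homopolymer(candidates: list[GuideCandidate]) -> list[GuideCandidate]:
    return [c for c in candidates if not has_homopolymer(c.protospacer)]


def filter_start_codon(
    candidates: list[GuideCandidate], model: GeneModel
) -> list[GuideCandidate]:
    return [c for c in candidates if not overlaps_start_codon(c, model)]


def filter_offtargets(
    candidates: list[GuideCandidate],
    genome: GenomeSequence,
    policy: OffTargetPolicy,
    index: PamSiteIndex | None = None,
) -> list[GuideCandidate]:
    """Fill offtarget_count; drop non-unique guides when the policy rejects any site."""
    if index is None:
        index = PamSiteIndex(genome, policy)
    out = []
    for c in candidates:
        c.offtarget_count = index.count(c)
        if policy.reject_if_any_site and c.offtarget_count > 0:
            continue
        out.append(c)
    return out


@dataclass
class FilterRecord:
    gene_id: str
    protospacer: str
    filter: str
    verdict: str  # pass | fail
    reason: str


@dataclass
class FilterAudit:
    retained: list[GuideCandidate]
    records: list[FilterRecord] = field(default_factory=list)


def apply_all_filters(
    candidates: list[GuideCandidate],
    genome: GenomeSequence,
    model: GeneModel,
    policy: OffTargetPolicy,
    index: PamSiteIndex | None = None,
) -> FilterAudit:
    """Compose the four filters; every removal is recorded with its reason.

    All predicates are evaluated for every candidate (a candidate failing two
    filters gets two fail records), so the retained set is independent of
    filter order.
    """
    if index is None:
        index = PamSiteIndex(genome, policy)
    audit = FilterAudit(retained=[])
    for c in candidates:
        c.offtarget_count = index.count(c)
        fails: list[tuple[str, str]] = []
        if policy.reject_if_any_site and c.offtarget_count > 0:
            fails.append(
                ("offtarget", f"{c.offtarget_count} predicted off-target site(s)")
            )
        if has_restriction_site(c.protospacer):
            m = _SITE_RE.search(c.protospacer)
            fails.append(("restriction_site", f"{m.group(0)} at protospacer pos {m.start()}"))
        if has_homopolymer(c.protospacer):
            m = _HOMOPOLYMER_RE.search(c.protospacer)
            fails.append(("homopolymer", f"run {m.group(0)} at protospacer pos {m.start()}"))
        if overlaps_start_codon(c, model):
            fails.append(("start_codon", "protospacer+PAM overlaps an isoform start codon"))
        if fails:
            for name, reason in fails:
                audit.records.append(
                    FilterRecord(c.gene_id, c.protospacer, name, "fail", reason)
                )
                logger.debug("%s %s removed by %s: %s", c.gene_id, c.protospacer, name, reason)
        else:
            audit.records.append(
                FilterRecord(c.gene_id, c.protospacer, "all", "pass", "")
            )
            audit.retained.append(c)
    return audit


def write_filter_report(records: list[FilterRecord], path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["gene", "protospacer", "filter", "verdict", "reason"])
        for r in records:
            w.writerow([r.gene_id, r.protospacer, r.filter, r.verdict, r.reason])
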