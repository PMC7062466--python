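"""Pooled-cloning oligo generation and two-step Type IIS assembly simulation.

Each selected guide pair becomes one pool oligo:

    amp5 - [BbsI>]..OH1 - proto1 - [OH2..<BsaI .. BsaI>..OH3] - proto2 - OH4..[<BbsI] - amp3

Step 1 amplifies the oligo, digests with BbsI (releasing the insert with
overhangs OH1/OH4, the recognition sites staying on the discarded handles) and
ligates it into a BbsI-opened vector. Step 2 digests the resulting plasmid
with BsaI, excising the internal cassette (which carries both BsaI sites), and
ligates in the guide-scaffold ("core") + tRNA fragment with overhangs
OH2 = core[:4] and OH3 = tRNA[-4:]. The final plasmid therefore reads

    ... proto1 - core - tRNA - proto2 ...

and contains no BbsI or BsaI recognition site in either orientation — Type IIS
assembly removes its own sites, which is what makes the one-pot reactions
converge. All part sequences (handles, overhangs, core, tRNA, mock vector) are
configuration with documented defaults.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .genome_io import revcomp
from .pair_select import GuidePair


@dataclass(frozen=True)
class EnzymeDef:
    """A Type IIS enzyme cutting downstream of its recognition site.

    ``cut_offset_top``/``cut_offset_bottom`` are measured from the 3' end of
    the recognition sequence on the strand carrying it; bottom - top = 4 yields
    4-nt 5' overhangs.
    """

    name: str
    recognition: str
    cut_offset_top: int
    cut_offset_bottom: int

    def __post_init__(self) -> None:
        if self.cut_offset_bottom - self.cut_offset_top != 4:
            raise ValueError(f"{self.name}: expected 4-nt 5' overhangs")


BBSI = EnzymeDef("BbsI", "GAAGAC", 2, 6)
BSAI = EnzymeDef("BsaI", "GGTCTC", 1, 5)


class CloningError(ValueError):
    """Raised for infeasible oligos, PCR failures or ambiguous assemblies."""


def find_recognition_sites(seq: str, enzyme: EnzymeDef, circular: bool = False):
    """All (position, orientation) recognition matches, both orientations.

    Positions refer to the start of the motif on the given (top) strand;
    orientation '+' means the recognition reads 5'->3' on top. For circular
    sequences matches may wrap the origin.
    """
    rec = enzyme.recognition
    rc = revcomp(rec)
    search = seq + seq[: len(rec) - 1] if circular else seq
    sites = []
    for motif, orient in ((rec, "+"), (rc, "-")):
        for m in re.finditer(f"(?={motif})", search):
            if m.start() < len(seq):
                sites.append((m.start(), orient))
    return sorted(sites)


def _top_cuts(seq: str, enzyme: EnzymeDef, circular: bool) -> list[int]:
    """Top-strand cut coordinates; the 4-nt overhang at cut c is seq[c:c+4]."""
    L = len(enzyme.recognition)
    n = len(seq)
    cuts = []
    for pos, orient in find_recognition_sites(seq, enzyme, circular):
        if orient == "+":
            c = pos + L + enzyme.cut_offset_top
        else:
            c = pos - enzyme.cut_offset_bottom
        if circular:
            c %= n
        elif not 0 <= c <= n - 4:
            raise CloningError(
                f"{enzyme.name} site at {pos} cuts outside the linear sequence"
            )
        cuts.append(c)
    return sorted(set(cuts))


@dataclass(frozen=True)
class Fragment:
    """A double-stranded fragment with 4-nt 5' overhang annotations.

    ``seq`` is the top strand from this fragment's top cut to the next one, so
    ``left_oh`` (the fragment's own 5' extension) is ``seq[:4]`` while
    ``right_oh`` is the 5' extension of the *bottom* strand, written in
    top-strand letters — i.e. the first 4 nt of the neighbouring fragment.
    Concatenating fragment seqs in order reconstructs the digested input.
    """

    seq: str
    left_oh: str  # "" at a blunt linear end
    right_oh: str

    def has_site(self, enzyme: EnzymeDef) -> bool:
        return bool(find_recognition_sites(self.seq, enzyme))


def digest(seq: str, enzyme: EnzymeDef, circular: bool = False) -> list[Fragment]:
    """Cut at every recognition site (both orientations) with Type IIS offsets."""
    cuts = _top_cuts(seq, enzyme, circular)
    n = len(seq)
    if not cuts:
        return [Fragment(seq, "", "")] if not circular else [Fragment(seq, "", "")]
    frags: list[Fragment] = []
    if circular:
        ext = seq + seq
        for i, c in enumerate(cuts):
            nxt = cuts[(i + 1) % len(cuts)]
            end = nxt if nxt > c else nxt + n
            frags.append(Fragment(ext[c:end], ext[c : c + 4], ext[end : end + 4]))
    else:
        bounds = [0] + cuts + [n]
        for i, (a, b) in enumerate(zip(bounds, bounds[1:])):
            left = seq[a : a + 4] if i > 0 else ""
            right = seq[b : b + 4] if i < len(bounds) - 2 else ""
            frags.append(Fragment(seq[a:b], left, right))
    return frags


def _is_palindrome(oh: str) -> bool:
    return oh == revcomp(oh)


def golden_gate(vector: str, insert_source: list[Fragment], enzyme: EnzymeDef) -> str:
    """One-pot digestion-ligation of a circular vector with insert fragments.

    The vector is digested; every fragment (vector- or insert-derived) still
    carrying a recognition site is removed from the ligation pool, mimicking
    the re-cutting that drives Golden-Gate reactions to completion. The
    remaining fragments must chain into a single circle via unique,
    non-palindromic complementary overhangs, starting from the vector
    backbone. Returns the assembled circular sequence (top strand, origin at
    the backbone fragment).
    """
    vec_frags = digest(vector, enzyme, circular=True)
    backbone = [f for f in vec_frags if not f.has_site(enzyme)]
    if len(backbone) != 1:
        raise CloningError(
            f"vector must yield exactly one {enzyme.name}-free backbone fragment, "
            f"got {len(backbone)}"
        )
    pool = [backbone[0]] + [f for f in insert_source if not f.has_site(enzyme)]
    overhangs = [f.left_oh for f in pool] + [f.right_oh for f in pool]
    if any(len(oh) != 4 for oh in overhangs):
        raise CloningError("all ligation fragments need 4-nt overhangs")
    bad = sorted({oh for oh in overhangs if _is_palindrome(oh)})
    if bad:
        raise CloningError(f"palindromic (self-ligating) overhangs: {bad}")
    by_left: dict[str, Fragment] = {}
    for f in pool:
        if f.left_oh in by_left:
            raise CloningError(
                f"ambiguous assembly: duplicate overhang {f.left_oh} "
                f"(overhang multiset: {sorted(overhangs)})"
            )
        by_left[f.left_oh] = f
    chain = [backbone[0]]
    while True:
        nxt = by_left.get(chain[-1].right_oh)
        if nxt is None:
            raise CloningError(
                f"no fragment ligates to overhang {chain[-1].right_oh} "
                f"(overhang multiset: {sorted(overhangs)})"
            )
        if nxt is chain[0]:
            break
        if nxt in chain:
            raise CloningError("assembly does not close into a single circle")
        chain.append(nxt)
    product = "".join(f.seq for f in chain)
    if find_recognition_sites(product, enzyme, circular=True):
        raise CloningError(f"assembled product retains {enzyme.name} sites")
    return product


def simulate_pcr(template: str, fwd: str, rev: str) -> str:
    """Amplicon of ``template`` bounded by ``fwd`` and the reverse primer.

    ``fwd`` must match the top strand exactly once, the reverse complement of
    ``rev`` must match the top strand exactly once and downstream of it.
    """
    rc = revcomp(rev)
    f_hits = [m.start() for m in re.finditer(f"(?={re.escape(fwd)})", template)]
    r_hits = [m.start() for m in re.finditer(f"(?={re.escape(rc)})", template)]
    if len(f_hits) != 1:
        raise CloningError(f"forward primer matches template {len(f_hits)} times")
    if len(r_hits) != 1:
        raise CloningError(f"reverse primer matches template {len(r_hits)} times")
    start, end = f_hits[0], r_hits[0] + len(rc)
    if start >= end:
        raise CloningError("primers face away from each other")
    return template[start:end]


# ---------------------------------------------------------------------------
# Part sequences (configurable; defaults are synthetic but structurally faithful)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CloningParts:
    """Sequences of the invariant oligo/vector parts.

    Defaults are synthetic stand-ins with the documented architecture: users
    with the real vector flanks and amplification primers substitute them via
    the ``cloning:`` config section. ``core`` is an sgRNA scaffold starting
    with the step-2 5' overhang; ``trna`` ends with the step-2 3' overhang.
    """

    amp5: str = "GGAGTTCGCTACGACTCACG"  # 5' amplification handle (Libamp-fwd site)
    amp3: str = "CGTGAGCATCGCTAAGCTCC"  # 3' amplification handle
    oh_vector_5: str = "CACC"  # OH1: vector/proto1 junction
    oh_vector_3: str = "ATGC"  # OH4: proto2/vector junction
    # sgRNA scaffold ("core"); first 4 nt are OH2
    core: str = (
        "GTTTCAGAGCTATGCTGGAAACAGCATAGCAAGTTGAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTG"
        "GCACCGAGTCGGTGC"
    )
    # spacer tRNA between the two guides; last 4 nt are OH3
    trna: str = (
        "GCATTGGTGGTTCAGTGGTAGAATTCTCGCCTGCCACGCGGGAGGCCCGGGTTCGATTCCCGGCCAATCCA"
    )
    vector_backbone: str = (
        "TTCTAGAGGTAGTCCTTACATCAGCACCAGTCCTTAGGACATTGGCAGTCCATTGGC"
        "ACTGGATCAACGTTGCCAATGACTGTTCACCGTTAGC"
    )
    ct_handle_5: str = "TGCCACTTGACGAGTCGT"  # core+tRNA PCR handle (Core_tRNA-fwd site)
    ct_handle_3: str = "TCAGCGTAACGTTCAGGC"

    @property
    def oh_core_5(self) -> str:  # OH2
        return self.core[:4]

    @property
    def oh_trna_3(self) -> str:  # OH3
        return self.trna[-4:]

    @property
    def mock_vector(self) -> str:
        """Circular BbsI acceptor: backbone around an excisable stuffer."""
        stuffer = "TACGATCCGGTTAACGGATC"
        return (
            self.vector_backbone
            + self.oh_vector_5 + "AA" + revcomp(BBSI.recognition)
            + stuffer
            + BBSI.recognition + "AA" + self.oh_vector_3
        )

    @property
    def core_trna_template(self) -> str:
        """PCR template providing the scaffold+tRNA step-2 insert."""
        return (
            self.ct_handle_5
            + BSAI.recognition + "A" + self.core + self.trna + "A"
            + revcomp(BSAI.recognition)
            + self.ct_handle_3
        )

    @property
    def libamp_fwd(self) -> str:
        return self.amp5

    @property
    def libamp_rev(self) -> str:
        return revcomp(self.amp3)

    @property
    def ct_fwd(self) -> str:
        return self.ct_handle_5

    @property
    def ct_rev(self) -> str:
        return revcomp(self.ct_handle_3)


DEFAULT_PARTS = CloningParts()


@dataclass
class LibraryOligo:
    """One pool oligonucleotide carrying both protospacers of a pair."""

    amp5: str
    flank_bbsI_5: str
    proto1: str
    cassette_bsaI: str
    proto2: str
    flank_bbsI_3: str
    amp3: str

    @property
    def full_sequence(self) -> str:
        return (
            self.amp5 + self.flank_bbsI_5 + self.proto1 + self.cassette_bsaI
            + self.proto2 + self.flank_bbsI_3 + self.amp3
        )

    @property
    def segments(self) -> list[tuple[str, str]]:
        return [
            ("amp5", self.amp5), ("flank_bbsI_5", self.flank_bbsI_5),
            ("proto1", self.proto1), ("cassette_bsaI", self.cassette_bsaI),
            ("proto2", self.proto2), ("flank_bbsI_3", self.flank_bbsI_3),
            ("amp3", self.amp3),
        ]


def make_oligo(pair: GuidePair, parts: CloningParts = DEFAULT_PARTS) -> LibraryOligo:
    """Build the pool oligo for a pair; junction-created sites are fatal."""
    oligo = LibraryOligo(
        amp5=parts.amp5,
        flank_bbsI_5=BBSI.recognition + "AA" + parts.oh_vector_5,
        proto1=pair.guide_a.protospacer,
        cassette_bsaI=(
            parts.oh_core_5 + "A" + revcomp(BSAI.recognition)
            + "TACGTGACTAAGCTCA"  # excised stuffer
            + BSAI.recognition + "A" + parts.oh_trna_3
        ),
        proto2=pair.guide_b.protospacer,
        flank_bbsI_3=parts.oh_vector_3 + "AA" + revcomp(BBSI.recognition),
        amp3=parts.amp3,
    )
    report = validate_oligo(oligo)
    if not report.ok:
        raise CloningError("; ".join(report.problems))
    return oligo


@dataclass
class OligoReport:
    sites: list[tuple[str, int, str]]  # (enzyme, position, orientation)
    ok: bool
    problems: list[str] = field(default_factory=list)


def validate_oligo(oligo: LibraryOligo) -> OligoReport:
    """Scan the full oligo for BbsI/BsaI sites and check the intended layout.

    Pass requires exactly two BbsI sites (one per orientation, in the flanks)
    and exactly two BsaI sites (both in the internal cassette), nowhere else.
    """
    seq = oligo.full_sequence
    sites: list[tuple[str, int, str]] = []
    for enz in (BBSI, BSAI):
        for pos, orient in find_recognition_sites(seq, enz):
            sites.append((enz.name, pos, orient))
    # intended intervals
    b5_start = len(oligo.amp5)
    cass_start = b5_start + len(oligo.flank_bbsI_5) + len(oligo.proto1)
    cass_end = cass_start + len(oligo.cassette_bsaI)
    b3_start = cass_end + len(oligo.proto2)
    b3_end = b3_start + len(oligo.flank_bbsI_3)
    problems: list[str] = []
    bbsi = [s for s in sites if s[0] == "BbsI"]
    bsai = [s for s in sites if s[0] == "BsaI"]
    if len(bbsi) != 2 or {o for _, _, o in bbsi} != {"+", "-"}:
        problems.append(f"expected 2 BbsI sites (one per orientation), found {bbsi}")
    if len(bsai) != 2:
        problems.append(f"expected 2 BsaI sites, found {bsai}")
    for name, pos, orient in sites:
        in_flank = b5_start <= pos < b5_start + len(oligo.flank_bbsI_5) or \
            b3_start <= pos < b3_end
        in_cassette = cass_start <= pos < cass_end
        intended = (name == "BbsI" and in_flank) or (name == "BsaI" and in_cassette)
        if not intended:
            problems.append(
                f"unexpected {name} site at position {pos} ({orient}) outside its "
                "intended segment (junction- or protospacer-created)"
            )
    return OligoReport(sites=sorted(sites, key=lambda s: s[1]), ok=not problems,
                       problems=problems)


@dataclass
class AssembledCassette:
    """The final tandem-sgRNA insert after both assembly steps."""

    sequence: str  # proto1 + core + tRNA + proto2
    layout: list[tuple[str, int, int]]  # (part, start, end) within sequence
    plasmid: str  # full circular product, origin at the vector backbone


def assemble_two_step(
    pair: GuidePair, parts: CloningParts = DEFAULT_PARTS, mock_vector: str | None = None
) -> AssembledCassette:
    """Simulate oligo synthesis, PCR, BbsI then BsaI Golden-Gate assembly."""
    vector = parts.mock_vector if mock_vector is None else mock_vector
    try:
        oligo = make_oligo(pair, parts)
    except CloningError as e:
        raise CloningError(f"oligo synthesis: {e}") from e
    try:
        amplicon = simulate_pcr(oligo.full_sequence, parts.libamp_fwd, parts.libamp_rev)
        insert = digest(amplicon, BBSI)
        step1 = golden_gate(vector, insert, BBSI)
    except CloningError as e:
        raise CloningError(f"step 1 (BbsI): {e}") from e
    try:
        ct_amplicon = simulate_pcr(parts.core_trna_template, parts.ct_fwd, parts.ct_rev)
        ct_frags = digest(ct_amplicon, BSAI)
        step2 = golden_gate(step1, ct_frags, BSAI)
    except CloningError as e:
        raise CloningError(f"step 2 (BsaI): {e}") from e

    cassette_seq = (
        pair.guide_a.protospacer + parts.core + parts.trna + pair.guide_b.protospacer
    )
    doubled = step2 + step2
    at = doubled.find(cassette_seq)
    if at < 0 or doubled.find(cassette_seq, at + 1) not in (-1, at + len(step2)):
        raise CloningError("final plasmid does not carry the cassette exactly once")
    p1, c, t = len(pair.guide_a.protospacer), len(parts.core), len(parts.trna)
    layout = [
        ("proto1", 0, p1),
        ("sgRNA_core", p1, p1 + c),
        ("tRNA", p1 + c, p1 + c + t),
        ("proto2", p1 + c + t, len(cassette_seq)),
    ]
    for enz in (BBSI, BSAI):
        if find_recognition_sites(step2, enz, circular=True):
            raise CloningError(f"final plasmid retains {enz.name} sites")
    return AssembledCassette(sequence=cassette_seq, layout=layout, plasmid=step2)


def write_oligo_sheet(rows: list[dict], path) -> None:
    """Order sheet TSV: library id, gene, protospacers, full oligo 5'->3'."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["library_id", "gene", "proto1", "proto2", "oligo"])
        for r in rows:
            w.writerow([r["library_id"], r["gene"], r["proto1"], r["proto2"], r["oligo"]])


def write_cassette_fasta(cassettes: dict[str, AssembledCassette], path) -> None:
    with open(path, "w") as fh:
        for name, cas in cassettes.items():
            fh.write(f">{name}\n{cas.sequence}\n")


def write_cassette_flat(cassettes: dict[str, AssembledCassette], path) -> None:
    """Annotated flat-file export: one feature line per cassette part."""
    with open(path, "w") as fh:
        for name, cas in cassettes.items():
            fh.write(f"LOCUS {name} {len(cas.sequence)} bp\n")
            for part, s, e in cas.layout:
                fh.write(f"FEATURE {part} {s + 1}..{e}\n")
            fh.write(f"ORIGIN {cas.sequence}\n//\n")
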