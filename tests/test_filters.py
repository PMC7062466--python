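import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dualguide import (
    FixtureSpec,
    GuideCandidate,
    OffTargetPolicy,
    PamSiteIndex,
    annotate_positions,
    apply_all_filters,
    count_offtargets,
    enumerate_guides,
    filter_homopolymer,
    filter_offtargets,
    filter_restriction_sites,
    filter_start_codon,
    make_fixture_genome,
    revcomp,
)
from dualguide.genome_io import GenomeSequence

from conftest import single_exon_gene


def brute_force_offtargets(candidate, genome, policy):
    """Independent oracle: Hamming-compare every PAM-adjacent window, per character."""
    pams = policy.expanded_pams()
    seed_len = policy.seed_length
    count = 0
    for contig, seq in genome.contigs.items():
        for strand in "+-":
            s = seq if strand == "+" else revcomp(seq)
            for i in range(len(s) - 22):
                if s[i + 20 : i + 23] not in pams:
                    continue
                window = s[i : i + 20]
                mm = sum(a != b for a, b in zip(window, candidate.protospacer))
                seed_mm = sum(
                    a != b
                    for a, b in zip(window[-seed_len:], candidate.protospacer[-seed_len:])
                )
                if mm > policy.max_mismatches_total or seed_mm > policy.max_mismatches_seed:
                    continue
                fwd_start = i if strand == "+" else len(s) - (i + 20)
                if (contig, fwd_start, strand) == (
                    candidate.contig, candidate.proto_start, candidate.strand
                ):
                    continue
                count += 1
    return count


def make_candidate(protospacer, gene_id="g", contig="c1", start=0, strand="+"):
    return GuideCandidate(
        gene_id=gene_id, protospacer=protospacer, pam="AGG", strand=strand,
        contig=contig, proto_start=start, proto_end=start + 20, cut_site=start + 17,
    )


POLICIES = [
    OffTargetPolicy(),
    OffTargetPolicy(max_mismatches_total=2, max_mismatches_seed=1, seed_length=10),
    OffTargetPolicy(max_mismatches_total=4, max_mismatches_seed=2, seed_length=8,
                    pams_considered=frozenset({"NGG"})),
]


class TestCountOfftargets:
    def test_planted_perfect_duplicate_counts_once(self):
        genome, genes, truth = make_fixture_genome(
            FixtureSpec(n_genes=2, n_duplications=1), seed=21
        )
        dup = truth.duplications[0]
        contig = next(iter(genome.contigs.values()))
        src = dup["source"]
        cand = make_candidate(contig[src : src + 20], contig="chr_sim", start=src)
        assert count_offtargets(cand, genome, OffTargetPolicy()) == 1

    def test_seed_mismatch_not_counted_under_strict_seed(self):
        proto = "GACTTCGAATCGTATCATTA"
        mutated = proto[:15] + ("A" if proto[15] != "A" else "T") + proto[16:]
        filler = "ATCATTATCATTATCATTAT"
        seq = proto + "AGG" + filler + mutated + "TGG" + filler
        genome = GenomeSequence({"c1": seq})
        cand = make_candidate(proto, contig="c1", start=0)
        assert count_offtargets(cand, genome, OffTargetPolicy()) == 0
        relaxed = OffTargetPolicy(max_mismatches_seed=1)
        assert count_offtargets(cand, genome, relaxed) == 1

    @pytest.mark.parametrize("policy", POLICIES)
    def test_matches_brute_force_oracle(self, policy):
        genome, genes, _ = make_fixture_genome(
            FixtureSpec(n_genes=3, n_duplications=2), seed=13
        )
        index = PamSiteIndex(genome, policy)
        model = genes[0]
        cands = enumerate_guides(genome, model)[:25]
        assert cands
        for c in cands:
            assert index.count(c) == brute_force_offtargets(c, genome, policy)


class TestFilterRules:
    def test_offtarget_filter_drops_planted_duplicate(self):
        genome, genes, truth = make_fixture_genome(
            FixtureSpec(n_genes=2, n_duplications=1), seed=21
        )
        dup = truth.duplications[0]
        model = next(
            g for g in genes
            if any(s <= dup["source"] < e for s, e in g.transcripts[0].cds_exons)
        )
        cands = enumerate_guides(genome, model)
        policy = OffTargetPolicy()
        retained = filter_offtargets(list(cands), genome, policy)
        assert all(c.offtarget_count == 0 for c in retained)
        dropped = {c.key for c in cands} - {c.key for c in retained}
        assert dropped  # the duplicated guide (at least) is gone
        keep_all = OffTargetPolicy(reject_if_any_site=False)
        relaxed = filter_offtargets(list(cands), genome, keep_all)
        assert len(relaxed) == len(cands)
        assert any(c.offtarget_count >= 1 for c in relaxed)

    @pytest.mark.parametrize("proto,kept", [
        ("ATGAAGACTTCCGGATACCA", False),  # BbsI GAAGAC
        ("ATCGGAGACCTTCCGATACA", False),  # BsaI reverse GAGACC
        ("ATCGGTCTCATTCCGATACA", False),  # BsaI GGTCTC
        ("ATGTCTTCGTTCCGGATACA", False),  # BbsI reverse GTCTTC
        ("ATCGCAGACGTTCCGATACA", True),
    ])
    def test_restriction_site_exclusion(self, proto, kept):
        out = filter_restriction_sites([make_candidate(proto)])
        assert bool(out) is kept

    @pytest.mark.parametrize("proto,kept", [
        ("ATTTTGCGCATGCGCATGCA", False),  # TTTT
        ("ATTTGCGCATGCGCATGCAT", True),  # max run 3
        ("CGCATGCGCATGCAGGGGAT", False),  # GGGG
    ])
    def test_homopolymer_exclusion(self, proto, kept):
        out = filter_homopolymer([make_candidate(proto)])
        assert bool(out) is kept

    @given(st.text(alphabet="ACGT", min_size=20, max_size=20))
    @settings(max_examples=60, deadline=None)
    def test_homopolymer_filter_idempotent_and_correct(self, proto):
        once = filter_homopolymer([make_candidate(proto)])
        assert filter_homopolymer(list(once)) == once
        has_run = any(b * 4 in proto for b in "ACGT")
        assert bool(once) is not has_run

    def test_start_codon_overlap(self):
        seq = "T" * 30 + "ATGGCAGCTGCAGCTGCAGCTTGAGCAGCT" + "T" * 30
        genome, model = single_exon_gene(seq, cds=(30, 60))
        near = make_candidate(seq[12:32], start=12)  # protospacer ends at 32 > 30
        away = make_candidate(seq[40:60], start=40)
        # minus-strand guide ending 1 bp before the ATG: its PAM faces away
        boundary = GuideCandidate(
            gene_id="g", protospacer=revcomp(seq[9:29]), pam="AGG",
            strand="-", contig="c1", proto_start=9, proto_end=29, cut_site=11,
        )
        assert filter_start_codon([near], model) == []
        assert filter_start_codon([away], model) == [away]
        assert filter_start_codon([boundary], model) == [boundary]
        # a plus-strand guide ending right at the ATG is removed: its PAM covers it
        pam_hit = make_candidate(seq[10:30], start=10)
        assert filter_start_codon([pam_hit], model) == []

    def test_start_codon_any_isoform(self):
        from dualguide import GeneModel, TranscriptModel

        seq = "T" * 30 + "ATGGCAGCTGCAGCTGCAGCT" + "T" * 9 + "ATGGCAGCTGCA" + "T" * 30
        t1 = TranscriptModel("t1", "c1", "+", [(30, 51)])
        t2 = TranscriptModel("t2", "c1", "+", [(60, 72)])
        model = GeneModel("g1", "c1", "+", [t1, t2])
        downstream_hit = make_candidate(seq[45:65], start=45)  # spans t2's ATG only
        assert filter_start_codon([downstream_hit], model) == []


class TestApplyAllFilters:
    def test_composition_and_order_invariance(self):
        genome, genes, _ = make_fixture_genome(
            FixtureSpec(n_genes=2, n_duplications=1, n_restriction_sites=2), seed=31
        )
        policy = OffTargetPolicy()
        for model in genes:
            cands = annotate_positions(enumerate_guides(genome, model), model)
            audit = apply_all_filters(cands, genome, model, policy)
            # oracle: apply single filters in every order
            index = PamSiteIndex(genome, policy)
            fns = [
                lambda cs: filter_offtargets(cs, genome, policy, index=index),
                filter_restriction_sites,
                filter_homopolymer,
                lambda cs: filter_start_codon(cs, model),
            ]
            expected = None
            for order in itertools.permutations(range(4)):
                out = list(cands)
                for i in order:
                    out = fns[i](out)
                keys = {c.key for c in out}
                assert expected is None or keys == expected
                expected = keys
            assert {c.key for c in audit.retained} == expected

    def test_multiple_failures_all_logged(self):
        genome, genes, _ = make_fixture_genome(FixtureSpec(n_genes=1), seed=2)
        model = genes[0]
        bad = make_candidate("ATGAAGACTTCCGGGGTACC", gene_id=model.gene_id,
                             contig=model.contig, start=model.transcripts[0].cds_exons[0][0])
        audit = apply_all_filters([bad], genome, model, OffTargetPolicy())
        assert audit.retained == []
        reasons = {r.filter for r in audit.records if r.verdict == "fail"}
        assert {"restriction_site", "homopolymer"} <= reasons

    def test_all_pass_is_identity(self):
        genome, genes, _ = make_fixture_genome(FixtureSpec(n_genes=1), seed=7)
        model = genes[0]
        cands = annotate_positions(enumerate_guides(genome, model), model)
        audit = apply_all_filters(cands, genome, model, OffTargetPolicy())
        again = apply_all_filters(list(audit.retained), genome, model, OffTargetPolicy())
        assert [c.key for c in again.retained] == [c.key for c in audit.retained]
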