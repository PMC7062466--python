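import dataclasses
from itertools import combinations

import numpy as np
import pytest

from dualguide import (
    FixtureSpec,
    OffTargetPolicy,
    ScoringWeights,
    annotate_positions,
    apply_all_filters,
    design_gene,
    enumerate_guides,
    make_fixture_genome,
    make_pair,
    sample_pairs,
    score_pair,
    select_top_pairs,
)


def spreadsheet_score(pair, model, w):
    """Independent recomputation of the pair score from raw guide fields."""
    a, b = pair.guide_a, pair.guide_b
    span = model.span[1] - model.span[0]
    bonus = w.w_transcript * len(set(a.transcripts_hit) | set(b.transcripts_hit))
    bonus += w.w_five_prime * ((a.orf_fraction < 0.5) + (b.orf_fraction < 0.5))
    for g in (a, b):
        term = 1.0 - g.tss_distance / span
        bonus += w.w_tss * min(1.0, max(0.0, term))
    penalty = 0.0
    if abs(a.cut_site - b.cut_site) < 75:
        penalty += w.p_close
    elif abs(a.cds_offset - b.cds_offset) < 500:
        penalty += w.p_near
    penalty += w.w_offtarget * (a.offtarget_count + b.offtarget_count)
    return bonus - penalty


@pytest.fixture(scope="module")
def filtered_gene():
    genome, genes, _ = make_fixture_genome(FixtureSpec(n_genes=1, exon_length=450), seed=17)
    model = genes[0]
    cands = annotate_positions(enumerate_guides(genome, model), model)
    audit = apply_all_filters(cands, genome, model, OffTargetPolicy())
    assert len(audit.retained) >= 10
    return genome, model, audit.retained


class TestSamplePairs:
    def test_exhaustive_when_small(self, filtered_gene):
        _, _, cands = filtered_gene
        pairs = sample_pairs(cands[:5], max_pairs=10_000, seed=0)
        assert len(pairs) == 10
        assert len({p.guide_keys for p in pairs}) == 10

    def test_sampled_branch_deterministic_and_distinct(self, filtered_gene):
        _, _, cands = filtered_gene
        n = len(cands)
        total = n * (n - 1) // 2
        k = total // 2
        p1 = sample_pairs(cands, max_pairs=k, seed=123)
        p2 = sample_pairs(cands, max_pairs=k, seed=123)
        assert len(p1) == k
        assert [p.guide_keys for p in p1] == [p.guide_keys for p in p2]
        assert len({p.guide_keys for p in p1}) == k
        p3 = sample_pairs(cands, max_pairs=k, seed=124)
        assert [p.guide_keys for p in p3] != [p.guide_keys for p in p1]

    def test_sampling_approximately_uniform(self, filtered_gene):
        # chi-square sanity over many seeds on a 10-candidate pool (45 pairs)
        from scipy.stats import chisquare

        _, _, cands = filtered_gene
        pool = cands[:10]
        counts: dict[frozenset, int] = {}
        draws = 400
        for seed in range(draws):
            for p in sample_pairs(pool, max_pairs=9, seed=seed):
                counts[p.guide_keys] = counts.get(p.guide_keys, 0) + 1
        all_pairs = [frozenset((a.key, b.key)) for a, b in combinations(pool, 2)]
        observed = [counts.get(k, 0) for k in all_pairs]
        assert sum(observed) == draws * 9
        _, pvalue = chisquare(observed)
        assert pvalue > 1e-3

    def test_fewer_than_two_candidates(self, filtered_gene):
        _, _, cands = filtered_gene
        assert sample_pairs(cands[:1], seed=0) == []
        assert sample_pairs([], seed=0) == []


class TestScorePair:
    def test_close_pair_scores_lower_by_strong_penalty(self, filtered_gene):
        genome, model, cands = filtered_gene
        w = ScoringWeights()
        pairs = sample_pairs(cands, seed=0)
        close = [p for p in pairs if p.genomic_cut_distance < 75]
        far = [p for p in pairs if p.coding_separation >= 500]
        assert close and far
        for p in pairs:
            score_pair(p, model, w)
        # any close pair carries the full p_close; removing it must recover p_near-free total
        for p in close:
            assert p.score.close_penalty == w.p_close
            assert p.score.near_penalty == 0.0
        for p in far:
            assert p.score.close_penalty == 0.0 and p.score.near_penalty == 0.0

    def test_component_arithmetic_single_isoform(self, filtered_gene):
        genome, model, cands = filtered_gene
        w = ScoringWeights()
        first_half = [c for c in cands if c.orf_fraction < 0.5]
        pair = next(
            p for p in sample_pairs(first_half, seed=0)
            if p.coding_separation >= 500 and p.genomic_cut_distance >= 75
        )
        s = score_pair(pair, model, w)
        assert s.transcript_bonus == 1.0  # single isoform
        assert s.five_prime_bonus == 2.0
        assert s.close_penalty == s.near_penalty == s.offtarget_penalty == 0.0
        assert s.total == pytest.approx(1.0 + 2.0 + s.tss_bonus)

    def test_matches_independent_recomputation(self, filtered_gene):
        genome, model, cands = filtered_gene
        w = ScoringWeights(w_transcript=1.5, w_five_prime=0.8, w_tss=2.0,
                           p_close=90.0, p_near=12.0, w_offtarget=4.0)
        for p in sample_pairs(cands, seed=1):
            score_pair(p, model, w)
            assert p.score.total == pytest.approx(spreadsheet_score(p, model, w))

    def test_total_is_signed_component_sum(self, filtered_gene):
        genome, model, cands = filtered_gene
        p = sample_pairs(cands, seed=0)[0]
        s = score_pair(p, model)
        assert s.total == pytest.approx(
            s.transcript_bonus + s.five_prime_bonus + s.tss_bonus
            - s.close_penalty - s.near_penalty - s.offtarget_penalty
        )

    def test_offtarget_monotonicity(self, filtered_gene):
        genome, model, cands = filtered_gene
        p = sample_pairs(cands, seed=0)[0]
        base = score_pair(p, model).total
        p.guide_a.offtarget_count += 2
        worse = score_pair(p, model).total
        p.guide_a.offtarget_count -= 2
        assert worse < base

    def test_unannotated_guides_rejected(self, filtered_gene):
        genome, model, cands = filtered_gene
        a = dataclasses.replace(cands[0], offtarget_count=None)
        b = cands[1]
        with pytest.raises(ValueError, match="off-target"):
            score_pair(make_pair(a, b), model)


class TestSelectTopPairs:
    def test_tie_break_lexicographic(self, filtered_gene):
        genome, model, cands = filtered_gene
        pairs = sample_pairs(cands[:4], seed=0)
        for p in pairs:
            score_pair(p, model)
        # force ties: give all pairs equal totals, check deterministic label order
        ranked = select_top_pairs(pairs, k=len(pairs), disjoint=False)
        totals = [p.score.total for p in ranked]
        assert totals == sorted(totals, reverse=True)
        for p, q in zip(ranked, ranked[1:]):
            if p.score.total == q.score.total:
                assert p.sort_label < q.sort_label

    def test_disjoint_mode_prefers_independent_pairs(self, filtered_gene):
        genome, model, cands = filtered_gene
        pairs = sample_pairs(cands, seed=0)
        for p in pairs:
            score_pair(p, model)
        top = select_top_pairs(pairs, k=2, disjoint=True)
        assert len(top) == 2
        assert not (top[0].guide_keys & top[1].guide_keys)
        best_disjoint = max(
            (p for p in pairs if not (p.guide_keys & top[0].guide_keys)),
            key=lambda p: (p.score.total, [-ord(c) for c in p.sort_label]),
        )
        assert top[1].score.total == best_disjoint.score.total

    def test_overlapping_fallback(self, filtered_gene):
        genome, model, cands = filtered_gene
        pairs = sample_pairs(cands[:3], seed=0)  # 3 pairs, all sharing guides
        for p in pairs:
            score_pair(p, model)
        top = select_top_pairs(pairs, k=2, disjoint=True)
        assert len(top) == 2  # falls back to overlapping pairs

    @pytest.mark.parametrize("seed", [0, 1])
    def test_equals_exhaustive_argmax(self, filtered_gene, seed):
        genome, model, cands = filtered_gene
        rng = np.random.default_rng(seed)
        w = ScoringWeights(
            w_transcript=float(rng.uniform(0, 3)),
            w_five_prime=float(rng.uniform(0, 3)),
            w_tss=float(rng.uniform(0, 3)),
            p_close=float(rng.uniform(50, 150)),
            p_near=float(rng.uniform(1, 40)),
            w_offtarget=float(rng.uniform(0, 10)),
        )
        pairs = sample_pairs(cands, max_pairs=10**9, seed=0)  # exhaustive
        for p in pairs:
            score_pair(p, model, w)
        best = select_top_pairs(pairs, k=1)[0]
        brute = max(pairs, key=lambda p: (p.score.total, [-ord(c) for c in p.sort_label]))
        assert best.guide_keys == brute.guide_keys


class TestDesignGene:
    def test_happy_path(self, filtered_gene):
        genome, model, _ = filtered_gene
        res = design_gene(genome, model, seed=5)
        assert res.status == "ok"
        assert 1 <= len(res.pairs) <= 2
        for p in res.pairs:
            assert p.score is not None

    def test_deterministic_under_seed(self, filtered_gene):
        genome, model, _ = filtered_gene
        r1 = design_gene(genome, model, seed=5)
        r2 = design_gene(genome, model, seed=5)
        assert [(p.guide_a.key, p.guide_b.key) for p in r1.pairs] == [
            (p.guide_a.key, p.guide_b.key) for p in r2.pairs
        ]
        assert [p.score.total for p in r1.pairs] == [p.score.total for p in r2.pairs]

    def test_gene_with_no_usable_guides(self):
        from conftest import single_exon_gene

        genome, model = single_exon_gene("ATATATATATATATATATATATATATAT")
        res = design_gene(genome, model, seed=0)
        assert res.status == "no_candidates"
        assert res.pairs == []
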