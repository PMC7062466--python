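"""Pair sampling, decomposed bonus/penalty scoring, and top-2 selection.

For each gene, up to ``max_pairs`` unordered candidate pairs are drawn
uniformly (exhaustively when the pool is small enough) and scored:

* bonus per transcript targeted by either guide (favours constitutive exons),
* bonus per guide cutting in the first half of the ORF,
* a TSS-proximity bonus decaying linearly over the gene span,
* a strong penalty for cut sites closer than 75 bp on the chromosome
  (overlapping guides can interfere with each other),
* an ordinary penalty for cut sites within 500 bp of spliced coding sequence
  (a second cut too close may restore the reading frame of the first),
* a penalty per predicted off-target site of either guide.

The two top-scoring pairs per gene are selected, by default sharing no guide
so that the two resulting reagents are independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .filters import FilterRecord, OffTargetPolicy, PamSiteIndex, apply_all_filters
from .genome_io import GeneModel, GenomeSequence
from .guide_enum import GuideCandidate, annotate_positions, enumerate_guides

logger = logging.getLogger(__name__)

CLOSE_DISTANCE_BP = 75  # genomic cut distance below which pairs are strongly penalized
NEAR_SEPARATION_BP = 500  # coding separation below which pairs are penalized


@dataclass(frozen=True)
class ScoringWeights:
    """Magnitudes of the score components (all configurable, all >= 0).

    Defaults keep the qualitative ordering strong-penalty >> ordinary penalty
    >> per-guide bonuses: the 75 bp penalty dominates any achievable bonus and
    the 500 bp penalty dominates per-guide bonuses but not transcript coverage
    across many isoforms.
    """

    w_transcript: float = 1.0  # per transcript targeted by either guide
    w_five_prime: float = 1.0  # per guide with orf_fraction < 0.5
    w_tss: float = 1.0  # scale of the TSS-proximity bonus
    p_close: float = 100.0  # cut distance < 75 bp (strong)
    p_near: float = 10.0  # coding separation < 500 bp
    w_offtarget: float = 5.0  # per predicted off-target site
    close_distance_bp: int = CLOSE_DISTANCE_BP
    near_separation_bp: int = NEAR_SEPARATION_BP

    def __post_init__(self) -> None:
        for name in ("w_transcript", "w_five_prime", "w_tss", "p_close", "p_near",
                     "w_offtarget"):
            if getattr(self, name) < 0:
                raise ValueError(f"scoring weight {name} must be >= 0")
        if self.p_close <= self.p_near:
            raise ValueError("p_close must exceed p_near (strong vs ordinary penalty)")


@dataclass
class PairScore:
    transcript_bonus: float = 0.0
    five_prime_bonus: float = 0.0
    tss_bonus: float = 0.0
    close_penalty: float = 0.0
    near_penalty: float = 0.0
    offtarget_penalty: float = 0.0

    @property
    def total(self) -> float:
        return (
            self.transcript_bonus
            + self.five_prime_bonus
            + self.tss_bonus
            - self.close_penalty
            - self.near_penalty
            - self.offtarget_penalty
        )


@dataclass
class GuidePair:
    guide_a: GuideCandidate  # 5' of guide_b on the spliced CDS
    guide_b: GuideCandidate
    score: PairScore | None = None

    def __post_init__(self) -> None:
        if self.guide_a.key == self.guide_b.key:
            raise ValueError("a pair requires two distinct guides")
        if self.guide_a.gene_id != self.guide_b.gene_id:
            raise ValueError("both guides must target the same gene")

    @property
    def genomic_cut_distance(self) -> int:
        return abs(self.guide_a.cut_site - self.guide_b.cut_site)

    @property
    def coding_separation(self) -> int:
        return abs(self.guide_a.cds_offset - self.guide_b.cds_offset)

    @property
    def guide_keys(self) -> frozenset:
        return frozenset((self.guide_a.key, self.guide_b.key))

    @property
    def sort_label(self) -> str:
        return self.guide_a.protospacer + self.guide_b.protospacer


def make_pair(a: GuideCandidate, b: GuideCandidate) -> GuidePair:
    """Order the two guides 5'->3' along the spliced CDS."""
    if a.cds_offset is None or b.cds_offset is None:
        raise ValueError("guides must be annotated before pairing")
    if (a.cds_offset, a.cut_site, a.strand) > (b.cds_offset, b.cut_site, b.strand):
        a, b = b, a
    return GuidePair(a, b)


def sample_pairs(
    candidates: list[GuideCandidate],
    max_pairs: int = 10_000,
    seed: int = 0,
) -> list[GuidePair]:
    """All unordered pairs, or a uniform sample of ``max_pairs`` of them.

    When the number of distinct pairs C(n,2) does not exceed ``max_pairs``
    every pair is returned (the sample is exhaustive and seed-independent);
    otherwise ``max_pairs`` distinct pairs are drawn uniformly without
    replacement, deterministically for a fixed seed.
    """
    n = len(candidates)
    if n < 2:
        logger.info("fewer than 2 candidates; no pairs to sample")
        return []
    total = n * (n - 1) // 2
    if total <= max_pairs:
        return [make_pair(a, b) for a, b in combinations(candidates, 2)]
    rng = np.random.default_rng(seed)
    picks = rng.choice(total, size=max_pairs, replace=False)
    picks.sort()
    # unrank k -> (i, j), i < j, pairs ordered (0,1), (0,2), ... (0,n-1), (1,2), ...
    counts = np.arange(n - 1, 0, -1)
    cum = np.cumsum(counts)
    rows = np.searchsorted(cum, picks, side="right")
    offsets = picks - np.concatenate(([0], cum[:-1]))[rows]
    cols = rows + 1 + offsets
    return [make_pair(candidates[int(i)], candidates[int(j)]) for i, j in zip(rows, cols)]


def score_pair(
    pair: GuidePair, model: GeneModel, weights: ScoringWeights = ScoringWeights()
) -> PairScore:
    """Compute the decomposed score and attach it to the pair.

    The near penalty is not applied on top of the close penalty: a pair under
    the 75 bp genomic threshold is already penalized by the stricter rule.
    """
    a, b = pair.guide_a, pair.guide_b
    for g in (a, b):
        if g.cds_offset is None or g.orf_fraction is None or g.tss_distance is None:
            raise ValueError("guides must be annotated before scoring")
        if g.offtarget_count is None:
            raise ValueError("off-target counts must be filled before scoring")
    span_lo, span_hi = model.span
    span = max(1, span_hi - span_lo)
    s = PairScore()
    s.transcript_bonus = weights.w_transcript * len(a.transcripts_hit | b.transcripts_hit)
    s.five_prime_bonus = weights.w_five_prime * sum(
        1 for g in (a, b) if g.orf_fraction < 0.5
    )
    s.tss_bonus = weights.w_tss * sum(
        min(1.0, max(0.0, 1.0 - g.tss_distance / span)) for g in (a, b)
    )
    if pair.genomic_cut_distance < weights.close_distance_bp:
        s.close_penalty = weights.p_close
    elif pair.coding_separation < weights.near_separation_bp:
        s.near_penalty = weights.p_near
    s.offtarget_penalty = weights.w_offtarget * (a.offtarget_count + b.offtarget_count)
    pair.score = s
    return s


def select_top_pairs(
    scored: list[GuidePair], k: int = 2, disjoint: bool = True
) -> list[GuidePair]:
    """Up to ``k`` pairs by (total desc, concatenated protospacers asc).

    With ``disjoint`` (default), each selected pair shares no guide with the
    previously selected ones whenever such a pair exists; otherwise the next
    best overlapping pair is taken.
    """
    ranked = sorted(scored, key=lambda p: (-p.score.total, p.sort_label))
    out: list[GuidePair] = []
    for _ in range(k):
        used = set().union(*(p.guide_keys for p in out)) if out else set()
        chosen = None
        if disjoint:
            chosen = next(
                (p for p in ranked
                 if p.guide_keys not in {q.guide_keys for q in out}
                 and not (p.guide_keys & used)),
                None,
            )
        if chosen is None:
            chosen = next(
                (p for p in ranked
                 if p.guide_keys not in {q.guide_keys for q in out}),
                None,
            )
        if chosen is None:
            break
        out.append(chosen)
    if len(out) < k:
        logger.info("only %d pair(s) available (requested %d)", len(out), k)
    return out


@dataclass
class DesignResult:
    """Full per-gene audit of the design pipeline."""

    gene_id: str
    status: str  # ok | no_candidates | single_guide_only | no_valid_pair
    pairs: list[GuidePair] = field(default_factory=list)
    n_enumerated: int = 0
    n_filtered: int = 0
    n_pairs_scored: int = 0
    seed: int = 0
    filter_records: list[FilterRecord] = field(default_factory=list)


def design_gene(
    genome: GenomeSequence,
    model: GeneModel,
    policy: OffTargetPolicy = OffTargetPolicy(),
    weights: ScoringWeights = ScoringWeights(),
    max_pairs: int = 10_000,
    seed: int = 0,
    k: int = 2,
    disjoint: bool = True,
    index: PamSiteIndex | None = None,
) -> DesignResult:
    """Run enumerate -> annotate -> filter -> sample -> score -> select for one gene."""
    result = DesignResult(gene_id=model.gene_id, status="ok", seed=seed)
    candidates = enumerate_guides(genome, model)
    annotate_positions(candidates, model)
    result.n_enumerated = len(candidates)
    if not candidates:
        result.status = "no_candidates"
        return result
    audit = apply_all_filters(candidates, genome, model, policy, index=index)
    result.filter_records = audit.records
    result.n_filtered = len(audit.retained)
    if not audit.retained:
        result.status = "no_candidates"
        return result
    if len(audit.retained) == 1:
        result.status = "single_guide_only"
        return result
    pairs = sample_pairs(audit.retained, max_pairs=max_pairs, seed=seed)
    for p in pairs:
        score_pair(p, model, weights)
    result.n_pairs_scored = len(pairs)
    result.pairs = select_top_pairs(pairs, k=k, disjoint=disjoint)
    if not result.pairs:
        result.status = "no_valid_pair"
    return result
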