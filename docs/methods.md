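# Methods

## Coordinate conventions and gene models

All internal coordinates are 0-based half-open; GFF3 I/O converts from/to the
format's 1-based closed convention. A gene model carries one or more
transcripts, each an ordered list of CDS exons in transcript 5′→3′ orientation.
Gene-level anchors used by scoring are defined across isoforms: the
transcription start site is the 5′-most transcript start over all isoforms,
the reference CDS is the longest spliced CDS (ties broken by transcript id),
and "the first half of the ORF" is measured on that reference. The spliced-CDS
offset of a genomic position is a strand-aware bijection between in-CDS
positions and `[0, spliced_cds_length)`; intron/UTR positions map to a
not-in-CDS marker. `N` bases are legal in genomes, but any protospacer+PAM
window containing one is discarded at enumeration: an undefined base cannot be
matched or synthesized.

## Candidate enumeration

SpCas9 candidates are all 20-mers immediately 5′ of an NGG PAM on either
strand. The blunt cut is placed between protospacer bases 17 and 18 (3 bp 5′
of the PAM), the standard SpCas9 geometry. Membership in the coding sequence
is decided by the *cut site*, not the whole protospacer: a guide whose 20-mer
overhangs an exon boundary still produces a coding lesion if the cut itself is
coding. No 5′-G is enforced on the spacer — in a tRNA-processed tandem
cassette the mature guide 5′ end is set by RNase cleavage, not by a Pol III
+1 requirement. Candidates are unique by (interval, strand) and sorted by
(cut site, strand), which makes every downstream step order-stable.

## Off-target policy

Published genome-wide guide designers reject guides with predicted off-target
sites but rarely print their exact thresholds, so the policy here is an
explicit, configurable surrogate with conservative defaults: a genomic site
counts as an off-target when the 20-mer matches with ≤ 3 total mismatches, 0
mismatches in the 12-bp PAM-proximal seed, adjacent to an NGG or NAG PAM, on
either strand; the on-target locus is excluded, and by default any off-target
rejects the guide (`reject_if_any_site`), in which case every guide entering
pair selection is genome-unique under the policy. Setting the flag off keeps
the counts for the scoring penalty instead. The scan vectorises all
PAM-adjacent windows of the genome into a byte matrix and Hamming-compares
each query against it; the test suite checks it exactly against a
per-character brute-force oracle under three different policies.

## Hard filters

Four independent predicates: off-target uniqueness; BbsI (`GAAGAC`) or BsaI
(`GGTCTC`) recognition in the protospacer in either orientation (such guides
could not survive the two Golden-Gate steps); homopolymer runs of ≥ 4
identical nucleotides (synthesis and Pol III termination artefacts — applied
to the protospacer only, since the PAM is never synthesized); and overlap of
the protospacer+PAM interval with *any* isoform's start codon. Note the PAM is
included in the overlap interval, so a plus-strand guide ending flush at the
ATG is removed (its PAM covers the codon) while a guide whose PAM faces away
is kept. Because the predicates are independent, the composed filter is
idempotent and order-invariant (property-tested over all 24 filter orders);
every removal is recorded with the failing rule and reason. Preference for
constitutive exons is expressed as the transcript-coverage *bonus* in scoring
rather than a hard all-isoform filter; callers wanting the strict behaviour
can pre-filter on `transcripts_hit`.

## Pair sampling and scoring

With `n` retained guides, all C(n,2) pairs are formed when that count is at
most `max_pairs` (default 10,000); otherwise `max_pairs` distinct pairs are
drawn uniformly without replacement by unranking combination indices under a
seeded generator, so the sampling branch is reproducible and, whenever the
pool is exhaustive, seed-independent. Guides within a pair are ordered 5′→3′
along the spliced CDS.

The score is a transparent sum of components, each magnitude configurable:

| component | default | trigger |
|---|---|---|
| transcript bonus | 1.0 / transcript | per transcript targeted by either guide |
| 5′-half bonus | 1.0 / guide | guide's cut in the first half of the reference ORF |
| TSS bonus | ≤ 1.0 / guide | `1 − tss_distance / gene_span`, clipped to [0, 1] |
| close penalty | 100 | genomic cut distance < 75 bp |
| near penalty | 10 | spliced coding separation < 500 bp |
| off-target penalty | 5.0 / site | sum of both guides' predicted off-target counts |

Design choices worth noting:

* The exact bonus/penalty magnitudes behind the qualitative description
  ("awarded", "penalized", "strongly penalized") are not published; the
  defaults preserve the ordering *strong penalty ≫ ordinary penalty ≫
  bonuses* — 100 exceeds any achievable bonus total on realistic gene models,
  while 10 exceeds per-guide bonuses but can be outweighed by covering many
  isoforms.
* The two distance rules are deliberately measured on different axes: the
  75-bp rule on *genomic* cut distance (physical interference between bound
  Cas9 complexes acts on the DNA), the 500-bp rule on *spliced coding*
  separation (frame restoration is a property of the mRNA). Both distances are
  recorded per pair. The stricter rule subsumes the weaker: a pair under 75 bp
  genomic is not additionally charged the near penalty.
* The TSS bonus's linear decay over the gene span is an invented functional
  form for "small distances to the TSS scored higher"; it is bounded per
  guide so it can never dominate the discrete bonuses, and both form scale are
  config-exposed.

Selection takes the top 2 pairs by (total desc, concatenated protospacers asc
as a deterministic tie-break). By default the second pair must share no guide
with the first — the two reagents made for a gene should fail independently —
falling back to the best overlapping pair when no disjoint one exists.

## Cloning simulation

Type IIS digestion is modelled exactly: for a recognition site at `q` reading
forward, the top strand is cut `cut_offset_top` nt after the site and the
bottom strand 4 nt further, producing 4-nt 5′ overhangs (BbsI `GAAGAC(2/6)`,
BsaI `GGTCTC(1/5)`); mirrored arithmetic handles reverse-orientation sites,
and circular molecules are scanned across the origin. Fragments carry their
overhangs such that concatenating fragment sequences reconstructs the input
(property-tested on random sequences). Golden-Gate assembly digests the
vector, discards every fragment still carrying a recognition site (the
re-cutting that drives one-pot reactions to completion), requires all pool
overhangs to be unique and non-palindromic, and chains fragments into a single
circle — mismatched, duplicated or self-complementary overhangs are errors
that name the overhang multiset.

The oligo architecture places the two BbsI sites in the amplification flanks
pointing inward and the two BsaI sites in the internal cassette pointing
outward, so step 1 (BbsI) transfers `proto1–cassette–proto2` into the vector
and step 2 (BsaI) replaces the cassette interior with the sgRNA scaffold +
tRNA. The step-2 overhangs are simply the first 4 nt of the scaffold and the
last 4 nt of the tRNA, so the final insert is literally
`proto1 + scaffold + tRNA + proto2` with zero recognition sites left — which
is asserted, along with single-occurrence of each protospacer, for every
assembled cassette. The default part sequences (handles, overhangs, scaffold,
tRNA, mock vector) are synthetic stand-ins with the documented architecture;
real vector flanks and primers are drop-in config (`cloning:` section).
`validate_oligo` independently re-scans every oligo and fails any motif
outside its intended segment, catching junction-created sites that the
per-protospacer filter cannot see.

## Screen classification and benchmarking

A cross is *lethal* when no correct-genotype adults eclose, *semi-lethal* when
they number fewer than half the balancer-class adults, *viable* otherwise;
a cross with zero flies of either class is classified lethal with a
low-confidence warning. The classifier is monotone in the correct-genotype
count. Benchmarking reports overall outcome percentages over **all** lines
(unscored lines stay in the denominator), and per-annotation-class rates:
false-negative = % viable among essential-gene lines, false-positive =
% lethal among nonessential-gene lines; unknown-annotation lines are tallied
but excluded from both rates. Records may carry raw counts, a categorical
outcome, or both; on conflict the recorded outcome wins with a warning, since
curated tables typically expose categories rather than counts.

Percentages are rounded half-away-from-zero to integers, which reproduces the
package's worked-example figures self-consistently; a `floor` mode is provided
because published tables occasionally truncate (e.g. 167/210 = 79.52 printed
as 79).

The screen simulator draws each essential-gene line lethal with probability
`sensitivity` and each nonessential-gene line viable with probability
`specificity`, splitting the remainder between semi-lethal and the opposite
extreme by `semi_lethal_fraction`, and emits fly counts consistent with the
outcome (balancer counts ~Poisson(40)). Defaults (210/54 lines, 0.79/0.89,
0.47) mirror the benchmarked screen's composition. `benchmark ∘ simulate`
recovers both probabilities within binomial sampling error; the acceptance
suite checks ±1 percentage point at 10,000 lines per class.

## Synthetic fixture genomes

The generator lays out `n_genes` alternating-strand genes on one contig, each
with jittered exon lengths (total divisible by 3, starting ATG), fixed intron
and UTR lengths, at the requested GC content, and can plant (a) exact copies
of a coding protospacer+PAM 23-mer into intergenic space as known off-targets
and (b) BbsI/BsaI motifs into coding sequence to exercise the restriction
filter. Everything is bit-reproducible under a seed, and the ground-truth
record lists every planted feature. Defaults (5 genes × 3 exons of ~300 bp,
120-bp introns, GC 0.43) give fly-like compact genes large enough to admit
500-bp-separated pairs.

What the fixtures do **not** emulate: repeat families and segmental
duplications (off-target pressure is far milder than in a real genome),
alternative isoform structure beyond what tests construct explicitly, soft
masking, chromosome-scale contigs, and biased codon usage. Passing tests
therefore demonstrate algorithmic correctness (enumeration, counting, scoring,
assembly are exact against independent oracles), not that the default
off-target policy matches any particular genome's guide-uniqueness landscape.

## Problem sizes and determinism

The test and acceptance workloads use genomes of 5–50 kb and 2–12 genes,
where every oracle (exhaustive 23-mer scans, per-character Hamming comparison,
exhaustive pair argmax over up to ~10⁵ pairs, 24-permutation filter-order
checks) runs exactly rather than approximately; the screen simulations use
10⁴ lines per class, where binomial error is ~0.4 percentage points. All
randomness flows through named seeds: batch runs derive a per-gene seed from
the run seed and a hash of the gene id, and the manifest records the config
hash and seed, making whole-run outputs byte-reproducible.

## Known limitations

* No on-target efficiency model (e.g. rule sets learned from screens) — the
  published pipeline used none, and scores here are positional/structural only.
* Off-target search is mismatch-only (no bulges, no CFD/MIT weighting) and
  exhaustive rather than index-accelerated; it is exact but not intended for
  chromosome-scale genomes.
* GFF3 only (no GTF); one level of gene→mRNA→CDS nesting is assumed.
* Ligation is modelled combinatorially (overhang identity), not
  thermodynamically; PCR requires exact primer matches.
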