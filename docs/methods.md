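# Methods

This note documents the models and procedures implemented in `copromito`,
the assumptions behind them, the parameters that matter, and the design
choices made where more than one reasonable implementation existed.

## The problem

A carnivore coprolite (fossilised dropping) contains DNA of at least two
organisms: the producer and its prey. A shotgun library from such a sample
is a mixture of short, damaged fragments from both mitogenomes (plus trace
taxa and environmental DNA). The pipeline answers three questions: *who is
in the sample* (competitive assignment), *what are their mitochondrial
genome sequences* (simultaneous iterative co-assembly), and *is the DNA
ancient* (damage authentication) — followed by downstream placement of the
assembled genome (annotation transfer, difference-count phylogenetics,
SNP genotyping with MDS) and dating (radiocarbon combination).

## Synthetic read generator

The generator (`copromito.synthetic`) emulates the relevant features of an
ancient single-end library:

- **Fragment lengths** — lognormal with median 48 nt (the hallmark of
  highly fragmented ancient DNA), truncated to the usable 20–101 nt range.
  Only the median and range of real libraries are well characterised; the
  lognormal family and its spread (`sigma = 0.35`, chosen so that the
  truncation removes little mass on either side) are modelling choices
  exposed in `FragmentLengthModel`.
- **Damage** — deamination applied on the read strand after orientation:
  G→A with probability `delta3 * decay^d` at distance `d` from the 3' end
  and C→T with `delta5 * decay^d` from the 5' end. This reproduces the
  signature of libraries built from end-repaired double-stranded templates,
  where the 3' G→A excess appears on reads of both orientations. Geometric
  decay (default `decay = 0.5`) is the standard single-parameter
  approximation of the overhang-length distribution; the generator does not
  model overhang repair explicitly.
- **Error** — uniform per-base substitution after damage.
- **Duplicates** — exact copies of earlier reads at a configurable rate
  (PCR/optical duplicates); no other duplicate structure.
- **Panels** — a star phylogeny: one ancestral random sequence and `n-1`
  derived genomes, each by independent per-site substitution. Every genome
  carries one synthetic CDS with a valid start/stop and no internal stop so
  that annotation transfer is testable. A star is the simplest shape that
  gives controlled pairwise divergence; its one artefact is that the centre
  genome shares short identical windows with every tip far more often than
  tips share them with each other, which inflates the shared-read category
  when the centre is a dominant source.

What the generator does **not** emulate: indel damage, coverage bias
(e.g. GC-correlated coverage seen in real libraries), quality-score decay,
contamination by additional unmodelled taxa, and NUMT-like nuclear copies.
Tests passing on this generator therefore demonstrate correctness of the
algorithms under the stated noise model, not robustness to every artefact
of real data.

## Read alignment

`copromito.align` is a seed-and-extend mapper for short reads against
small circular references.

- **Edit ceiling** (`maxdiff`): the maximum edit distance for a read of
  length `l` is the smallest `k` with `P(X > k) < miss_thres` for
  `X ~ Poisson(err·l)`, with `err = 0.02` and `miss_thres = 0.1`. At these
  defaults the ceiling is 1 mismatch for 20–26 nt reads rising to 4 for
  88–101 nt reads.
- **Seeding**: exact k-mers at every read offset, both strands. The
  effective seed length is `min(seed_len, l // (k+1))`; by the pigeonhole
  principle every placement within the ceiling contains an exact run at
  least that long, so the aligner is fully sensitive within its own model.
  Candidate starts are additionally widened by ±k because a seed located
  downstream of an indel reports a diagonal shifted by the gap length.
- **Scoring**: unit-cost banded edit distance (band ±k) with at most
  `max_gap_opens` gap openings (default 1, mirroring a gap-opening cap
  rather than affine scores). The production path scores the gapless
  diagonal with vectorised mismatch counts and explores single gaps by a
  prefix/suffix split over shifted diagonals; a generic banded DP covers
  the two-opening case. The first and last read bases must be aligned
  (gaps are internal); reference flanks are free.
- **Uncalled reference positions (N)** count as mismatches: an N carries
  no evidence that a read matches there. This matters during iterative
  co-assembly (below).
- **Mapping quality** is a three-tier uniqueness score over placement
  *loci* (placements clustered when on the same genome and strand within
  ±k): 0 when the best locus is tied anywhere in the panel call, 20 when a
  second-best locus exists one edit above the best, 37 otherwise. Loci are
  ranked by informative (N-discounted) edit distance with the strict edit
  as tie-break — an uncalled reference position is evidence neither for
  nor against a placement's uniqueness. Within a locus the representative
  with the fewest gap openings wins ties, so a gapped re-anchoring of an
  optimal ungapped alignment neither counts as a second placement nor
  displaces the ungapped interpretation. The downstream gate "mapping
  quality of at least 25" therefore passes only tier 37.

## Competitive assignment

A read is credited to a panel genome only when it matches it perfectly —
full length, zero edits, either strand, across the circular origin if
needed — and matches no other genome. Reads perfect in two or more genomes
go to `n_shared` (counted once, credited to nobody); reads with only
imperfect placements within the ceiling to `n_imperfect_only`; the rest to
`n_unmapped`. The four categories partition the pool exactly.

## Iterative co-assembly

The core procedure generalises to N genomes; the study case is N = 2.
Each round:

1. align the full pool simultaneously to the current references,
2. per target, keep reads with **no acceptable placement on any
   competitor** and mapping quality ≥ 25,
3. collapse identical placements (genome, start, strand, read bases) to
   unique reads,
4. call a majority consensus per position from at least `min_concordant=2`
   concordant unique sequences (reads or PCR fragments); positions below
   that support are N, flagged `no_coverage` (depth 0) or
   `single_coverage` (depth 1),
5. flag columns where more than 25% of aligned read bases disagree as
   `disputed`; keep the majority base only when the disagreement is
   entirely A-against-G within 10 bases of the contributing reads' 3'
   ends (`damage_explained`, the mechanised version of a manual
   damage-inspection step) or when a PCR fragment confirms the majority
   (`pcr_confirmed`); otherwise call N. Ties call N.

Rounds repeat until both consensuses are unchanged, up to
`max_iterations = 5`; non-convergence is a warning, not an error.

Three design points deserve explanation:

- **N is a mismatch, not a wildcard, during realignment.** Treating
  uncalled positions as free matches couples the two genomes into an
  oscillation: each genome's N runs "capture" the other genome's reads
  through zero-cost positions, the exclusivity filter then removes those
  reads from their true genome, coverage collapses there, and the N runs
  swap sides every round. With N as mismatch the uncalled set can only
  shrink read support, so the iteration contracts to a fixed point.
- **Exclusivity uses the N-discounted edit distance.** For the question
  "could this read come from the competitor?", edit distance *minus* the
  uncalled positions covered is compared against the ceiling: an N is no
  evidence of a difference, so a read is still considered a cross-mapper
  when only uncalled positions separate it from the competitor. This
  removes limit cycles in which a borderline read's exclusivity toggled
  with a single N, at the price of conservatism: around uncalled runs,
  more reads are treated as potentially cross-mapping, so ambiguous
  low-divergence regions stay uncalled rather than being called from
  possibly misattributed reads.
- **Within-round joint fixed point.** Placements are frozen within a
  round, but the gates are not: calling a position N raises the
  recomputed edit distance of reads spanning it; correcting a base
  re-admits reads that disagreed with the previous reference; and either
  change on one genome can flip a read's exclusivity on the other. None
  of these cascades needs realignment, so acceptance, exclusivity and
  consensus calling are re-evaluated jointly across all genomes against
  each provisional consensus until the sequences stop changing, inside
  every round. The co-assembly also asks the aligner to retain placements
  up to two edits above the ceiling (never letting them influence mapping
  quality) so that re-gating within the round sees boundary-crossing
  placements instead of waiting for the next realignment. With these in
  place the realignment iteration reaches its fixed point in three to
  five rounds at the study scale.

Gap filling mirrors the study workflow: `propose_pcr_targets` emits
amplicon intervals (primer margin 25 nt, amplicon cap 150 nt) covering all
gap and singleton positions; error-free consensus fragments re-enter the
pileup as ordinary concordant evidence (they have no mapping quality and
bypass that gate, but count once each).

Consensus coordinates stay in the frame of the round's reference: the
generator produces no indels, so a majority-deletion column (possible only
through alignment artefacts) calls N + disputed rather than contracting
the coordinate frame.

## Damage authentication

Substitution rates are computed against the final consensus, stratified by
the 12 substitution types and by distance 0–24 from each read end, in
read-strand coordinates (minus-strand placements are compared against the
reverse-complemented consensus segment). Opportunities are counted per
consensus base, and consensus-N positions are excluded from both numerator
and denominator. The verdict is `authentic_like` when the terminal 3' G→A
or 5' C→T rate is at least `fold_threshold = 3` times its interior plateau
(mean over distances 10–24) with ≥ 100 opportunities at the terminal
position; `flat` otherwise; `insufficient` when neither end has enough
opportunities, *and* the terminal mismatch count exceeds the plateau's
Poisson expectation by more than three standard deviations (with a floor
of one expected hit) — without the significance condition a near-zero
plateau is formally "exceeded" by a single noise hit. The three-fold
factor and the significance floor are this package's operational
criterion — the qualitative hallmark (elevated terminal rates) has no
published numeric threshold. Note that reads failing the edit ceiling or
the mapping-quality gate are absent from the profile, which biases
estimated terminal rates slightly downward at high damage levels; the
recovery tests budget for this within binomial sampling error.

## Annotation transfer

A banded Needleman–Wunsch (unit costs, band 200, vectorised row updates
with a prefix-min for gap runs) aligns the assembled genome end-to-end
with an annotated reference; circular inputs are first rotated to a shared
anchor k-mer near the reference origin. Feature boundaries map through the
alignment; a boundary falling in a deletion moves to the nearest aligned
column toward the feature interior and is flagged. CDS validation uses the
vertebrate mitochondrial code: starts {ATG, ATA, GTG}, stops {TAA, TAG,
AGA, AGG}, and incomplete terminal T/TA stops (completed by
polyadenylation in vivo) pass with a flag.

## Phylogenetics

Distances are p-distances (difference counts / sites used) with complete
deletion as the default site filter; no multiple-hit correction by default
(difference counts are the reported quantity), Jukes–Cantor optional.
Trees are built by Neighbor-Joining with the standard Q criterion;
negative intermediate branch lengths are clamped to zero with the deficit
shifted to the sister edge, preserving the pair's summed length. Supports
come from column bootstrap (default 500 replicates, seeded): the support
of an internal edge is the fraction of replicate NJ trees containing its
bipartition. Maximum-likelihood and minimum-evolution inference are out of
scope; NJ is retained as the distance-based member of the method family.

## SNP genotyping and MDS

Low-coverage ancient samples cannot support diploid calls, so genotyping
is pseudo-haploid: per panel site, the majority base among mapped,
quality-gated reads, with the call set to missing when covering depth is
below 2, the majority is tied, or any third allele is observed. Samples
are compared by allele-sharing distance, `1 − matches/shared`, over
non-missing sites (pairs sharing fewer than `min_shared = 100` sites are
an error, not a silent zero), and embedded by classical (Torgerson) MDS:
double-centre the squared distance matrix, eigendecompose, scale
eigenvectors by the root of their positive eigenvalues. Negative
eigenvalues (non-Euclidean input) are truncated and reported.

## Radiocarbon combination

Two replicate measurements of one sample combine arithmetically: the mean
age truncated toward zero, and sigma `sqrt(Σ sigma_i²)/n` rounded half-up
— the only rounding convention consistent with the published combined
value this module reproduces (32,316 ± 215 and 32,623 ± 200 → 32,469 ±
147 BP). An inverse-variance weighted mean with the chi-square consistency
statistic is available as an alternative. Calibration to calendar years
requires an external calibration curve; a hook exists but no curve is
bundled.

## Problem sizes and numerical choices

- The co-assembly recovery experiment uses two 16-kb circular genomes at
  5% divergence, 30× coverage per genome (~20,000 reads), damage
  `delta3 = delta5 = 0.1`, `decay = 0.5`, error 0.001, and round-0
  references diverged ~1% from the truths (of the same order as the
  reference-to-final divergence observed in real reference-guided
  assemblies of this kind). Other experiments use 2–8-kb genomes and
  3,000–10,000 reads — large enough for binomial 3σ bounds to be tight,
  small enough to iterate on.
- All randomness flows through `numpy.random.default_rng` seeds;
  identical seeds give byte-identical read pools and pipeline outputs.
- Alignment ties: within a placement locus, fewer gap openings win; among
  loci, ties zero the mapping quality. Majority ties in consensus calling
  and genotyping are never broken arbitrarily — they yield N/missing.

## Known limitations

- At 5% inter-genome divergence a substantial fraction of 48-nt reads is
  compatible with both genomes and is deliberately discarded by the
  exclusivity filter; regions of locally low divergence therefore stay
  uncalled (N) without PCR evidence (roughly a fifth of positions under
  the recovery experiment's conditions). This is the intended behaviour of
  the exclusive-mapping strategy, not a defect; called positions are
  near-exact. At realistic producer-versus-prey divergences (an order of
  magnitude larger) the uncalled fraction shrinks to coverage gaps alone.
- The gate fixed point is not unique: evaluating exclusivity against the
  current consensuses (as done here) settles on a more conservative
  called set than pinning the exclusivity pool to alignment-time
  acceptance would; the two differ only around ambiguous runs, with
  identical accuracy over called positions in our experiments.
- The aligner enumerates candidate loci by dictionary lookup and is meant
  for mitogenome-scale references, not nuclear genomes.
- The mapping-quality model is a three-tier uniqueness gate, not a
  probabilistic posterior; it reproduces the gate semantics the pipeline
  needs, nothing more.
- `maxdiff` assumes sequencing error is the only mismatch source; damage
  and reference divergence consume the same budget, which is what makes
  heavily damaged terminal bases slightly under-represented in profiles.
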