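# Methods

This note documents the models, rules and numerical choices behind
`chromoforge`, what the synthetic fixtures do and do not emulate, and the
design decisions taken where the problem was genuinely open.

## Coordinate model and edit algebra

All internal coordinates are 0-based half-open on the forward strand; GFF3
I/O converts to 1-based inclusive. Minus-strand features keep forward-strand
coordinates and are reverse-complemented on extraction, so a single
coordinate frame covers the whole chromosome. Ambiguity codes are rejected
at load: a synthesis design must be fully specified.

Every design rule emits `Edit` records (deletion / insertion / substitution)
in *original* coordinates; the combined `EditLog` must be pairwise
non-overlapping, which makes application a single deterministic
left-to-right splice and makes rule order irrelevant to the final sequence.
The `LiftoverMap` derived from a log is piecewise monotone; equal-length
substitutions preserve coordinates (the base changes, the frame does not),
which is what lets CDS features containing PCRTag recodings or stop swaps
lift intact. Positions inside deletions map to a `deleted` sentinel,
designed positions inside insertions to `novel`. The round-trip property
(designed[lift(p)] == original[p] for untouched p) is enforced by a
brute-force tagging oracle over hundreds of random logs in the tests.

## Redesign rules

Applied in a fixed order — element deletions, TAG swap, loxPsym insertion,
PCRTag recoding, telomere capping, chunk-junction recoding — so every
coordinate is computed once in the original frame. The order is a
convention; because the log is non-overlapping, any order yields the same
sequence.

- **Element deletion.** Every tRNA, LTR, subtelomeric repeat and
  non-essential intron is deleted. Deleted tRNA/LTR loci are replaced in
  place by one loxPsym landmark site. Subtelomeric repeats abutting a
  terminal telomere are left for telomere capping to absorb, so the two
  rules never overlap. Elements overlapping an essential CDS, or lying
  within the centromere buffer, are skipped with a warning rather than
  failing the run — a validator surfaces any residue.
- **TAG→TAA stop swap.** The terminating codon is read from the *spliced*
  CDS, never from a genomic window, so stops whose codon is interrupted by
  an intron are found (an intron-naive scan provably misses them; the
  regression test constructs exactly this case). The edit is a single
  strand-aware G→A substitution at the stop's third position — the minimal
  change. If that base lies inside another gene's frame where the change
  would be non-synonymous, the gene is skipped and warned, never silently
  edited.
- **loxPsym insertion.** One 34-bp loxPsym site (13-bp arm / 8-bp symmetric
  spacer / 13-bp arm; the site equals its own reverse complement) is
  inserted 3 bp past the stop of every non-essential gene. The 3-bp offset
  is a convention made configurable — only "in the 3′ UTR" is prescribed.
  Guards, in order: (a) *centromere buffer*, default 100 bp on each side of
  an annotated centromere, within which no edit of any kind is allowed —
  the default reflects the documented finding that a site 66 bp from a
  centromere (intended: 100 bp) measurably impairs growth; (b) *Puf3
  guard*: if the 200-bp 3′ window on the coding strand contains the Puf3p
  consensus TGTAHATA (H = A/C/T), mitochondrial-function genes are skipped
  and others warned — loxPsym insertion into Puf3-motif 3′ UTRs disrupts
  mRNA localization to mitochondria; window size and policy are this
  package's choices; (c) *overlap guard*: the insertion point may not fall
  inside another feature or an existing edit; (d) *convergent merge*: two
  candidate points within 50 bp collapse to one shared site at their
  midpoint.
- **PCRTags.** For each gene (longest first), codon-aligned windows ≥50 bp
  inside a single CDS block are recoded by exhaustive per-codon Hamming-
  distance maximization (ties broken lexicographically — deterministic, no
  heuristic; the search is trivially feasible at primer length). A window
  qualifies as a primer if wild-type and recoded variants both have Wallace
  Tm (2·AT + 4·GC) in 54–66 °C, differ at ≥8 positions with ≥1 in the 3′
  hexamer, and pair into a 200–800 bp amplicon; up to 2 non-overlapping
  tags per gene. The Wallace rule was chosen over nearest-neighbor models
  for determinism and zero dependencies, with bounds widened accordingly.
  Because PCRTag recoding operates in the original frame on windows that
  cannot collide with any other rule's edits (they sit mid-CDS), the
  pipeline keeps one coordinate frame throughout.
- **Telomere capping.** Each terminal telomere plus its abutting
  subtelomeric repeat is block-substituted with the user-supplied seed
  (reverse complement on the right arm). The seed content is an input; no
  canonical sequence is bundled. Capping is undefined for circular
  topology.

`verify_design` re-derives every rule from the two genomes alone (no edit
log): residual spliced TAG stops, residual deleted-class elements, any
sequence difference within the centromere buffer (windows anchored at the
centromere feature in each genome), junction recognition sites inside chunk
bodies, non-synonymous CDS changes, and loxPsym sites at an essential
gene's 3′ offset. The guard-soundness property — verify(run_design(·)) has
zero violations — is asserted on the default fixture.

## Synthesis partitioning

Chunk bodies must contain no occurrence of the junction enzyme's
recognition pattern on either strand. The default enzyme is SfiI
(GGCCNNNNNGGCC), whose cut leaves a 3-nt programmable overhang; the pattern
is its own reverse complement, so one scan suffices. In-CDS occurrences are
destroyed by the lexicographically first synonymous codon change that does
not recreate the pattern nearby; occurrences outside any CDS cannot be
recoded and must coincide with a junction cut (the partitioner forces the
cut at the site's midpoint or raises an error naming the interval).

Partitioning is greedy left-to-right over feature-free candidate positions:
target size is the midpoint of the 4,800–9,800 bp bounds, ties go to the
leftmost candidate, and a cut is only taken if the remainder is itself
partitionable. Greedy with fixed tie-breaks was chosen over global
optimization because the only stated objective is the size range, and
determinism matters more than optimality here.

Overhangs are assigned lexicographically first-feasible, excluding
self-complementary sequences (none exist at odd length; 16 of 256 at
length 4) and requiring distinctness within each megachunk and across its
boundary. Megachunks follow the 2-then-5 rule (the final one takes the
remainder), letters A, B, C, …, markers alternating LEU2, URA3, … starting
with LEU2. The synthesis bill sums chunk bodies plus two junction adapters
each (default 20 bp), one marker cassette per megachunk (placeholder
2,000 bp) and a 500-bp SwAP-In homology overlap per megachunk; marker and
overlap lengths are placeholders, configurable, and the bill's invariant
`synthesized_total ≥ chromosome_length` holds for any settings.

## Verification

- **Perfect-match landscape.** A design position is covered iff ≥1 length-k
  window containing it occurs exactly (either strand, canonical k-mer form)
  in the contigs; k defaults to 50 (minimum 15). Uncovered runs are
  deviations; a single interior substitution uncovers exactly one position.
  Amplification is flagged where the contig/design k-mer multiplicity ratio
  exceeds 1.75 (matching the repeat-caller threshold; the underlying
  reports give integer tandem copies, and 1.75 separates 1× from 2× with
  margin). Foreign insertions are contig k-mer runs absent from the design,
  anchored between two design-mapped flanks, with estimated inserted length
  ≥50 bp (shorter runs are indistinguishable from substitutions, which
  produce runs of exactly k windows). This operates on contigs with a fixed
  k — a desk-scale analog of read-based perfect-match genotyping, not a
  reimplementation of any read pipeline. Equivalence with a quadratic
  substring-search oracle is asserted on ≤2-kb sequences.
- **Repeat calling.** Depth is averaged into 100-bp bins (per-base Poisson
  noise at depth 30 would otherwise fragment runs), normalized by the
  genome-wide mean, thresholded at 1.75, merged across ≤200-bp gaps and
  filtered to ≥1 kb. The background mean is then re-estimated excluding
  called regions — a multi-kilobase amplification inflates the naive
  genome-wide mean and would bias copy numbers low — and copy number is
  round(region mean / background mean). The caller is exactly invariant to
  global depth scaling.
- **Growth fitting.** Exponential growth linear in log space: OLS of
  ln(OD) on t, reporting μ (h⁻¹), intercept and R². The window is either
  explicit or the maximum-R² sliding window of 5 consecutive points —
  window selection is explicit because real series include lag and
  saturation phases. Constant OD returns μ = 0 with R² reported as 0 by
  convention; non-positive OD in the window is an error.

## eccDNA model

A locus is an ordered list of elements and loxPsym sites. Because the
loxPsym spacer is symmetric, every unordered site pair yields both an
excision (circle + residual, each retaining one recombinant site) and an
inversion (interval reversed, orientations flipped, both sites kept);
sister-chromatid mode adds a duplication (one molecule gains the interval
and a site, the sister loses the interval). Products are canonicalized —
circles minimized over rotation and reflection-with-flip — and
deduplicated. Only single events are enumerated; iterated recombination is
available by re-application but not exhaustively expanded (combinatorial
blow-up). A circle is a propagable SPecc iff it carries ≥1 ARS.

The inheritance simulator is explicitly **phenomenological** — the
observations it mirrors (uneven inheritance, variable copy number,
enrichment under selection) come with no measured rates, so all parameters
are exposed: replication (`ars_doubling` doubles copies pre-division;
`none` does not), segregation bias `a` = probability a copy stays in the
mother (0.5 = unbiased), selection (`none`; `advantage s`: non-carriers
survive with probability 1/(1+s); `dropout`: non-carriers die). Both
daughter lineages are tracked each generation (the pedigree doubles), so
without replication and selection the total copy count is conserved
*exactly*, not just in expectation. Memory grows as n_lineages·2^g;
simulations here use ≤ a few thousand founders over ≤10 generations.
"Carrier fraction" means cells with ≥1 copy — a proxy for
reporter-positive cells, with no fluorescence-intensity calibration
attempted.

## Synthetic fixtures

The toy chromosome (default 60 kb, 30 genes, 30% essential, 15%
mitochondrial-function, 3 tRNAs, 4 LTRs, 3 ARSs, 20% intron-bearing genes,
central centromere, telomere+subtelomere ends) is self-consistent by
construction: genes are ATG + sense codons + stop with configurable stop
proportions (default TAA 0.5 / TAG 0.3 / TGA 0.2 — enough TAG genes to
exercise the swap), introns have GT…AG boundaries, and ~30% of introns
interrupt the stop codon itself to exercise spliced-frame stop detection.
Mitochondrial-function genes get a planted TGTAAATA in their 3′ window so
the Puf3 guard fires. One seed governs everything through per-component
spawned streams, so adding a feature class does not shift unrelated draws.

What the fixtures do **not** emulate: real codon usage or GC skew,
overlapping or nested gene models, multi-intron genes, repetitive DNA
beyond the subtelomeric unit, and read-level sequencing error. Passing
tests therefore demonstrate the correctness of the rules and detectors on
clean annotation and exact sequence, not robustness to messy real-world
annotation.

Artifact injection produces contigs with known truth: tandem amplification
(optionally interspersed with vector sequence between copies — the
signature of plasmid backbone riding in with a repeated chunk), foreign
insertion with partial landing-site duplication, and substitutions. Depth
simulation draws per-base Poisson(mean·copy) from the truth table.

## Problem sizes and determinism

The default test suite and the acceptance script run the full pipeline on
the 60-kb / 30-gene toy chromosome (≈8 chunks, ≈60 PCRTag pairs), repeat
calling on 50-kb tracks at depth 30, and inheritance simulations of a few
thousand lineages — sizes chosen so the whole suite completes in seconds
while every code path (guards, forced junctions, intron-split stops,
convergent merges) is exercised. All randomness flows from explicit integer
seeds; identical inputs produce byte-identical designed sequences.

## Known limitations

- PCRTag primers are checked for mismatch count, Tm and uniqueness-by-
  construction, not thermodynamics (no dimer/hairpin screening).
- In-silico PCR is exact-match (tolerance configurable); it models
  presence/absence discrimination, not amplification efficiency.
- The partitioner does not score codon context of junction recodings and
  does not model inefficient digestion.
- verify_design compares annotated CDS translations; unannotated ORFs are
  invisible to it.
- The eccDNA simulator's parameters are placeholders for exploration; no
  fit to measured retention or fluorescence data is claimed.
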