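# chromoforge

Design, partition, verify and SCRaMbLE-model synthetic yeast chromosomes.

`chromoforge` is a desk-scale toolkit for the redesign rules used to build
synthetic *Saccharomyces cerevisiae* chromosomes (the Sc2.0 style), aimed at
synthetic-genomics researchers who want to apply, audit, or stress-test those
rules computationally:

- **Redesign rules** — delete tRNAs, LTRs, subtelomeric repeats and
  non-essential introns (with loxPsym "landmark" sites replacing deleted
  tRNA/LTR loci); recode every spliced TAG stop codon to TAA with a single
  G→A substitution; insert a 34-bp loxPsym site 3′ of every non-essential
  gene, guarded by a centromere buffer, a Puf3p-consensus (TGTAHATA) scan of
  the 3′ window, feature-overlap checks and convergent-gene merging; water-
  mark genes with synonymous PCRTag primer pairs; cap telomeres with a seed
  sequence. All edits accumulate in one log with original↔designed
  coordinate liftover, and `verify_design` re-derives every rule from
  scratch on any designed sequence.
- **Synthesis partitioning** — tile the design into 4.8–9.8 kb chunks with
  recognition-site-free bodies (in-CDS sites removed synonymously),
  non-palindromic junction overhangs, 2-then-5 megachunk grouping with
  alternating LEU2/URA3 markers (SwAP-In), and a synthesized-DNA bill.
- **Verification** — a perfect-match k-mer landscape that diffs assembled
  contigs against the design (substitutions, amplifications, anchored
  foreign insertions); a depth-track repeat caller reporting integer tandem
  copy numbers; and an exponential growth-rate estimator, ordinary least
  squares of ln(OD) on time (μ in h⁻¹, R²).
- **eccDNA / SPecc modeling** — enumerate Cre×loxPsym excision, inversion
  and sister-chromatid duplication products of a loxPsym-formatted locus,
  classify propagable ARS-bearing circles (SPeccs), and simulate their
  replication/segregation/selection dynamics down a dividing pedigree.
- **Fixtures** — seeded generators for toy chromosomes, assembly artifacts
  with truth tables, and Poisson depth tracks, so everything above is
  testable without downloads.

## Worked example

```python
from chromoforge import DesignRuleSet, generate_toy_genome, run_design, \
    verify_design, partition_chunks, group_megachunks

genome = generate_toy_genome(seed=42)                 # 60 kb, 30 genes
rules = DesignRuleSet(telomere_seed="ACGGTTTACCCTGTG" * 4)
designed, log, report = run_design(genome, rules)
print(len(designed), report.counts["loxpsym_utr"], report.counts["tag_swaps"])
print(len(verify_design(genome, designed, rules)))
chunks, final = partition_chunks(designed)
print([c.length for c in chunks])
```

prints

```
55636 18 8
0
[5850, 7300, 7300, 7572, 7148, 7300, 7300, 5866]
```

meaning: the 60,000-bp toy chromosome shrank to 55,636 bp after element
deletion and telomere capping; 18 loxPsym sites were inserted 3′ of
non-essential genes (3 skipped by the Puf3 guard on mitochondrial-function
genes) and 8 TAG stops were swapped to TAA; the independent re-check found
zero rule violations; and the design tiles into 8 synthesis chunks, all
within the 4.8–9.8 kb range.

The `examples/` directory contains one narrative script per capability
(redesign, PCRTag screening of a chimeric chromosome, chunk partitioning,
assembly verification, eccDNA enumeration and inheritance); each prints its
numbers with a line on what they mean. A thin CLI mirrors the library:
`chromoforge design|pcrtag|chunk|verify|ecc|fixtures --help`.

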