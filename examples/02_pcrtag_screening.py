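"""In-silico PCRTag genotyping of a partially synthetic chromosome.

Builds a chimeric template that switches from the designed sequence to
wild type halfway along the chromosome -- the situation during megachunk-
by-megachunk replacement -- and screens it with every designed tag pair.
"""

from chromoforge import DesignRuleSet, generate_toy_genome, run_design
from chromoforge.annotation_io import EditLog, apply_edits
from chromoforge.pcrtag import pcrtag_screen

genome = generate_toy_genome(seed=42)
designed, log, report = run_design(
    genome, DesignRuleSet(telomere_seed="ACGGTTTACCCTGTG" * 4))
tags = sorted(report.pcrtags, key=lambda p: p.amplicon_start)
print(f"designed {len(tags)} PCRTag pairs")

# chimera: synthetic left half, wild-type right half
x = len(genome) // 2
chimera = apply_edits(genome.sequence,
                      EditLog([e for e in log if e.orig_end <= x]))

calls = pcrtag_screen(chimera, tags)
statuses = [c.status for c in calls]
switch = statuses.index("WT") if "WT" in statuses else len(statuses)
print("genotype calls along the chromosome:")
print("  " + " ".join(statuses))
print(f"synthetic/wild-type boundary lies between tag "
      f"{calls[switch - 1].tag_id} and {calls[switch].tag_id}")
# SYN calls mean only the synthetic (recoded) primer pair amplified; the
# first WT call localizes how far the synthetic DNA extends.
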