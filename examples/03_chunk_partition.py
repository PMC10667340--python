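"""Partition a designed chromosome into synthesis chunks and megachunks.

Chunks (4.8-9.8 kb) are the units of DNA synthesis; megachunks (2 chunks
for A, 5 thereafter) are the units of in-vivo integration, each ending in
an alternating LEU2/URA3 marker for SwAP-In selection.
"""

from chromoforge import (
    DesignRuleSet, assign_overhangs, generate_toy_genome, group_megachunks,
    partition_chunks, run_design, synthesis_bill,
)

genome = generate_toy_genome(seed=42)
designed, _, _ = run_design(
    genome, DesignRuleSet(telomere_seed="ACGGTTTACCCTGTG" * 4))

chunks, final = partition_chunks(designed)
assign_overhangs(chunks)
megas = group_megachunks(chunks)
bill = synthesis_bill(chunks, megas)

print(f"{len(chunks)} chunks in {len(megas)} megachunks")
for m in megas:
    labels = ", ".join(c.label for c in m.chunks)
    print(f"  megachunk {m.letter} [{m.marker}]: {labels}")
print("chunk sizes (bp):",
      ", ".join(f"{c.label}={c.length}" for c in chunks))
print("junction overhangs:",
      ", ".join(c.right_junction.overhang for c in chunks[:-1]))
print(f"synthesized total : {bill.synthesized_total:,} bp "
      f"(bodies + adapters + markers + overlaps)")
print(f"chromosome length : {bill.chromosome_length:,} bp")
# The synthesized total always exceeds the chromosome length: junction
# adapters, marker cassettes and SwAP-In homology overlaps are synthesized
# but do not all persist in the final chromosome.
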