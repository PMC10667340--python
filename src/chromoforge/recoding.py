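"""Codon-level rewriting: TAG->TAA stop swaps and constrained synonymous recoding.

Only the standard nuclear genetic code is supported. The stop-swap is
intron-aware: the terminating codon is read from the SPLICED coding sequence,
not from a naive genomic window, so genes whose stop codon is annotated past
an intron are handled correctly (a naive scan silently misses them).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from .annotation_io import Edit, EditLog, Feature, Genome

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: codon -> amino acid ('*' for stop), standard nuclear code
CODON_TABLE: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TABLE[_stop] = "*"

#: amino acid -> sorted list of codons
SYNONYMS: dict[str, list[str]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    SYNONYMS.setdefault(_aa, []).append(_codon)


class RecodingError(ValueError):
    """Raised when a requested recoding is infeasible."""


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def translate(seq: str) -> str:
    """Translate an in-frame DNA string; stops render as '*'."""
    if len(seq) % 3:
        raise RecodingError(f"length {len(seq)} not a multiple of 3")
    return "".join(CODON_TABLE[seq[i:i + 3]] for i in range(0, len(seq), 3))


@dataclass
class RecodingResult:
    original_fragment: str
    recoded_fragment: str
    substitutions: list[tuple[int, str, str]] = field(default_factory=list)
    objective_value: float = 0.0


# ---------------------------------------------------------------------------
# spliced CDS access
# ---------------------------------------------------------------------------

def spliced_cds(genome: Genome, gene_id: str) -> str:
    """Concatenated exon sequence of a gene, in translation order.

    Minus-strand genes are reverse-complemented; intron intervals contained
    in CDS blocks are excised.
    """
    gene = genome.feature_by_id(gene_id)
    blocks = genome.cds_blocks(gene_id)
    if not blocks:
        raise RecodingError(f"gene {gene_id} has no CDS blocks")
    introns = genome.introns(gene_id)
    pieces = []
    for b in blocks:
        segs = [(b.start, b.end)]
        for i in introns:
            segs = [
                part
                for s, e in segs
                for part in (((s, min(e, i.start)), (max(s, i.end), e)))
                if part[0] < part[1]
            ] if i.start < b.end and i.end > b.start else segs
        for s, e in segs:
            pieces.append(genome.sequence[s:e])
    cds = "".join(pieces)
    if gene.strand == "-":
        cds = revcomp(cds)
    if len(cds) % 3:
        raise RecodingError(
            f"gene {gene_id}: spliced CDS length {len(cds)} not divisible by 3")
    return cds


def _spliced_genomic_positions(genome: Genome, gene_id: str) -> list[int]:
    """Genomic positions of the spliced CDS, in translation order."""
    gene = genome.feature_by_id(gene_id)
    introns = genome.introns(gene_id)
    positions: list[int] = []
    for b in genome.cds_blocks(gene_id):
        for p in range(b.start, b.end):
            if any(i.start <= p < i.end for i in introns):
                continue
            positions.append(p)
    if gene.strand == "-":
        positions.reverse()
    return positions


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def swap_tag_stops(genome: Genome,
                   skip_check=None) -> tuple[EditLog, dict]:
    """Recode every TAG terminating codon to TAA with one G->A substitution.

    The substitution targets the third position of the SPLICED stop codon,
    strand-aware. ``skip_check(genomic_pos)`` may veto an edit (e.g. when the
    base lies inside another feature where the change would be
    non-synonymous in that feature's frame); vetoed genes are skipped with a
    warning, never silently edited.

    Returns (EditLog, report) where report counts genes scanned/edited/skipped.
    """
    edits = []
    report = {"genes_scanned": 0, "tag_stops": 0, "edited": 0,
              "skipped": [], "warnings": []}
    for gene in genome.genes():
        if gene.attributes.get("invalid"):
            continue
        blocks = genome.cds_blocks(gene.id)
        if not blocks:
            continue
        report["genes_scanned"] += 1
        cds = spliced_cds(genome, gene.id)
        if cds[-3:] != "TAG":
            continue
        report["tag_stops"] += 1
        positions = _spliced_genomic_positions(genome, gene.id)
        third_pos = positions[-1]  # third base of the stop, genomic coords
        if skip_check is not None and not skip_check(third_pos):
            report["skipped"].append(gene.id)
            report["warnings"].append(
                f"{gene.id}: TAG stop swap vetoed at position {third_pos}")
            continue
        # confirm no overlapping CDS of another gene would change protein
        conflict = _stop_swap_conflict(genome, gene, third_pos)
        if conflict:
            report["skipped"].append(gene.id)
            report["warnings"].append(f"{gene.id}: {conflict}")
            continue
        new_base = "A" if gene.strand == "+" else "T"
        edits.append(Edit("substitution", third_pos, third_pos + 1,
                          new_base, rule="tag_swap",
                          note=f"{gene.id} TAG->TAA"))
        report["edited"] += 1
    return EditLog(edits), report


def _stop_swap_conflict(genome: Genome, gene: Feature, pos: int) -> str | None:
    for other in genome.genes():
        if other.id == gene.id or other.attributes.get("invalid"):
            continue
        positions = _spliced_genomic_positions(genome, other.id)
        if pos not in set(positions):
            continue
        idx = positions.index(pos)
        codon_idx = idx // 3
        cds = spliced_cds(genome, other.id)
        codon = cds[codon_idx * 3:codon_idx * 3 + 3]
        base = "A" if other.strand == gene.strand else "T"
        offset = idx % 3
        new_codon = codon[:offset] + base + codon[offset + 1:]
        if CODON_TABLE[new_codon] != CODON_TABLE[codon]:
            return (f"stop swap at {pos} is non-synonymous in overlapping "
                    f"gene {other.id} ({codon}->{new_codon})")
    return None


def naive_tag_scan(genome: Genome) -> list[str]:
    """Intron-NAIVE scan: reads the last 3 genomic bases of the terminal CDS
    block. Provided as the regression counterpart of the intron-aware scan —
    it misses TAG stops read through an intron boundary.
    """
    hits = []
    for gene in genome.genes():
        blocks = genome.cds_blocks(gene.id)
        if not blocks:
            continue
        if gene.strand == "+":
            window = genome.sequence[blocks[-1].end - 3:blocks[-1].end]
        else:
            window = revcomp(genome.sequence[blocks[0].start:blocks[0].start + 3])
        if window == "TAG":
            hits.append(gene.id)
    return hits


# ---------------------------------------------------------------------------
# constrained synonymous recoding
# ---------------------------------------------------------------------------

def _codon_slots(fragment: str, frame_offset: int):
    """Indices of complete codons within the fragment given the frame."""
    # frame_offset = index within its codon of fragment[0]
    lead = (3 - frame_offset % 3) % 3
    slots = []
    i = lead
    while i + 3 <= len(fragment):
        slots.append(i)
        i += 3
    return slots


def _contains_motif(seq: str, motif: str) -> bool:
    return motif in seq or revcomp(motif) in seq


def synonymous_recode(fragment: str, frame_offset: int, mode: str,
                      params: dict | None = None) -> RecodingResult:
    """Rewrite a coding fragment without changing its protein.

    ``frame_offset`` is the codon-internal index (0..2) of the fragment's
    first base; partial codons at the edges are never touched.

    Modes
    -----
    remove_motif : eliminate every occurrence of ``params['motif']`` on both
        strands by minimal synonymous codon changes; fails naming the
        blocking codon when no synonymous escape exists.
    introduce_motif : place ``params['motif']`` at ``params['offset']`` via
        synonymous changes only.
    maximize_mismatch : per-codon exhaustive search for the synonymous codon
        maximizing Hamming distance to the original; ties broken by the
        alphabetically smallest codon.
    """
    params = params or {}
    fragment = fragment.upper()
    slots = _codon_slots(fragment, frame_offset)

    if mode == "maximize_mismatch":
        return _maximize_mismatch(fragment, slots)
    if mode == "remove_motif":
        return _remove_motif(fragment, slots, params["motif"].upper())
    if mode == "introduce_motif":
        return _introduce_motif(fragment, slots, params["motif"].upper(),
                                params["offset"])
    raise RecodingError(f"unknown mode {mode!r}")


def _maximize_mismatch(fragment: str, slots: list[int]) -> RecodingResult:
    out = list(fragment)
    subs = []
    total = 0
    for k, i in enumerate(slots):
        codon = fragment[i:i + 3]
        aa = CODON_TABLE[codon]
        best = max(
            SYNONYMS[aa],
            key=lambda c: (sum(a != b for a, b in zip(c, codon)),
                           [-ord(x) for x in c]),
        )
        dist = sum(a != b for a, b in zip(best, codon))
        if dist:
            out[i:i + 3] = best
            subs.append((k, codon, best))
            total += dist
    return RecodingResult(fragment, "".join(out), subs, float(total))


def _remove_motif(fragment: str, slots: list[int], motif: str) -> RecodingResult:
    current = fragment
    subs: list[tuple[int, str, str]] = []
    guard = 0
    while _contains_motif(current, motif):
        guard += 1
        if guard > len(fragment):
            raise RecodingError("motif removal did not converge")
        occ = _first_occurrence(current, motif)
        changed = False
        overlapping = [
            (k, i) for k, i in enumerate(slots)
            if i < occ[1] and occ[0] < i + 3
        ]
        for k, i in overlapping:
            codon = current[i:i + 3]
            for cand in SYNONYMS[CODON_TABLE[codon]]:
                if cand == codon:
                    continue
                trial = current[:i] + cand + current[i + 3:]
                window_lo = max(0, occ[0] - len(motif))
                if _contains_motif(trial[window_lo:occ[1] + len(motif)], motif):
                    continue
                if _count_motif(trial, motif) >= _count_motif(current, motif):
                    continue
                current = trial
                subs.append((k, codon, cand))
                changed = True
                break
            if changed:
                break
        if not changed:
            blockers = [current[i:i + 3] for _, i in overlapping] or ["<none in frame>"]
            raise RecodingError(
                f"cannot remove motif {motif} at {occ[0]}: no synonymous "
                f"escape (blocking codons: {', '.join(blockers)})")
    n = sum(a != b for a, b in zip(fragment, current))
    return RecodingResult(fragment, current, subs, float(n))


def _introduce_motif(fragment: str, slots: list[int], motif: str,
                     offset: int) -> RecodingResult:
    if offset < 0 or offset + len(motif) > len(fragment):
        raise RecodingError("motif does not fit at requested offset")
    target = fragment[:offset] + motif + fragment[offset + len(motif):]
    out = list(fragment)
    subs = []
    slot_set = set(slots)
    for pos in range(offset, offset + len(motif)):
        if fragment[pos] == target[pos]:
            continue
        i = max((s for s in slots if s <= pos), default=None)
        if i is None or pos >= i + 3:
            raise RecodingError(
                f"position {pos} lies outside a complete codon")
    for i in slots:
        want = target[i:i + 3]
        codon = fragment[i:i + 3]
        if want == codon:
            continue
        if not (i < offset + len(motif) and offset < i + 3):
            continue
        # codon must become compatible with the motif bases while synonymous
        fixed = {
            j: motif[i + j - offset]
            for j in range(3)
            if offset <= i + j < offset + len(motif)
        }
        chosen = None
        for cand in SYNONYMS[CODON_TABLE[codon]]:
            if all(cand[j] == b for j, b in fixed.items()):
                chosen = cand
                break
        if chosen is None:
            raise RecodingError(
                f"infeasible: codon {codon} (aa {CODON_TABLE[codon]}) cannot "
                f"carry motif bases {fixed}")
        if chosen != codon:
            out[i:i + 3] = chosen
            subs.append((slots.index(i), codon, chosen))
    result = "".join(out)
    if result[offset:offset + len(motif)] != motif:
        raise RecodingError("motif placement failed (edge bases not in frame)")
    n = sum(a != b for a, b in zip(fragment, result))
    return RecodingResult(fragment, result, subs, float(n))


def _first_occurrence(seq: str, motif: str) -> tuple[int, int]:
    a = seq.find(motif)
    rc = revcomp(motif)
    b = seq.find(rc) if rc != motif else -1
    starts = [x for x in (a, b) if x >= 0]
    s = min(starts)
    return s, s + len(motif)


def _count_motif(seq: str, motif: str) -> int:
    rc = revcomp(motif)
    n = _count_overlapping(seq, motif)
    if rc != motif:
        n += _count_overlapping(seq, rc)
    return n


def _count_overlapping(seq: str, sub: str) -> int:
    n = start = 0
    while True:
        i = seq.find(sub, start)
        if i < 0:
            return n
        n += 1
        start = i + 1


def brute_force_max_mismatch(fragment: str) -> int:
    """Exhaustive oracle: maximum Hamming distance over all fully synonymous
    codon combinations of an in-frame fragment. Exponential; test-scale only.
    """
    if len(fragment) % 3:
        raise RecodingError("fragment not in frame")
    codons = [fragment[i:i + 3] for i in range(0, len(fragment), 3)]
    choices = [SYNONYMS[CODON_TABLE[c]] for c in codons]
    best = 0
    for combo in product(*choices):
        d = sum(a != b
                for cod, orig in zip(combo, codons)
                for a, b in zip(cod, orig))
        best = max(best, d)
    return best
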