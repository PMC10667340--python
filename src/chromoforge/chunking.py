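"""Synthesis partitioning: chunks, junction overhangs, megachunks, bill.

The designed chromosome is tiled into synthesis chunks of 4.8-9.8 kb whose
boundaries fall at intergenic positions (or at recognition sites that
cannot be recoded away). Each junction is cut by a type-IIS-like enzyme
leaving a programmable non-palindromic sticky end, so neighboring chunks
ligate uniquely. Chunks are grouped into megachunks -- the in vivo
integration unit -- of 2 chunks for the first (A) and 5 thereafter, each
megachunk ending in an auxotrophic marker that alternates LEU2/URA3 so
every integration round can select for the new marker and against the old
one (SwAP-In).
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from itertools import product

from .annotation_io import Genome
from .recoding import CODON_TABLE, SYNONYMS, revcomp


class ChunkingError(RuntimeError):
    pass


@dataclass(frozen=True)
class JunctionSpec:
    """Restriction junction: enzyme, recognition pattern (N = any base),
    and the programmable overhang it leaves."""
    enzyme: str = "SfiI"
    recognition: str = "GGCCNNNNNGGCC"
    overhang: str = ""
    overhang_len: int = 3

    def __post_init__(self):
        if self.overhang:
            if self.overhang == revcomp(self.overhang):
                raise ChunkingError(
                    f"overhang {self.overhang} is its own reverse complement")


@dataclass
class ChunkParams:
    chunk_size_min: int = 4800
    chunk_size_max: int = 9800
    junction: JunctionSpec = field(default_factory=JunctionSpec)
    overhang_len: int = 3
    adapter_len_bp: int = 20       # synthesis adapter per chunk end
    marker_len_bp: int = 2000      # auxotrophic marker cassette placeholder
    homology_overlap_bp: int = 500  # megachunk 5' overlap for SwAP-In
    first_megachunk_size: int = 2
    megachunk_size: int = 5
    markers: tuple[str, str] = ("LEU2", "URA3")


@dataclass
class Chunk:
    label: str
    start: int
    end: int
    left_junction: JunctionSpec | None = None
    right_junction: JunctionSpec | None = None
    internal_recode_edits: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Megachunk:
    letter: str
    chunks: list[Chunk]
    marker: str
    homology_overlap_bp: int = 500


@dataclass
class SynthesisBill:
    per_chunk: list[tuple[str, int, int]]       # label, body, synthesized
    per_megachunk: list[tuple[str, str, int, int]]  # letter, marker, marker_len, overlap
    synthesized_total: int = 0
    chromosome_length: int = 0


# ---------------------------------------------------------------------------
# recognition-site handling
# ---------------------------------------------------------------------------

def _pattern_regexes(pattern: str):
    pat = pattern.upper().replace("N", "[ACGT]")
    fwd = re.compile(f"(?=({pat}))")
    rc = revcomp(pattern.upper())
    pats = {pattern.upper()}
    if rc not in pats:
        rcpat = rc.replace("N", "[ACGT]")
        return [fwd, re.compile(f"(?=({rcpat}))")]
    return [fwd]


def find_recognition_sites(seq: str, pattern: str) -> list[int]:
    """Start positions of the recognition pattern on either strand."""
    hits = set()
    for rx in _pattern_regexes(pattern):
        hits.update(m.start() for m in rx.finditer(seq))
    return sorted(hits)


def recode_internal_sites(genome: Genome, params: ChunkParams
                          ) -> tuple[list[tuple[int, str]], list[str]]:
    """Destroy recognition-site occurrences lying in CDS by synonymous
    codon changes. Returns ([(position, new_base)], warnings); occurrences
    outside CDS (not recodable) are reported in warnings and must later be
    placed at a junction."""
    pattern = params.junction.recognition
    edits: list[tuple[int, str]] = []
    warnings: list[str] = []
    seq = genome.sequence
    for site in find_recognition_sites(seq, pattern):
        span = (site, site + len(pattern))
        hit = _recode_site(genome, seq, span, pattern)
        if hit is None:
            warnings.append(
                f"recognition site at {site} lies outside any CDS frame and "
                f"cannot be recoded; it must coincide with a junction")
            continue
        for pos, base in hit:
            seq = seq[:pos] + base + seq[pos + 1:]
            edits.append((pos, base))
    return edits, warnings


def _recode_site(genome: Genome, seq: str, span, pattern):
    s, e = span
    for gene in genome.genes():
        if gene.attributes.get("invalid"):
            continue
        for block in genome.cds_blocks(gene.id):
            if not (block.start < e and s < block.end):
                continue
            frame_positions = _block_codon_starts(genome, gene, block)
            for cs in frame_positions:
                if cs + 3 <= s or cs >= e:
                    continue
                codon_genomic = seq[cs:cs + 3]
                coding = (codon_genomic if gene.strand == "+"
                          else revcomp(codon_genomic))
                aa = CODON_TABLE.get(coding)
                if aa is None:
                    continue
                for cand in SYNONYMS[aa]:
                    if cand == coding:
                        continue
                    new_genomic = cand if gene.strand == "+" else revcomp(cand)
                    trial = seq[:cs] + new_genomic + seq[cs + 3:]
                    lo = max(0, s - len(pattern))
                    window = trial[lo:e + len(pattern)]
                    if find_recognition_sites(window, pattern):
                        continue
                    return [(cs + i, new_genomic[i]) for i in range(3)
                            if new_genomic[i] != codon_genomic[i]]
    return None


def _block_codon_starts(genome: Genome, gene, block) -> list[int]:
    blocks = genome.cds_blocks(gene.id)
    ordered = blocks if gene.strand == "+" else list(reversed(blocks))
    acc = 0
    frame = 0
    for b in ordered:
        if b.id == block.id:
            frame = acc % 3
            break
        acc += b.length
    if gene.strand == "+":
        shift = (3 - frame) % 3
        first = block.start + shift
        return list(range(first, block.end - 2, 3))
    shift = (3 - frame) % 3
    top = block.end - shift
    return [p for p in range(top - 3, block.start - 1, -3)]


# ---------------------------------------------------------------------------
# partitioning
# ---------------------------------------------------------------------------

def _candidate_positions(genome: Genome) -> list[int]:
    """Feature-free positions usable as junction cuts."""
    n = len(genome)
    occupied = [(f.start, f.end) for f in genome.features
                if f.kind != "pcrtag"]
    occupied.sort()
    out = []
    cursor = 0
    for s, e in occupied:
        if s > cursor:
            out.extend(range(cursor, s))
        cursor = max(cursor, e)
    if cursor < n:
        out.extend(range(cursor, n))
    return out


def partition_chunks(genome: Genome, params: ChunkParams | None = None
                     ) -> tuple[list[Chunk], Genome]:
    """Tile the designed chromosome into chunks within size bounds.

    Internal recognition sites are first removed by synonymous recoding
    where a CDS frame allows; a non-recodable site must coincide with a
    cut. Partitioning is greedy left-to-right, aiming at the midpoint of
    the size bounds with ties to the leftmost feasible candidate.
    Returns (chunks, genome-after-recoding); chunk bodies tile the returned
    genome's sequence exactly.
    """
    params = params or ChunkParams()
    site_edits, warnings = recode_internal_sites(genome, params)
    if site_edits:
        seq = genome.sequence
        for pos, base in site_edits:
            seq = seq[:pos] + base + seq[pos + 1:]
        genome = Genome(id=genome.id, sequence=seq, topology=genome.topology,
                        features=list(genome.features))

    n = len(genome)
    lo, hi = params.chunk_size_min, params.chunk_size_max
    if n <= hi:
        chunks = [Chunk("chunk_001", 0, n,
                        params.junction, params.junction,
                        list(site_edits))]
        return chunks, genome

    candidates = _candidate_positions(genome)
    pattern = params.junction.recognition
    forced = [s + len(pattern) // 2
              for s in find_recognition_sites(genome.sequence, pattern)]
    target = (lo + hi) // 2

    cuts = [0]
    start = 0
    while n - start > hi:
        window = [c for c in candidates if start + lo <= c <= start + hi]
        nxt_forced = [f for f in forced if start < f <= start + hi]
        if nxt_forced:
            f = nxt_forced[0]
            if f < start + lo:
                raise ChunkingError(
                    f"unremovable recognition site at {f} falls inside "
                    f"chunk starting at {start} (below minimum size)")
            window = [f]
        # remainder after the cut must itself be partitionable
        window = [c for c in window if n - c == 0 or n - c >= lo]
        if not window:
            raise ChunkingError(
                f"no feasible junction in [{start + lo}, {start + hi}] "
                f"(interval {start}..{min(n, start + hi)})")
        cut = min(window, key=lambda c: (abs(c - (start + target)), c))
        cuts.append(cut)
        start = cut
    cuts.append(n)

    chunks = []
    for i, (s, e) in enumerate(zip(cuts[:-1], cuts[1:]), start=1):
        if not (lo <= e - s <= hi):
            raise ChunkingError(f"chunk [{s}, {e}) violates size bounds")
        body = genome.sequence[s:e]
        interior = [p for p in find_recognition_sites(body, pattern)
                    if 0 < p and p + len(pattern) < len(body)]
        if interior:
            raise ChunkingError(
                f"recognition site persists inside chunk [{s}, {e}) at "
                f"body offset {interior[0]}")
        chunks.append(Chunk(f"chunk_{i:03d}", s, e,
                            params.junction, params.junction,
                            [ed for ed in site_edits if s <= ed[0] < e]))
    return chunks, genome


# ---------------------------------------------------------------------------
# overhangs, megachunks, bill
# ---------------------------------------------------------------------------

def _overhang_candidates(L: int) -> list[str]:
    out = []
    for combo in product("ACGT", repeat=L):
        s = "".join(combo)
        if s != revcomp(s):  # no odd-length self-complement exists
            out.append(s)
    return out


def _group_sizes(n_chunks: int, params: ChunkParams) -> list[int]:
    sizes = []
    remaining = n_chunks
    first = min(params.first_megachunk_size, remaining)
    sizes.append(first)
    remaining -= first
    while remaining > 0:
        take = min(params.megachunk_size, remaining)
        sizes.append(take)
        remaining -= take
    return sizes


def assign_overhangs(chunks: list[Chunk], params: ChunkParams | None = None
                     ) -> list[str]:
    """Deterministically assign a non-palindromic overhang to each junction
    (one per chunk boundary, n_chunks - 1 internal junctions plus the two
    terminal adapters): lexicographic first candidate not already used
    within the same megachunk or across its boundary."""
    params = params or ChunkParams()
    cands = _overhang_candidates(params.overhang_len)
    n_junctions = len(chunks) + 1
    sizes = _group_sizes(len(chunks), params)
    group_of_chunk = []
    for g, size in enumerate(sizes):
        group_of_chunk.extend([g] * size)
    # junction j sits left of chunk j (j = 0..n); its constraint group(s)
    junction_groups = []
    for j in range(n_junctions):
        gs = set()
        if j > 0:
            gs.add(group_of_chunk[j - 1])
        if j < len(chunks):
            gs.add(group_of_chunk[j])
        junction_groups.append(gs)
    used_by_group: dict[int, set[str]] = {}
    out = []
    for j in range(n_junctions):
        gs = junction_groups[j]
        taken = set().union(*(used_by_group.get(g, set()) for g in gs))
        pick = next((c for c in cands if c not in taken), None)
        if pick is None:
            raise ChunkingError(
                f"overhang alphabet exhausted at junction {j} "
                f"(4^{params.overhang_len} candidates)")
        out.append(pick)
        for g in gs:
            used_by_group.setdefault(g, set()).add(pick)
    for c, left, right in zip(chunks, out[:-1], out[1:]):
        c.left_junction = JunctionSpec(params.junction.enzyme,
                                       params.junction.recognition,
                                       left, params.overhang_len)
        c.right_junction = JunctionSpec(params.junction.enzyme,
                                        params.junction.recognition,
                                        right, params.overhang_len)
    return out


def group_megachunks(chunks: list[Chunk], params: ChunkParams | None = None
                     ) -> list[Megachunk]:
    """Group chunks 2-then-5 into lettered megachunks with alternating
    LEU2/URA3 markers; chunks are relabeled letter+ordinal (A1, A2, B1...)."""
    params = params or ChunkParams()
    sizes = _group_sizes(len(chunks), params)
    letters = list(string.ascii_uppercase)
    letters += [a + b for a in string.ascii_uppercase
                for b in string.ascii_uppercase]
    out = []
    idx = 0
    for g, size in enumerate(sizes):
        members = chunks[idx:idx + size]
        idx += size
        letter = letters[g]
        for k, c in enumerate(members, start=1):
            c.label = f"{letter}{k}"
        out.append(Megachunk(letter, members,
                             params.markers[g % len(params.markers)],
                             params.homology_overlap_bp))
    return out


def synthesis_bill(chunks: list[Chunk], megachunks: list[Megachunk],
                   params: ChunkParams | None = None) -> SynthesisBill:
    """Account for every synthesized base: chunk bodies plus junction
    adapters, megachunk marker cassettes and SwAP-In homology overlaps."""
    params = params or ChunkParams()
    per_chunk = []
    total = 0
    for c in chunks:
        synth = c.length + 2 * params.adapter_len_bp
        per_chunk.append((c.label, c.length, synth))
        total += synth
    per_mega = []
    for m in megachunks:
        overlap = m.homology_overlap_bp
        per_mega.append((m.letter, m.marker, params.marker_len_bp, overlap))
        total += params.marker_len_bp + overlap
    chrom_len = sum(c.length for c in chunks)
    return SynthesisBill(per_chunk, per_mega, total, chrom_len)


def write_chunk_tables(chunks, megachunks, bill, out_dir) -> None:
    from pathlib import Path
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "chunks.tsv", "w") as fh:
        fh.write("label\tstart\tend\tlength\tleft_overhang\tright_overhang\n")
        for c in chunks:
            fh.write(f"{c.label}\t{c.start}\t{c.end}\t{c.length}\t"
                     f"{c.left_junction.overhang if c.left_junction else ''}\t"
                     f"{c.right_junction.overhang if c.right_junction else ''}\n")
    with open(out_dir / "megachunks.tsv", "w") as fh:
        fh.write("letter\tmarker\tchunks\toverlap_bp\n")
        for m in megachunks:
            fh.write(f"{m.letter}\t{m.marker}\t"
                     f"{','.join(c.label for c in m.chunks)}\t"
                     f"{m.homology_overlap_bp}\n")
    with open(out_dir / "synthesis_bill.tsv", "w") as fh:
        fh.write("label\tbody_bp\tsynthesized_bp\n")
        for label, body, synth in bill.per_chunk:
            fh.write(f"{label}\t{body}\t{synth}\n")
        fh.write(f"#total_synthesized\t{bill.synthesized_total}\t\n")
        fh.write(f"#chromosome_length\t{bill.chromosome_length}\t\n")
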