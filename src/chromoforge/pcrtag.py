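"""PCRTag watermark design and in-silico PCRTag genotyping.

A PCRTag is a short synonymous recoding of a CDS window that creates a
primer site present only in the synthetic chromosome; the untouched native
window is the paired wild-type primer site. Screening a strain with both
primer sets distinguishes synthetic from wild-type DNA locus by locus
(SYN / WT / BOTH / NONE calls) without sequencing.

In-silico PCR here is exact-match by default: tag primers are designed for
presence/absence discrimination with many mismatches, so a perfect-match
model is the appropriate desk-scale analog of the screening PCR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_io import Edit, EditLog, Genome
from .recoding import (
    CODON_TABLE, RecodingError, revcomp, synonymous_recode, translate,
)


class PCRTagError(ValueError):
    pass


@dataclass
class PCRTagParams:
    primer_len_min: int = 18
    primer_len_max: int = 33
    tm_min: float = 54.0
    tm_max: float = 66.0
    min_mismatches: int = 8
    require_3prime_mismatch_within: int = 6
    amplicon_min: int = 200
    amplicon_max: int = 800
    tags_per_gene_max: int = 2
    end_margin_bp: int = 50      # keep windows away from CDS start/stop
    mismatch_tolerance: int = 0  # exact-match in-silico PCR

    def __post_init__(self):
        for lo, hi in ((self.primer_len_min, self.primer_len_max),
                       (self.tm_min, self.tm_max),
                       (self.amplicon_min, self.amplicon_max)):
            if lo > hi:
                raise PCRTagError("min exceeds max in PCRTagParams")


@dataclass
class PCRTagPair:
    gene_id: str
    tag_index: int
    wt_fwd: str
    wt_rev: str
    syn_fwd: str
    syn_rev: str
    amplicon_start: int   # designed coordinates
    amplicon_end: int
    tm_fwd_wt: float = 0.0
    tm_rev_wt: float = 0.0
    tm_fwd_syn: float = 0.0
    tm_rev_syn: float = 0.0
    mismatches_fwd: int = 0
    mismatches_rev: int = 0

    @property
    def tag_id(self) -> str:
        return f"{self.gene_id}.{self.tag_index}"


@dataclass
class GenotypeCall:
    tag_id: str
    syn_amplified: bool
    wt_amplified: bool

    @property
    def status(self) -> str:
        if self.syn_amplified and self.wt_amplified:
            return "BOTH"
        if self.syn_amplified:
            return "SYN"
        if self.wt_amplified:
            return "WT"
        return "NONE"


def tm_wallace(primer: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C), in deg C."""
    primer = primer.upper()
    if not primer or set(primer) - set("ACGT"):
        raise PCRTagError(f"primer must be non-empty ACGT, got {primer!r}")
    at = primer.count("A") + primer.count("T")
    gc = primer.count("G") + primer.count("C")
    return 2.0 * at + 4.0 * gc


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _window_in_frame(genome: Genome, gene, block, start: int, length: int,
                     block_frame: int):
    """Return (wt, syn, n_mm, mm_positions) for a codon-aligned window, or
    None when constraints cannot be met. Coordinates are genomic; recoding
    is performed in the gene's coding orientation."""
    wt = genome.sequence[start:start + length]
    if gene.strand == "+":
        coding = wt
    else:
        coding = revcomp(wt)
    try:
        res = synonymous_recode(coding, 0, "maximize_mismatch")
    except (RecodingError, KeyError):
        return None
    syn_coding = res.recoded_fragment
    syn = syn_coding if gene.strand == "+" else revcomp(syn_coding)
    mm = [i for i, (a, b) in enumerate(zip(wt, syn)) if a != b]
    return wt, syn, len(mm), mm


def design_pcrtags(genome: Genome, params: PCRTagParams | None = None,
                   existing: EditLog | None = None
                   ) -> tuple[list[PCRTagPair], EditLog, dict]:
    """Design synonymous watermark primer pairs for every taggable gene.

    Genes are processed longest-CDS-first; within a gene, codon-aligned
    windows inside a single CDS block (>= ``end_margin_bp`` from the block
    edges) are recoded by exhaustive per-codon mismatch maximization and
    paired into amplicons of 200-800 bp. Genes with no feasible window pair
    are reported untagged. Returns (pairs, recoding EditLog in original
    coordinates, report).
    """
    params = params or PCRTagParams()
    existing = existing or EditLog([])
    pairs: list[PCRTagPair] = []
    edits: list[Edit] = []
    report = {"untagged": [], "tagged": []}
    taken: list[tuple[int, int]] = [
        (e.orig_start, e.orig_end) if e.kind != "insertion"
        else (e.orig_start, e.orig_start) for e in existing]

    def free(s: int, e: int) -> bool:
        return not any(s < te and ts < e for ts, te in taken if ts != te) and \
            not any(s < tp < e for tp, te2 in taken if tp == te2)

    genes = sorted(
        (g for g in genome.genes()
         if not g.attributes.get("invalid") and genome.cds_blocks(g.id)),
        key=lambda g: -sum(b.length for b in genome.cds_blocks(g.id)))

    win_lens = [l for l in (24, 18, 21, 27, 30, 33)
                if params.primer_len_min <= l <= params.primer_len_max
                and l % 3 == 0]
    if not win_lens:
        raise PCRTagError("no codon-aligned primer length within bounds")

    for gene in genes:
        gene_pairs = _design_gene_tags(genome, gene, params, win_lens, free)
        if not gene_pairs:
            report["untagged"].append(gene.id)
            continue
        report["tagged"].append(gene.id)
        for tag_index, (fwd_w, rev_w) in enumerate(gene_pairs, start=1):
            (fs, f_wt, f_syn, f_mm), (rs, r_wt, r_syn, r_mm) = fwd_w, rev_w
            pair = PCRTagPair(
                gene_id=gene.id, tag_index=tag_index,
                wt_fwd=f_wt, syn_fwd=f_syn,
                wt_rev=revcomp(r_wt), syn_rev=revcomp(r_syn),
                amplicon_start=fs, amplicon_end=rs + len(r_wt),
                tm_fwd_wt=tm_wallace(f_wt), tm_rev_wt=tm_wallace(r_wt),
                tm_fwd_syn=tm_wallace(f_syn), tm_rev_syn=tm_wallace(r_syn),
                mismatches_fwd=f_mm, mismatches_rev=r_mm)
            pairs.append(pair)
            for s, wt, syn in ((fs, f_wt, f_syn), (rs, r_wt, r_syn)):
                edits.append(Edit("substitution", s, s + len(wt), syn,
                                  rule="pcrtag",
                                  note=f"{pair.tag_id}"))
                taken.append((s, s + len(wt)))
    return pairs, EditLog(edits), report


def _design_gene_tags(genome: Genome, gene, params: PCRTagParams,
                      win_lens, free):
    """Greedy per-gene window pairing; returns [(fwd_window, rev_window)]
    where each window is (start, wt, syn, n_mismatch)."""
    out = []
    blocks = genome.cds_blocks(gene.id)
    # frame of each block start within the coding sequence
    frames = {}
    acc = 0
    ordered = blocks if gene.strand == "+" else list(reversed(blocks))
    for b in ordered:
        frames[b.id] = acc % 3
        acc += b.length
    for block in blocks:
        lo = block.start + params.end_margin_bp
        hi = block.end - params.end_margin_bp
        cursor = lo
        while len(out) < params.tags_per_gene_max:
            pair = _find_pair(genome, gene, block, frames[block.id],
                              cursor, hi, params, win_lens, free)
            if pair is None:
                break
            out.append(pair)
            cursor = pair[1][0] + len(pair[1][1])  # after the rev window
        if len(out) >= params.tags_per_gene_max:
            break
    return out


def _codon_align(pos: int, block_start: int, block_frame: int,
                 strand: str, block_end: int) -> int:
    """Smallest codon-aligned genomic position >= pos within the block."""
    if strand == "+":
        # coding position of genomic p is (p - block_start + frame_shift)
        shift = (3 - block_frame) % 3
        base = block_start + shift
        if pos <= base:
            return base
        return base + ((pos - base + 2) // 3) * 3
    # minus strand: codons run right-to-left; genomic position p starts a
    # codon-aligned triple [p, p+3) iff (block_end - (p + 3) + frame... )
    # the last coding base is at block_start when frame of block is f.
    # codon boundaries (genomic) satisfy (block_end - p) % 3 == frame_adj
    shift = (3 - block_frame) % 3
    top = block_end - shift
    # want largest t <= ... positions p with (top - p) % 3 == 0
    r = (top - pos) % 3
    return pos + r


def _window_ok(genome: Genome, gene, start: int, length: int,
               params: PCRTagParams, free, three_prime: str):
    if not free(start, start + length):
        return None
    got = _window_in_frame(genome, gene, None, start, length, 0)
    if got is None:
        return None
    wt, syn, n_mm, mm = got
    if n_mm < params.min_mismatches:
        return None
    w = params.require_3prime_mismatch_within
    if three_prime == "right":
        if not any(p >= length - w for p in mm):
            return None
    else:
        if not any(p < w for p in mm):
            return None
    for primer in (wt, syn):
        if not params.tm_min <= tm_wallace(primer) <= params.tm_max:
            return None
    return start, wt, syn, n_mm


def _find_pair(genome: Genome, gene, block, block_frame, lo, hi,
               params: PCRTagParams, win_lens, free):
    strand = gene.strand
    start = _codon_align(lo, block.start, block_frame, strand, block.end)
    while start + params.primer_len_min <= hi:
        fwd = None
        for L in win_lens:
            if start + L > hi:
                continue
            fwd = _window_ok(genome, gene, start, L, params, free, "right")
            if fwd:
                break
        if fwd:
            fs, f_wt = fwd[0], fwd[1]
            r_lo = max(fs + params.amplicon_min - params.primer_len_max,
                       fs + len(f_wt))
            r_start = _codon_align(r_lo, block.start, block_frame,
                                   strand, block.end)
            while r_start + params.primer_len_min <= hi:
                rev = None
                for L in win_lens:
                    amp = r_start + L - fs
                    if r_start + L > hi or amp > params.amplicon_max:
                        continue
                    if amp < params.amplicon_min:
                        continue
                    rev = _window_ok(genome, gene, r_start, L, params,
                                     free, "left")
                    if rev:
                        break
                if rev:
                    return fwd, rev
                r_start += 3
                if r_start + params.primer_len_min - fs > params.amplicon_max:
                    break
        start += 3
    return None


# ---------------------------------------------------------------------------
# in-silico PCR and screening
# ---------------------------------------------------------------------------

def _find_all(template: str, probe: str) -> list[int]:
    out, i = [], template.find(probe)
    while i >= 0:
        out.append(i)
        i = template.find(probe, i + 1)
    return out


def insilico_pcr(template: Genome | str, fwd: str, rev: str,
                 max_product: int = 5000) -> list[tuple[int, int, int]]:
    """Exact-match PCR: amplicons (start, end, length) for every convergent
    placement of fwd on the + strand and rev on the - strand, product
    length <= max_product, sorted by coordinate."""
    seq = template.sequence if isinstance(template, Genome) else template
    fwd, rev = fwd.upper(), rev.upper()
    if len(fwd) < 12 or len(rev) < 12:
        raise PCRTagError("primers must be >= 12 nt")
    fwd_sites = _find_all(seq, fwd)
    rev_sites = _find_all(seq, revcomp(rev))  # rev binds the - strand here
    out = []
    for f in fwd_sites:
        for r in rev_sites:
            end = r + len(rev)
            length = end - f
            if length >= max(len(fwd), len(rev)) and length <= max_product:
                out.append((f, end, length))
    return sorted(out)


def pcrtag_screen(template: Genome | str, pairs: list[PCRTagPair],
                  max_product: int = 5000) -> list[GenotypeCall]:
    """Genotype a template with every tag pair; SYN/WT/BOTH/NONE per tag,
    ordered by amplicon coordinate."""
    calls = []
    for p in sorted(pairs, key=lambda q: q.amplicon_start):
        syn = bool(insilico_pcr(template, p.syn_fwd, p.syn_rev, max_product))
        wt = bool(insilico_pcr(template, p.wt_fwd, p.wt_rev, max_product))
        calls.append(GenotypeCall(p.tag_id, syn, wt))
    return calls


def write_tag_table(pairs: list[PCRTagPair], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttag_index\twt_fwd\twt_rev\tsyn_fwd\tsyn_rev\t"
                 "amplicon_start\tamplicon_end\n")
        for p in pairs:
            fh.write(f"{p.gene_id}\t{p.tag_index}\t{p.wt_fwd}\t{p.wt_rev}\t"
                     f"{p.syn_fwd}\t{p.syn_rev}\t{p.amplicon_start}\t"
                     f"{p.amplicon_end}\n")


def read_tag_table(path) -> list[PCRTagPair]:
    import csv
    out = []
    with open(path) as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(PCRTagPair(
                gene_id=row["gene_id"], tag_index=int(row["tag_index"]),
                wt_fwd=row["wt_fwd"], wt_rev=row["wt_rev"],
                syn_fwd=row["syn_fwd"], syn_rev=row["syn_rev"],
                amplicon_start=int(row["amplicon_start"]),
                amplicon_end=int(row["amplicon_end"])))
    return out


def write_genotype_matrix(calls: list[GenotypeCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("tag_id\tsyn\twt\tstatus\n")
        for c in calls:
            fh.write(f"{c.tag_id}\t{int(c.syn_amplified)}\t"
                     f"{int(c.wt_amplified)}\t{c.status}\n")
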