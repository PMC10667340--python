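"""Genome/annotation I/O, edit logs, and coordinate liftover.

Internal coordinates are 0-based half-open on the forward strand; GFF3 I/O
converts to/from the 1-based inclusive convention. Minus-strand features are
stored in forward-strand coordinates and reverse-complemented on extraction.
Gene essentiality and mitochondrial-function flags come from a sidecar
tab-separated table, keeping the toolkit independent of any particular
annotation release.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGT")

FEATURE_KINDS = {
    "gene", "CDS_block", "intron", "tRNA", "LTR", "subtelomeric_repeat",
    "centromere", "ARS", "telomere", "marker", "loxPsym", "pcrtag", "other",
}

#: sentinel returned by LiftoverMap for positions removed by the design
DELETED = "deleted"
#: sentinel for designed positions with no original counterpart
NOVEL = "novel"

_GFF_TYPE_MAP = {"CDS": "CDS_block"}
_GFF_TYPE_MAP_OUT = {"CDS_block": "CDS"}


class AnnotationError(ValueError):
    """Raised for malformed genomes, features, or edit logs."""


@dataclass
class Feature:
    """A typed genomic interval in forward-strand 0-based half-open coords."""

    id: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise AnnotationError(f"unknown feature kind {self.kind!r}")
        if not (0 <= self.start < self.end):
            raise AnnotationError(
                f"feature {self.id}: bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise AnnotationError(f"feature {self.id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, start: int, end: int) -> bool:
        return self.start < end and start < self.end


@dataclass
class Genome:
    """A chromosome sequence with its typed feature annotation."""

    id: str
    sequence: str
    topology: str = "linear"
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self):
        if not self.sequence:
            raise AnnotationError("empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise AnnotationError(
                f"sequence contains non-ACGT characters {sorted(bad)} "
                "(ambiguity codes are rejected: synthesis designs must be "
                "fully specified)")
        if self.topology not in ("linear", "circular"):
            raise AnnotationError(f"bad topology {self.topology!r}")
        for f in self.features:
            if f.end > len(self.sequence):
                raise AnnotationError(
                    f"feature {f.id} extends past sequence end "
                    f"({f.end} > {len(self.sequence)})")
        self.features.sort(key=lambda f: (f.start, f.end, f.id))

    def __len__(self) -> int:
        return len(self.sequence)

    # -- feature queries -------------------------------------------------
    def features_of_kind(self, kind: str) -> list[Feature]:
        return [f for f in self.features if f.kind == kind]

    def genes(self) -> list[Feature]:
        return self.features_of_kind("gene")

    def feature_by_id(self, fid: str) -> Feature:
        for f in self.features:
            if f.id == fid:
                return f
        raise KeyError(fid)

    def children(self, parent_id: str, kind: str | None = None) -> list[Feature]:
        out = [f for f in self.features
               if f.attributes.get("parent") == parent_id]
        if kind is not None:
            out = [f for f in out if f.kind == kind]
        return out

    def cds_blocks(self, gene_id: str) -> list[Feature]:
        return sorted(self.children(gene_id, "CDS_block"), key=lambda f: f.start)

    def introns(self, gene_id: str) -> list[Feature]:
        return sorted(self.children(gene_id, "intron"), key=lambda f: f.start)

    def extract(self, start: int, end: int, strand: str = "+") -> str:
        s = self.sequence[start:end]
        return str(Seq(s).reverse_complement()) if strand == "-" else s

    def overlapping(self, start: int, end: int,
                    exclude_kinds: tuple[str, ...] = ()) -> list[Feature]:
        return [f for f in self.features
                if f.overlaps(start, end) and f.kind not in exclude_kinds]


@dataclass(frozen=True)
class Edit:
    """One edit in ORIGINAL coordinates.

    ``deletion`` removes [orig_start, orig_end); ``insertion`` has
    orig_start == orig_end and a non-empty replacement; ``substitution``
    replaces the interval with ``replacement`` (length may differ).
    """

    kind: str
    orig_start: int
    orig_end: int
    replacement: str = ""
    rule: str = ""
    note: str = ""

    def __post_init__(self):
        if self.kind not in ("deletion", "insertion", "substitution"):
            raise AnnotationError(f"bad edit kind {self.kind!r}")
        if self.orig_start > self.orig_end or self.orig_start < 0:
            raise AnnotationError(f"bad edit interval "
                                  f"[{self.orig_start}, {self.orig_end})")
        if self.kind == "insertion":
            if self.orig_start != self.orig_end:
                raise AnnotationError("insertion must have zero-length interval")
            if not self.replacement:
                raise AnnotationError("insertion needs a replacement sequence")
        if self.kind == "deletion":
            if self.orig_start == self.orig_end:
                raise AnnotationError("deletion interval is empty")
            if self.replacement:
                raise AnnotationError("deletion carries no replacement")
        if self.kind == "substitution" and self.orig_start == self.orig_end:
            raise AnnotationError("substitution interval is empty")
        if set(self.replacement) - DNA_ALPHABET:
            raise AnnotationError("replacement contains non-ACGT characters")

    @property
    def delta(self) -> int:
        return len(self.replacement) - (self.orig_end - self.orig_start)


@dataclass
class EditLog:
    """Ordered, pairwise non-overlapping edits in original coordinates."""

    edits: list[Edit] = field(default_factory=list)

    def __post_init__(self):
        self.edits = sorted(self.edits,
                            key=lambda e: (e.orig_start, e.orig_end))
        self._check_overlaps()

    def _check_overlaps(self):
        prev_end = -1
        prev_point = None
        for e in self.edits:
            if e.orig_start < prev_end:
                raise AnnotationError(
                    f"overlapping edits at original position {e.orig_start}")
            if e.kind == "insertion":
                if e.orig_start == prev_point:
                    raise AnnotationError(
                        f"two insertions at the same point {e.orig_start}")
                prev_point = e.orig_start
                prev_end = max(prev_end, e.orig_start)
            else:
                # a non-insertion starting exactly at an insertion point is
                # fine (the insertion lands before the interval)
                prev_end = e.orig_end
                prev_point = None

    def __iter__(self):
        return iter(self.edits)

    def __len__(self):
        return len(self.edits)

    def add(self, edit: Edit) -> None:
        self.edits.append(edit)
        self.edits.sort(key=lambda e: (e.orig_start, e.orig_end))
        self._check_overlaps()

    def overlaps_interval(self, start: int, end: int) -> bool:
        """True if any existing edit touches [start, end)."""
        for e in self.edits:
            if e.kind == "insertion":
                if start < e.orig_start < end:
                    return True
            elif e.orig_start < end and start < e.orig_end:
                return True
        return False

    def by_rule(self, rule: str) -> list[Edit]:
        return [e for e in self.edits if e.rule == rule]

    def merged(self, other: "EditLog") -> "EditLog":
        return EditLog(self.edits + list(other.edits))

    def validate_against(self, length: int) -> None:
        for e in self.edits:
            if e.orig_end > length:
                raise AnnotationError(
                    f"edit [{e.orig_start}, {e.orig_end}) out of bounds "
                    f"for length {length}")


def apply_edits(sequence: str, edit_log: EditLog) -> str:
    """Apply an edit log to a sequence, returning the designed sequence."""
    edit_log.validate_against(len(sequence))
    parts = []
    cursor = 0
    for e in edit_log:
        parts.append(sequence[cursor:e.orig_start])
        parts.append(e.replacement)
        cursor = e.orig_end
    parts.append(sequence[cursor:])
    return "".join(parts)


@dataclass(frozen=True)
class _Segment:
    orig_start: int
    orig_end: int
    des_start: int
    des_end: int
    kind: str  # match | replaced | inserted


class LiftoverMap:
    """Monotone piecewise map between original and designed coordinates.

    Positions inside a deletion or a length-changing substitution lift to the
    :data:`DELETED` sentinel; designed positions inside an insertion map back
    to :data:`NOVEL`. Equal-length substitutions keep 1:1 coordinates (the
    sequence differs but the frame is preserved).
    """

    def __init__(self, edit_log: EditLog, original_length: int):
        edit_log.validate_against(original_length)
        segs: list[_Segment] = []
        o = d = 0
        for e in edit_log:
            if e.orig_start > o:
                segs.append(_Segment(o, e.orig_start,
                                     d, d + (e.orig_start - o), "match"))
                d += e.orig_start - o
                o = e.orig_start
            olen = e.orig_end - e.orig_start
            rlen = len(e.replacement)
            if e.kind == "substitution" and olen == rlen:
                segs.append(_Segment(o, o + olen, d, d + rlen, "match_sub"))
            else:
                if olen:
                    segs.append(_Segment(o, o + olen, d, d, "replaced"))
                if rlen:
                    segs.append(_Segment(o + olen, o + olen,
                                         d, d + rlen, "inserted"))
            o += olen
            d += rlen
        if o < original_length:
            segs.append(_Segment(o, original_length,
                                 d, d + (original_length - o), "match"))
            d += original_length - o
        self.segments = segs
        self.original_length = original_length
        self.designed_length = d
        self._ostarts = [s.orig_start for s in segs]
        self._dstarts = [s.des_start for s in segs]

    def to_designed(self, pos: int):
        """Lift an original position; returns an int or ``DELETED``."""
        if not 0 <= pos < self.original_length:
            raise IndexError(pos)
        i = bisect_right(self._ostarts, pos) - 1
        # skip zero-length (insertion) segments sharing the start
        while i >= 0 and self.segments[i].orig_end <= pos:
            i -= 1
        s = self.segments[i]
        if s.kind in ("match", "match_sub"):
            return s.des_start + (pos - s.orig_start)
        return DELETED

    def to_original(self, pos: int):
        """Map a designed position back; returns an int or ``NOVEL``."""
        if not 0 <= pos < self.designed_length:
            raise IndexError(pos)
        i = bisect_right(self._dstarts, pos) - 1
        while i >= 0 and self.segments[i].des_end <= pos:
            i -= 1
        s = self.segments[i]
        if s.kind in ("match", "match_sub"):
            return s.orig_start + (pos - s.des_start)
        return NOVEL

    def lift_interval(self, start: int, end: int) -> tuple[int, int] | None:
        """Lift [start, end) to the smallest designed interval covering the
        surviving part; None if the interval is wholly deleted."""
        des = [self.to_designed(p) for p in (start, end - 1)]
        lo = des[0]
        if lo == DELETED:
            lo = self._next_surviving(start, end)
            if lo is None:
                return None
        hi = des[1]
        if hi == DELETED:
            hi = self._prev_surviving(end - 1, start)
            if hi is None:
                return None
        else:
            pass
        if isinstance(lo, int) and isinstance(hi, int) and lo <= hi:
            return lo, hi + 1
        return None

    def _next_surviving(self, start: int, end: int):
        for s in self.segments:
            if s.kind in ("match", "match_sub") and s.orig_end > start:
                p = max(s.orig_start, start)
                if p < end:
                    return s.des_start + (p - s.orig_start)
                return None
        return None

    def _prev_surviving(self, pos: int, floor: int):
        best = None
        for s in self.segments:
            if s.kind in ("match", "match_sub") and s.orig_start <= pos:
                p = min(s.orig_end - 1, pos)
                if p >= floor:
                    best = s.des_start + (p - s.orig_start)
        return best

    def surviving_original_positions(self):
        """Positions whose base is carried unchanged into the design."""
        for s in self.segments:
            if s.kind == "match":
                yield from range(s.orig_start, s.orig_end)


def build_liftover(edit_log: EditLog, original_length: int) -> LiftoverMap:
    """Build the original<->designed coordinate map implied by an edit log."""
    return LiftoverMap(edit_log, original_length)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _parse_gff_attributes(text: str) -> dict:
    out = {}
    for item in text.strip().split(";"):
        if not item:
            continue
        if "=" not in item:
            raise AnnotationError(f"malformed GFF3 attribute {item!r}")
        k, v = item.split("=", 1)
        out[k.strip()] = v.strip()
    return out


def _format_gff_attributes(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


_BOOL_ATTRS = ("essential", "essential_intron", "mitochondrial_function")


def _coerce_bools(attrs: dict) -> dict:
    out = dict(attrs)
    for k in _BOOL_ATTRS:
        if k in out and isinstance(out[k], str):
            out[k] = out[k].lower() in ("true", "1", "yes")
    return out


def read_genome(fasta_path, gff_path, essentiality_table_path) -> Genome:
    """Load a genome from FASTA + GFF3 + sidecar essentiality table.

    The table must have a header ``gene_id<TAB>essential<TAB>
    mitochondrial_function``. GFF3 ``CDS`` rows become ``CDS_block``
    features. Genes whose spliced CDS length is not a multiple of 3 are
    flagged ``invalid=True`` (load continues with a recorded warning).
    """
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        raise AnnotationError(f"no FASTA records in {fasta_path}")

    flags: dict[str, dict] = {}
    with open(essentiality_table_path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_id", "essential", "mitochondrial_function"}
        if not required <= set(reader.fieldnames or ()):
            raise AnnotationError(
                f"essentiality table needs columns {sorted(required)}")
        for row in reader:
            flags[row["gene_id"]] = {
                "essential": row["essential"].lower() in ("true", "1", "yes"),
                "mitochondrial_function":
                    row["mitochondrial_function"].lower() in ("true", "1", "yes"),
            }

    seqid = None
    features: list[Feature] = []
    with open(gff_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise AnnotationError(f"malformed GFF3 line: {line!r}")
            sid, _src, ftype, start1, end1, _score, strand, _phase, attr = cols
            if sid not in records:
                raise AnnotationError(
                    f"GFF3 seqid {sid!r} not found among FASTA records "
                    f"{sorted(records)}")
            seqid = seqid or sid
            attrs = _coerce_bools(_parse_gff_attributes(attr))
            fid = attrs.pop("ID", None) or attrs.pop("id", None)
            if fid is None:
                raise AnnotationError(f"GFF3 feature without ID: {line!r}")
            if "Parent" in attrs:
                attrs["parent"] = attrs.pop("Parent")
            kind = _GFF_TYPE_MAP.get(ftype, ftype)
            if kind not in FEATURE_KINDS:
                kind = "other"
                attrs.setdefault("source_type", ftype)
            start = int(start1) - 1  # GFF3 is 1-based inclusive
            end = int(end1)
            features.append(Feature(fid, kind, start, end,
                                    strand if strand in "+-" else "+", attrs))

    genome = Genome(id=seqid or next(iter(records)),
                    sequence=records[seqid or next(iter(records))],
                    features=features)

    for gene in genome.genes():
        if gene.id in flags:
            gene.attributes.update(flags[gene.id])
        gene.attributes.setdefault("essential", False)
        gene.attributes.setdefault("mitochondrial_function", False)
        blocks = genome.cds_blocks(gene.id)
        spliced_len = sum(b.length for b in blocks)
        if blocks and spliced_len % 3 != 0:
            gene.attributes["invalid"] = True
            gene.attributes["invalid_reason"] = (
                f"spliced CDS length {spliced_len} not a multiple of 3")
    return genome


def write_genome(genome: Genome, fasta_path, gff_path,
                 table_path=None) -> None:
    """Write a genome back out as FASTA + GFF3 (+ optional sidecar table)."""
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write([rec], str(fasta_path), "fasta")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome)}\n")
        for f in genome.features:
            attrs = {"ID": f.id}
            for k, v in f.attributes.items():
                if k == "parent":
                    attrs["Parent"] = v
                elif isinstance(v, bool):
                    attrs[k] = "true" if v else "false"
                else:
                    attrs[k] = v
            ftype = _GFF_TYPE_MAP_OUT.get(f.kind, f.kind)
            fh.write("\t".join([
                genome.id, "chromoforge", ftype,
                str(f.start + 1), str(f.end), ".", f.strand, ".",
                _format_gff_attributes(attrs)]) + "\n")
    if table_path is not None:
        with open(table_path, "w") as fh:
            fh.write("gene_id\tessential\tmitochondrial_function\n")
            for g in genome.genes():
                fh.write(f"{g.id}\t"
                         f"{str(bool(g.attributes.get('essential'))).lower()}\t"
                         f"{str(bool(g.attributes.get('mitochondrial_function'))).lower()}\n")


def write_edit_log(edit_log: EditLog, path) -> None:
    with open(path, "w") as fh:
        fh.write("orig_start\torig_end\tkind\treplacement\trule\tnote\n")
        for e in edit_log:
            fh.write(f"{e.orig_start}\t{e.orig_end}\t{e.kind}\t"
                     f"{e.replacement}\t{e.rule}\t{e.note}\n")


def read_edit_log(path) -> EditLog:
    edits = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            edits.append(Edit(kind=row["kind"],
                              orig_start=int(row["orig_start"]),
                              orig_end=int(row["orig_end"]),
                              replacement=row["replacement"] or "",
                              rule=row.get("rule", ""),
                              note=row.get("note", "")))
    return EditLog(edits)


def lift_features(genome: Genome, lift: LiftoverMap,
                  extra_features: list[Feature] | None = None
                  ) -> tuple[list[Feature], list[Feature]]:
    """Re-coordinate features through a liftover map.

    Returns (lifted, dropped): features whose interval survives (possibly
    shrunk at deleted edges) and features wholly removed by the design.
    """
    lifted, dropped = [], []
    for f in genome.features:
        ival = lift.lift_interval(f.start, f.end)
        if ival is None:
            dropped.append(f)
            continue
        lifted.append(replace(f, start=ival[0], end=ival[1],
                              attributes=dict(f.attributes)))
    # drop children of dropped parents (e.g. CDS of a deleted gene)
    dropped_ids = {f.id for f in dropped}
    keep = []
    for f in lifted:
        if f.attributes.get("parent") in dropped_ids:
            dropped.append(f)
        else:
            keep.append(f)
    if extra_features:
        keep.extend(extra_features)
    return keep, dropped


def write_design(genome: Genome, edit_log: EditLog, out_dir,
                 designed_genome: Genome | None = None) -> dict:
    """Write designed FASTA, lifted GFF3, edit-log TSV and a drop report.

    If ``designed_genome`` is not given it is derived by applying the log and
    lifting the annotation (new loxPsym insertions become loxPsym features).
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if designed_genome is None:
        designed_genome = derive_designed_genome(genome, edit_log)

    paths = {
        "fasta": out_dir / f"{genome.id}_design.fasta",
        "gff": out_dir / f"{genome.id}_design.gff3",
        "edits": out_dir / f"{genome.id}_edits.tsv",
        "dropped": out_dir / f"{genome.id}_dropped_features.tsv",
    }
    write_genome(designed_genome, paths["fasta"], paths["gff"])
    write_edit_log(edit_log, paths["edits"])
    lift = build_liftover(edit_log, len(genome))
    _, dropped = lift_features(genome, lift)
    with open(paths["dropped"], "w") as fh:
        fh.write("id\tkind\tstart\tend\tstrand\n")
        for f in dropped:
            fh.write(f"{f.id}\t{f.kind}\t{f.start}\t{f.end}\t{f.strand}\n")
    return paths


def derive_designed_genome(genome: Genome, edit_log: EditLog) -> Genome:
    """Apply an edit log and lift the annotation onto the designed sequence.

    Insertions and substitutions whose rule tag mentions loxPsym gain a new
    ``loxPsym`` feature at the inserted interval.
    """
    designed_seq = apply_edits(genome.sequence, edit_log)
    lift = build_liftover(edit_log, len(genome))
    new_feats = []
    n = 0
    for e in edit_log:
        if "loxpsym" not in e.rule.lower():
            continue
        # locate the replacement interval in designed coordinates
        des_start = _designed_offset(edit_log, e)
        n += 1
        new_feats.append(Feature(f"loxPsym_{n:03d}", "loxPsym",
                                 des_start, des_start + len(e.replacement),
                                 "+", {"rule": e.rule}))
    lifted, _ = lift_features(genome, lift, new_feats)
    return Genome(id=genome.id, sequence=designed_seq,
                  topology=genome.topology, features=lifted)


def _designed_offset(edit_log: EditLog, target: Edit) -> int:
    d = 0
    for e in edit_log:
        if e is target:
            return target.orig_start + d
        d += e.delta
    raise ValueError("edit not in log")
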