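"""Seeded synthetic genomes, assembly artifacts, and depth tracks.

Everything the toolkit consumes can be generated here deterministically,
so the whole pipeline is testable without downloads. The toy genome is a
miniature chromosome: telomeres and subtelomeric repeats at both ends, a
central centromere, intron-sparse protein-coding genes (ATG...stop, sense
codons only), tRNAs, LTRs and ARS elements separated by random intergenic
gaps. Genes flagged with mitochondrial function get a planted Puf3p
consensus in their 3' window so the insertion guard has something to
find; a fraction of intron-containing genes carry the intron inside the
stop codon, reproducing the annotation pattern that breaks intron-naive
stop-codon scans.

One integer seed governs all randomness, split into per-component streams
(layout, intergenic sequence, gene content) so adding a feature class
does not shift unrelated draws.

The toy genome is deliberately unrealistic in places: uniform codon
usage, no GC skew, short genes, no overlapping features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_io import Feature, Genome, write_genome
from .recoding import revcomp
from .verification import DepthTrack

_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA"))


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    genome_length: int = 60_000
    n_genes: int = 30
    essential_fraction: float = 0.3
    mito_fraction: float = 0.15
    n_trna: int = 3
    n_ltr: int = 4
    n_ars: int = 3
    intron_fraction: float = 0.2
    terminal_intron_fraction: float = 0.3   # introns placed inside the stop
    essential_intron_fraction: float = 0.2
    stop_weights: dict = field(default_factory=lambda: {
        "TAA": 0.5, "TAG": 0.3, "TGA": 0.2})
    gene_len_range: tuple[int, int] = (500, 1800)
    intron_len_range: tuple[int, int] = (60, 200)
    gap_range: tuple[int, int] = (150, 500)
    telomere_len: int = 500
    subtelomere_len: int = 800
    centromere_len: int = 120
    centromere_clearance: int = 150


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def _make_gene(rng: np.random.Generator, spec: FixtureSpec):
    """Returns (genomic_seq, strand, cds_split, intron_len, stop, flags)."""
    lo, hi = spec.gene_len_range
    n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
    stops = sorted(spec.stop_weights)
    probs = np.array([spec.stop_weights[s] for s in stops], dtype=float)
    probs /= probs.sum()
    stop = stops[rng.choice(len(stops), p=probs)]
    codon_idx = rng.integers(0, len(_SENSE_CODONS), n_codons - 2)
    cds = "ATG" + "".join(_SENSE_CODONS[i] for i in codon_idx) + stop
    strand = "+" if rng.random() < 0.5 else "-"

    intron = None
    split = None
    if rng.random() < spec.intron_fraction:
        ilen = int(rng.integers(*spec.intron_len_range))
        intron = "GT" + _rand_seq(rng, ilen - 4) + "AG"
        if rng.random() < spec.terminal_intron_fraction:
            # intron interrupts the stop codon itself
            split = len(cds) - 3 + int(rng.integers(1, 3))
        else:
            k = int(rng.integers(10, (len(cds) // 3) - 10))
            split = 3 * k
    essential_intron = intron is not None and (
        rng.random() < spec.essential_intron_fraction)

    if intron is None:
        coding = cds
    else:
        coding = cds[:split] + intron + cds[split:]
    genomic = coding if strand == "+" else revcomp(coding)
    return genomic, strand, split, (len(intron) if intron else 0), \
        essential_intron, len(cds)


def generate_toy_genome(spec: FixtureSpec | None = None, seed: int = 42,
                        out_dir=None) -> Genome:
    """Generate a deterministic toy chromosome; optionally write
    FASTA + GFF3 + essentiality TSV to ``out_dir``."""
    spec = spec or FixtureSpec()
    ss = np.random.SeedSequence(seed)
    rng_layout, rng_seq, rng_gene = (
        np.random.default_rng(s) for s in ss.spawn(3))

    n_ess = int(round(spec.n_genes * spec.essential_fraction))
    n_mito = int(round(spec.n_genes * spec.mito_fraction))
    gene_ids = [f"G{i:04d}" for i in range(1, spec.n_genes + 1)]
    essential = set(rng_layout.choice(spec.n_genes, n_ess, replace=False))
    mito = set(rng_layout.choice(spec.n_genes, n_mito, replace=False))
    # keep at least one non-essential mitochondrial gene so the Puf3 guard
    # has a live target
    if mito and mito <= essential:
        mito.add(next(i for i in range(spec.n_genes) if i not in essential))

    queue: list[tuple[str, int]] = [("gene", i) for i in range(spec.n_genes)]
    queue += [("tRNA", i) for i in range(spec.n_trna)]
    queue += [("LTR", i) for i in range(spec.n_ltr)]
    queue += [("ARS", i) for i in range(spec.n_ars)]
    order = rng_layout.permutation(len(queue))
    queue = [queue[i] for i in order]

    parts: list[str] = []
    features: list[Feature] = []
    cursor = 0

    def emit(seq: str):
        nonlocal cursor
        parts.append(seq)
        cursor += len(seq)

    emit(_rand_seq(rng_seq, spec.telomere_len))
    features.append(Feature("TEL_L", "telomere", 0, cursor, "+"))
    sub_start = cursor
    unit = _rand_seq(rng_seq, 50)
    emit((unit * (spec.subtelomere_len // 50 + 1))[:spec.subtelomere_len])
    features.append(Feature("XSUB_L", "subtelomeric_repeat",
                            sub_start, cursor, "+"))

    centromere_placed = False
    half = spec.genome_length // 2
    pending_motif: tuple[int, str] | None = None

    for kind, idx in queue:
        gap = int(rng_layout.integers(*spec.gap_range))
        gap_seq = list(_rand_seq(rng_seq, gap))
        if pending_motif is not None:
            off, motif = pending_motif
            if off + len(motif) <= gap:
                gap_seq[off:off + len(motif)] = motif
            pending_motif = None
        emit("".join(gap_seq))

        if not centromere_placed and cursor >= half:
            emit(_rand_seq(rng_seq, spec.centromere_clearance))
            cen_start = cursor
            emit(_rand_seq(rng_seq, spec.centromere_len))
            features.append(Feature("CEN", "centromere",
                                    cen_start, cursor, "+"))
            emit(_rand_seq(rng_seq, spec.centromere_clearance))
            centromere_placed = True
            emit(_rand_seq(rng_seq, int(rng_layout.integers(*spec.gap_range))))

        if kind == "gene":
            gid = gene_ids[idx]
            genomic, strand, split, ilen, ess_intron, cds_len = \
                _make_gene(rng_gene, spec)
            g0 = cursor
            emit(genomic)
            g1 = cursor
            attrs = {
                "essential": idx in essential,
                "mitochondrial_function": idx in mito,
            }
            features.append(Feature(gid, "gene", g0, g1, strand, attrs))
            total = g1 - g0
            if ilen == 0:
                features.append(Feature(f"{gid}.cds1", "CDS_block", g0, g1,
                                        strand, {"parent": gid}))
            else:
                if strand == "+":
                    i0, i1 = g0 + split, g0 + split + ilen
                else:
                    i0 = g0 + (total - split - ilen)
                    i1 = g0 + (total - split)
                features.append(Feature(f"{gid}.cds1", "CDS_block", g0, i0,
                                        strand, {"parent": gid}))
                features.append(Feature(f"{gid}.intron1", "intron", i0, i1,
                                        strand, {"parent": gid,
                                                 "essential_intron": ess_intron}))
                features.append(Feature(f"{gid}.cds2", "CDS_block", i1, g1,
                                        strand, {"parent": gid}))
            if idx in mito:
                # plant the Puf3 consensus ~20 bp into the 3' window
                if strand == "+":
                    pending_motif = (20, "TGTAAATA")
                else:
                    # coding-strand motif upstream of the genomic start: the
                    # last emitted gap is gone, so rewrite the tail of the
                    # previous gap part
                    prev = parts[-2]
                    m = revcomp("TGTAAATA")
                    if len(prev) >= 28:
                        parts[-2] = prev[:-28] + m + prev[-20:]
        elif kind == "tRNA":
            length = int(rng_gene.integers(70, 91))
            s0 = cursor
            emit(_rand_seq(rng_seq, length))
            features.append(Feature(f"tRNA_{idx + 1:02d}", "tRNA",
                                    s0, cursor, "+"))
        elif kind == "LTR":
            length = int(rng_gene.integers(250, 351))
            s0 = cursor
            emit(_rand_seq(rng_seq, length))
            features.append(Feature(f"LTR_{idx + 1:02d}", "LTR",
                                    s0, cursor, "+"))
        elif kind == "ARS":
            length = int(rng_gene.integers(150, 251))
            s0 = cursor
            emit(_rand_seq(rng_seq, length))
            features.append(Feature(f"ARS_{idx + 1:02d}", "ARS",
                                    s0, cursor, "+"))

    tail_needed = cursor + spec.subtelomere_len + spec.telomere_len
    if tail_needed > spec.genome_length:
        raise FixtureError(
            f"spec infeasible: elements need {tail_needed} bp "
            f"> genome_length {spec.genome_length}")
    if not centromere_placed:
        raise FixtureError("spec infeasible: centromere was never reached")
    filler = spec.genome_length - tail_needed
    emit(_rand_seq(rng_seq, filler))
    s0 = cursor
    emit((unit * (spec.subtelomere_len // 50 + 1))[:spec.subtelomere_len])
    features.append(Feature("XSUB_R", "subtelomeric_repeat", s0, cursor, "+"))
    s0 = cursor
    emit(_rand_seq(rng_seq, spec.telomere_len))
    features.append(Feature("TEL_R", "telomere", s0, cursor, "+"))

    genome = Genome(id=f"toy_chr_seed{seed}", sequence="".join(parts),
                    topology="linear", features=features)
    if out_dir is not None:
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_genome(genome, out / "toy.fasta", out / "toy.gff3",
                     out / "toy_essentiality.tsv")
    return genome


# ---------------------------------------------------------------------------
# assembly artifacts
# ---------------------------------------------------------------------------

@dataclass
class Artifact:
    type: str             # tandem_amplification | foreign_insertion | substitution
    start: int
    end: int
    copies: int = 1
    vector: str = ""
    payload: str = ""
    payload_id: str = ""
    dup_len: int = 20

    def __post_init__(self):
        if self.type not in ("tandem_amplification", "foreign_insertion",
                             "substitution"):
            raise FixtureError(f"bad artifact type {self.type!r}")


@dataclass
class ArtifactTruth:
    records: list[Artifact]

    def of_type(self, t: str) -> list[Artifact]:
        return [a for a in self.records if a.type == t]


def inject_artifacts(sequence: str, artifacts: list[Artifact], seed: int = 0
                     ) -> tuple[list[str], ArtifactTruth]:
    """Mutate a design sequence into 'assembled' contigs carrying known
    artifacts; returns (contigs, truth table). Artifacts must not overlap.
    """
    arts = sorted(artifacts, key=lambda a: a.start)
    for a, b in zip(arts, arts[1:]):
        if b.start < a.end:
            raise FixtureError("overlapping artifact targets")
    rng = np.random.default_rng(seed)
    seq = sequence
    for a in reversed(arts):
        if a.end > len(sequence):
            raise FixtureError("artifact target out of bounds")
        if a.type == "tandem_amplification":
            interval = sequence[a.start:a.end]
            copies = [interval] * a.copies
            joined = (a.vector.join(copies) if a.vector
                      else "".join(copies))
            seq = seq[:a.start] + joined + seq[a.end:]
        elif a.type == "foreign_insertion":
            p = a.start
            dup = sequence[max(0, p - a.dup_len):p]
            seq = seq[:p] + a.payload + dup + seq[p:]
        elif a.type == "substitution":
            length = a.end - a.start
            orig = seq[a.start:a.end]
            repl = orig
            while repl == orig:
                repl = _rand_seq(rng, length)
            seq = seq[:a.start] + repl + seq[a.end:]
    return [seq], ArtifactTruth(list(arts))


def simulate_depth(design_length: int, truth: ArtifactTruth | None = None,
                   mean_depth: float = 30.0, noise: bool = True,
                   seed: int = 0) -> DepthTrack:
    """Per-base depth ~ Poisson(mean_depth x local copy number); copy
    number comes from the tandem-amplification truth records."""
    if mean_depth <= 0:
        raise FixtureError("mean_depth must be > 0")
    copy = np.ones(design_length)
    if truth is not None:
        for a in truth.of_type("tandem_amplification"):
            copy[a.start:a.end] = a.copies
    lam = mean_depth * copy
    if noise:
        rng = np.random.default_rng(seed)
        values = rng.poisson(lam).astype(float)
    else:
        values = lam
    return DepthTrack("design", values, 1)
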