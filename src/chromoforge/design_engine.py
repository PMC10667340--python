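"""The Sc2.0-style redesign rule engine.

Applies, in a fixed order, the full rule set to a native chromosome:
element deletions (tRNA, LTR, subtelomeric repeats, non-essential introns,
with loxPsym landmarks at deleted tRNA/LTR positions), TAG->TAA stop
recoding, loxPsym insertion 3' of non-essential genes with safety guards
(centromere buffer, Puf3-consensus scan, feature-overlap, convergent-gene
merge), PCRTag watermark recoding, telomere seed capping, and synthesis
chunk-junction recoding. Every edit is accumulated in one EditLog in
original coordinates; `verify_design` re-checks any designed sequence
against the rules from scratch.

The centromere buffer exists because mis-spacing a loxPsym site 66 bp from
a centromere (instead of the intended 100 bp) measurably impairs growth;
the Puf3 guard exists because loxPsym insertion into 3' UTRs carrying the
Puf3p binding consensus disrupts mRNA localization to mitochondria.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .annotation_io import (
    Edit, EditLog, Feature, Genome, build_liftover, derive_designed_genome,
)
from . import recoding
from .recoding import revcomp, spliced_cds, swap_tag_stops

#: the 34-bp symmetric Cre target site: 13-bp arm / 8-bp symmetric spacer /
#: 13-bp arm; the full site equals its own reverse complement, so Cre
#: recombines pairs of sites in either relative orientation.
LOXPSYM = "ATAACTTCGTATAATGTACATTATACGAAGTTAT"

#: Puf3p binding consensus on the coding strand (DNA; H = A/C/T)
PUF3_CONSENSUS = "TGTAHATA"
_H = "ACT"


class DesignError(RuntimeError):
    pass


@dataclass
class DesignRuleSet:
    """Tunable switches and thresholds of the redesign rule set."""

    delete_trna: bool = True
    delete_ltr: bool = True
    delete_nonessential_introns: bool = True
    delete_subtelomeric: bool = True
    swap_tag: bool = True
    insert_loxpsym: bool = True
    loxpsym_offset_bp: int = 3
    landmark_loxpsym: bool = True
    centromere_buffer_bp: int = 100
    puf3_guard: str = "skip"          # off | warn | skip
    puf3_scan_window_bp: int = 200
    convergent_merge_bp: int = 50
    telomere_seed: str | None = None
    loxpsym_site: str = LOXPSYM
    pcrtag_params: object | None = "default"
    chunk_params: object | None = "default"

    def __post_init__(self):
        if self.loxpsym_offset_bp < 0 or self.centromere_buffer_bp < 0:
            raise ValueError("offsets and buffers must be >= 0")
        if self.puf3_guard not in ("off", "warn", "skip"):
            raise ValueError(f"bad puf3_guard {self.puf3_guard!r}")


@dataclass
class DesignReport:
    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    guard_skips: list = field(default_factory=list)

    def bump(self, key: str, n: int = 1):
        self.counts[key] = self.counts.get(key, 0) + n


@dataclass
class Violation:
    kind: str
    message: str
    start: int = -1
    end: int = -1


def puf3_sites(window: str) -> list[int]:
    """Offsets of the Puf3p consensus TGTAHATA within a coding-strand window."""
    hits = []
    for h in _H:
        motif = PUF3_CONSENSUS.replace("H", h)
        start = 0
        while True:
            i = window.find(motif, start)
            if i < 0:
                break
            hits.append(i)
            start = i + 1
    return sorted(hits)


def _near_centromere(genome: Genome, start: int, end: int, buffer_bp: int) -> bool:
    for cen in genome.features_of_kind("centromere"):
        if start < cen.end + buffer_bp and cen.start - buffer_bp < end:
            return True
    return False


def _essential_cds_overlap(genome: Genome, start: int, end: int) -> str | None:
    for gene in genome.genes():
        if not gene.attributes.get("essential"):
            continue
        for b in genome.cds_blocks(gene.id):
            if b.overlaps(start, end):
                return gene.id
    return None


# ---------------------------------------------------------------------------
# rule steps
# ---------------------------------------------------------------------------

def delete_elements(genome: Genome, rules: DesignRuleSet,
                    report: DesignReport | None = None) -> EditLog:
    """Delete tRNAs, LTRs, subtelomeric repeats and non-essential introns.

    Deleted tRNA/LTR landmarks are replaced in place by one loxPsym site
    when ``landmark_loxpsym`` is on. Subtelomeric repeats abutting a
    terminal telomere are left for the telomere-capping step to absorb (so
    the two rules never overlap). Elements overlapping an essential CDS or
    lying inside the centromere buffer are skipped with a warning.
    """
    report = report if report is not None else DesignReport()
    edits: list[Edit] = []
    telomeres = genome.features_of_kind("telomere")

    targets: list[tuple[Feature, str]] = []
    if rules.delete_trna:
        targets += [(f, "delete_trna") for f in genome.features_of_kind("tRNA")]
    if rules.delete_ltr:
        targets += [(f, "delete_ltr") for f in genome.features_of_kind("LTR")]
    if rules.delete_subtelomeric:
        for f in genome.features_of_kind("subtelomeric_repeat"):
            if rules.telomere_seed and any(
                    t.end >= f.start - 1 and t.start <= f.end + 1
                    for t in telomeres):
                continue  # absorbed by cap_telomeres
            targets.append((f, "delete_subtelomeric"))
    if rules.delete_nonessential_introns:
        for f in genome.features_of_kind("intron"):
            if not f.attributes.get("essential_intron", False):
                targets.append((f, "delete_intron"))
            else:
                report.bump("introns_retained")

    for f, rule in sorted(targets, key=lambda t: t[0].start):
        if rule != "delete_intron":
            owner = _essential_cds_overlap(genome, f.start, f.end)
            if owner:
                report.guard_skips.append((f.id, rule, f"overlaps essential CDS {owner}"))
                report.warnings.append(
                    f"{rule}: {f.id} skipped (overlaps essential CDS {owner})")
                continue
        if _near_centromere(genome, f.start, f.end, rules.centromere_buffer_bp):
            report.guard_skips.append((f.id, rule, "centromere buffer"))
            report.warnings.append(
                f"{rule}: {f.id} skipped (within centromere buffer)")
            continue
        landmark = (rules.landmark_loxpsym and rule in ("delete_trna", "delete_ltr"))
        if landmark:
            edits.append(Edit("substitution", f.start, f.end,
                              rules.loxpsym_site, rule="landmark_loxpsym",
                              note=f"{f.kind}:{f.id}"))
        else:
            edits.append(Edit("deletion", f.start, f.end,
                              rule=rule, note=f"{f.kind}:{f.id}"))
        report.bump(rule.replace("delete_", "") + "_deleted")
        if landmark:
            report.bump("loxpsym_landmark")
    return EditLog(edits)


def _gene_stop_flank(genome: Genome, gene: Feature) -> tuple[int, int]:
    """(insertion point at offset 0, direction sign) just past the stop."""
    blocks = genome.cds_blocks(gene.id)
    if gene.strand == "+":
        return max(b.end for b in blocks), +1
    return min(b.start for b in blocks), -1


def insert_loxpsym(genome: Genome, rules: DesignRuleSet,
                   existing: EditLog | None = None,
                   report: DesignReport | None = None) -> EditLog:
    """Insert one loxPsym 3' of each non-essential gene, subject to guards.

    Guards, in order: centromere buffer, Puf3 consensus in the 3' window
    (policy per ``puf3_guard``; mitochondrial-function genes are skipped,
    others warned), overlap with another feature or an existing edit, and
    convergent-gene merge (two candidate points within
    ``convergent_merge_bp`` collapse to one shared site at their midpoint).
    """
    report = report if report is not None else DesignReport()
    existing = existing or EditLog([])
    candidates: list[tuple[int, str]] = []

    for gene in sorted(genome.genes(), key=lambda g: g.start):
        if gene.attributes.get("essential") or gene.attributes.get("invalid"):
            continue
        if not genome.cds_blocks(gene.id):
            continue
        anchor, sign = _gene_stop_flank(genome, gene)
        point = anchor + sign * rules.loxpsym_offset_bp
        if not (0 <= point <= len(genome)):
            report.guard_skips.append((gene.id, "loxpsym_utr", "out of bounds"))
            continue
        if _near_centromere(genome, point, point, rules.centromere_buffer_bp):
            report.guard_skips.append((gene.id, "loxpsym_utr", "centromere buffer"))
            report.warnings.append(
                f"loxPsym for {gene.id} skipped: inside centromere buffer")
            continue
        if rules.puf3_guard != "off":
            w = rules.puf3_scan_window_bp
            if sign > 0:
                window = genome.sequence[anchor:anchor + w]
            else:
                window = revcomp(genome.sequence[max(0, anchor - w):anchor])
            if puf3_sites(window):
                mito = gene.attributes.get("mitochondrial_function", False)
                if rules.puf3_guard == "skip" and mito:
                    report.guard_skips.append((gene.id, "loxpsym_utr", "puf3"))
                    report.warnings.append(
                        f"loxPsym for {gene.id} skipped: Puf3 consensus in "
                        f"3' window of a mitochondrial-function gene")
                    continue
                report.warnings.append(
                    f"loxPsym for {gene.id}: Puf3 consensus in 3' window "
                    f"(inserted; policy={rules.puf3_guard}, mito={mito})")
        inside = [f for f in genome.features
                  if f.start < point < f.end and f.id != gene.id
                  and f.attributes.get("parent") != gene.id]
        if inside:
            report.guard_skips.append(
                (gene.id, "loxpsym_utr", f"inside feature {inside[0].id}"))
            report.warnings.append(
                f"loxPsym for {gene.id} skipped: point {point} lies inside "
                f"feature {inside[0].id}")
            continue
        if existing.overlaps_interval(point, point) or any(
                e.kind != "insertion" and e.orig_start < point < e.orig_end
                for e in existing):
            report.guard_skips.append((gene.id, "loxpsym_utr", "edit overlap"))
            report.warnings.append(
                f"loxPsym for {gene.id} skipped: point {point} collides with "
                f"an existing edit")
            continue
        candidates.append((point, gene.id))

    candidates.sort()
    merged: list[tuple[int, str]] = []
    for point, gid in candidates:
        if merged and point - merged[-1][0] <= rules.convergent_merge_bp:
            prev_point, prev_gid = merged[-1]
            mid = (prev_point + point) // 2
            merged[-1] = (mid, f"{prev_gid}+{gid}")
            report.bump("loxpsym_merged")
        else:
            merged.append((point, gid))

    edits = []
    for point, gid in merged:
        edits.append(Edit("insertion", point, point, rules.loxpsym_site,
                          rule="loxpsym_utr", note=gid))
        report.bump("loxpsym_utr")
    return EditLog(edits)


def cap_telomeres(genome: Genome, rules: DesignRuleSet,
                  report: DesignReport | None = None) -> EditLog:
    """Replace each terminal telomere (plus its abutting subtelomeric repeat,
    when repeat deletion is on) with the user-supplied seed sequence; the
    right arm receives the reverse complement of the seed."""
    report = report if report is not None else DesignReport()
    if genome.topology == "circular":
        raise DesignError("telomere capping undefined for circular topology")
    if not rules.telomere_seed:
        raise DesignError("telomere_seed not provided")
    telomeres = sorted(genome.features_of_kind("telomere"), key=lambda f: f.start)
    if len(telomeres) < 2:
        report.warnings.append("telomere annotation missing at one or both "
                               "ends: no capping performed")
        return EditLog([])
    left, right = telomeres[0], telomeres[-1]
    subs = genome.features_of_kind("subtelomeric_repeat")
    l_end, r_start = left.end, right.start
    if rules.delete_subtelomeric:
        for f in subs:
            if f.start <= left.end + 1 and f.end > left.end:
                l_end = max(l_end, f.end)
            if f.end >= right.start - 1 and f.start < right.start:
                r_start = min(r_start, f.start)
    edits = [
        Edit("substitution", left.start, l_end, rules.telomere_seed,
             rule="telomere_cap", note="left arm"),
        Edit("substitution", r_start, right.end, revcomp(rules.telomere_seed),
             rule="telomere_cap", note="right arm (revcomp seed)"),
    ]
    report.bump("telomeres_capped", 2)
    return EditLog(edits)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_design(genome: Genome, rules: DesignRuleSet | None = None
               ) -> tuple[Genome, EditLog, DesignReport]:
    """Apply the full rule set in fixed order and return the designed
    genome, the combined edit log (original coordinates) and the report.

    Order: element deletions -> TAG swap -> loxPsym insertion -> PCRTag
    recoding -> telomere capping -> chunk-junction recoding.
    """
    rules = rules or DesignRuleSet()
    report = DesignReport()
    log = EditLog([])

    if any((rules.delete_trna, rules.delete_ltr, rules.delete_subtelomeric,
            rules.delete_nonessential_introns)):
        log = log.merged(delete_elements(genome, rules, report))

    if rules.swap_tag:
        def ok(pos: int) -> bool:
            if _near_centromere(genome, pos, pos + 1, rules.centromere_buffer_bp):
                return False
            return not log.overlaps_interval(pos, pos + 1)
        swap_log, swap_report = swap_tag_stops(genome, skip_check=ok)
        report.counts["tag_swaps"] = swap_report["edited"]
        report.warnings.extend(swap_report["warnings"])
        log = log.merged(swap_log)

    if rules.insert_loxpsym:
        log = log.merged(insert_loxpsym(genome, rules, existing=log,
                                        report=report))

    if rules.pcrtag_params is not None:
        from . import pcrtag as pcrtag_mod
        params = (pcrtag_mod.PCRTagParams()
                  if rules.pcrtag_params == "default" else rules.pcrtag_params)
        tags, tag_log, tag_report = pcrtag_mod.design_pcrtags(
            genome, params, existing=log)
        report.counts["pcrtag_pairs"] = len(tags)
        report.counts["pcrtag_untagged_genes"] = len(tag_report["untagged"])
        log = log.merged(tag_log)
        report.pcrtags = tags  # type: ignore[attr-defined]

    if rules.telomere_seed:
        log = log.merged(cap_telomeres(genome, rules, report))

    designed = derive_designed_genome(genome, log)

    if rules.chunk_params is not None:
        from . import chunking
        params = (chunking.ChunkParams()
                  if rules.chunk_params == "default" else rules.chunk_params)
        site_edits, junction_warnings = chunking.recode_internal_sites(
            designed, params)
        report.warnings.extend(junction_warnings)
        if site_edits:
            lift = build_liftover(log, len(genome))
            added = 0
            for des_pos, new_base in site_edits:
                orig = lift.to_original(des_pos)
                if not isinstance(orig, int) or log.overlaps_interval(
                        orig, orig + 1):
                    report.warnings.append(
                        f"junction recode at designed position {des_pos} "
                        f"could not be merged into the edit log; site left "
                        f"for junction placement")
                    continue
                log.add(Edit("substitution", orig, orig + 1, new_base,
                             rule="junction_recode",
                             note=f"designed pos {des_pos}"))
                added += 1
            report.counts["junction_recodes"] = added
            designed = derive_designed_genome(genome, log)

    # final roll-up of per-rule counts straight from the log
    landmark_notes = [e.note for e in log.by_rule("landmark_loxpsym")]
    report.counts["trna_deleted"] = (
        len(log.by_rule("delete_trna"))
        + sum(n.startswith("tRNA:") for n in landmark_notes))
    report.counts["ltr_deleted"] = (
        len(log.by_rule("delete_ltr"))
        + sum(n.startswith("LTR:") for n in landmark_notes))
    for rule_tag, key in (("delete_intron", "intron_deleted"),
                          ("delete_subtelomeric", "subtelomeric_deleted"),
                          ("landmark_loxpsym", "loxpsym_landmark"),
                          ("loxpsym_utr", "loxpsym_utr"),
                          ("tag_swap", "tag_swaps"),
                          ("telomere_cap", "telomeres_capped"),
                          ("pcrtag", "pcrtag_edits"),
                          ("junction_recode", "junction_recodes")):
        report.counts[key] = len(log.by_rule(rule_tag))
    report.counts["loxpsym_inserted"] = (
        report.counts["loxpsym_utr"] + report.counts["loxpsym_landmark"])
    return designed, log, report


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------

def verify_design(original: Genome, designed: Genome,
                  rules: DesignRuleSet | None = None,
                  chunks=None,
                  translation_exclusions: tuple[str, ...] = ()
                  ) -> list[Violation]:
    """Check a designed genome against the rule set; returns all violations.

    Checks: residual spliced TAG stops; residual tRNA/LTR/subtelomeric
    features; any sequence change within the centromere buffer; junction
    recognition sites inside chunk bodies (when chunks are supplied);
    non-synonymous CDS changes (minus an exclusion list); loxPsym placed at
    the 3' insertion offset of an essential gene.
    """
    rules = rules or DesignRuleSet()
    out: list[Violation] = []

    for gene in designed.genes():
        if gene.attributes.get("invalid") or not designed.cds_blocks(gene.id):
            continue
        try:
            cds = spliced_cds(designed, gene.id)
        except recoding.RecodingError as exc:
            out.append(Violation("invalid_cds", f"{gene.id}: {exc}",
                                 gene.start, gene.end))
            continue
        if rules.swap_tag and cds[-3:] == "TAG":
            out.append(Violation("residual_tag_stop",
                                 f"{gene.id} still terminates TAG",
                                 gene.start, gene.end))

    for kind, flag in (("tRNA", rules.delete_trna),
                       ("LTR", rules.delete_ltr),
                       ("subtelomeric_repeat", rules.delete_subtelomeric)):
        if not flag:
            continue
        for f in designed.features_of_kind(kind):
            out.append(Violation("residual_element",
                                 f"{kind} {f.id} survives in design",
                                 f.start, f.end))

    out.extend(_centromere_window_check(original, designed,
                                        rules.centromere_buffer_bp))

    if chunks is not None:
        from . import chunking
        for c in chunks:
            body = designed.sequence[c.start:c.end]
            for enzyme in (c.left_junction, c.right_junction):
                if enzyme is None:
                    continue
                for pos in chunking.find_recognition_sites(body, enzyme.recognition):
                    out.append(Violation(
                        "junction_site_in_body",
                        f"{enzyme.enzyme} site inside chunk {c.label} at "
                        f"body offset {pos}", c.start + pos))

    orig_genes = {g.id for g in original.genes()}
    for gene in designed.genes():
        if gene.id not in orig_genes or gene.id in translation_exclusions:
            continue
        if gene.attributes.get("invalid"):
            continue
        try:
            a = recoding.translate(spliced_cds(original, gene.id))
            b = recoding.translate(spliced_cds(designed, gene.id))
        except recoding.RecodingError:
            continue  # reported above
        if a[:-1] != b[:-1] or (a[-1] == "*") != (b[-1] == "*"):
            out.append(Violation("translation_changed",
                                 f"{gene.id} protein differs after design",
                                 gene.start, gene.end))

    for gene in designed.genes():
        if not gene.attributes.get("essential"):
            continue
        blocks = designed.cds_blocks(gene.id)
        if not blocks:
            continue
        anchor, sign = _gene_stop_flank(designed, gene)
        for lox in designed.features_of_kind("loxPsym"):
            pos = lox.start if sign > 0 else lox.end
            if 0 <= sign * (pos - anchor) <= rules.loxpsym_offset_bp:
                out.append(Violation(
                    "loxpsym_in_essential_utr",
                    f"loxPsym {lox.id} at 3' offset of essential gene {gene.id}",
                    lox.start, lox.end))
    return out


def _centromere_window_check(original: Genome, designed: Genome,
                             buffer_bp: int) -> list[Violation]:
    o_cens = original.features_of_kind("centromere")
    d_cens = designed.features_of_kind("centromere")
    out = []
    for o, d in zip(o_cens, d_cens):
        up_o = original.sequence[max(0, o.start - buffer_bp):o.start]
        up_d = designed.sequence[max(0, d.start - buffer_bp):d.start]
        dn_o = original.sequence[o.end:o.end + buffer_bp]
        dn_d = designed.sequence[d.end:d.end + buffer_bp]
        if up_o != up_d:
            out.append(Violation(
                "centromere_buffer_edit",
                f"sequence within {buffer_bp} bp upstream of {o.id} was edited",
                max(0, d.start - buffer_bp), d.start))
        if dn_o != dn_d:
            out.append(Violation(
                "centromere_buffer_edit",
                f"sequence within {buffer_bp} bp downstream of {o.id} was edited",
                d.end, d.end + buffer_bp))
    if len(o_cens) != len(d_cens):
        out.append(Violation("centromere_buffer_edit",
                             "centromere count differs between original and "
                             "designed annotation"))
    return out
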