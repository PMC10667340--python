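"""Rule application, insertion guards, full-pipeline consistency checks."""

import pytest

from chromoforge.annotation_io import (
    Edit, EditLog, Feature, Genome, apply_edits, derive_designed_genome,
)
from chromoforge.design_engine import (
    LOXPSYM, DesignError, DesignRuleSet, cap_telomeres, delete_elements,
    insert_loxpsym, puf3_sites, run_design, verify_design,
)
from chromoforge.recoding import revcomp, spliced_cds, translate


def _bare_rules(**kw):
    base = dict(pcrtag_params=None, chunk_params=None)
    base.update(kw)
    return DesignRuleSet(**base)


def locus_with_elements():
    """120-bp spacers around 2 tRNAs and 3 LTRs, nothing else."""
    parts, feats = [], []
    cursor = 0

    def pad(n=120):
        nonlocal cursor
        parts.append("ACGT" * (n // 4))
        cursor += n

    pad()
    for i in range(2):
        parts.append("TTCCGGAA" * 10)
        feats.append(Feature(f"t{i}", "tRNA", cursor, cursor + 80, "+"))
        cursor += 80
        pad()
    for i in range(3):
        parts.append("GGGCCCTT" * 30)
        feats.append(Feature(f"l{i}", "LTR", cursor, cursor + 240, "+"))
        cursor += 240
        pad()
    return Genome("elems", "".join(parts), features=feats)


class TestLoxPsymSite:
    def test_site_is_its_own_reverse_complement(self):
        assert len(LOXPSYM) == 34
        assert revcomp(LOXPSYM) == LOXPSYM

    def test_arm_spacer_arm_structure(self):
        arm_l, spacer, arm_r = LOXPSYM[:13], LOXPSYM[13:21], LOXPSYM[21:]
        assert len(spacer) == 8
        assert revcomp(arm_r) == arm_l
        assert revcomp(spacer) == spacer


class TestDeleteElements:
    def test_landmark_replacement_counts(self):
        g = locus_with_elements()
        log = delete_elements(g, _bare_rules())
        subs = [e for e in log if e.rule == "landmark_loxpsym"]
        assert len(subs) == 5  # 2 tRNA + 3 LTR, each replaced by a site
        assert all(e.replacement == LOXPSYM for e in subs)

    def test_landmark_off_gives_plain_deletions(self):
        g = locus_with_elements()
        log = delete_elements(g, _bare_rules(landmark_loxpsym=False))
        assert len(log) == 5
        assert all(e.kind == "deletion" for e in log)

    def test_no_elements_empty_log(self):
        g = Genome("empty", "ACGT" * 100)
        assert len(delete_elements(g, _bare_rules())) == 0

    def test_essential_intron_retained(self, toy_genome, default_rules):
        log = delete_elements(toy_genome, default_rules)
        deleted_ids = {e.note.split(":")[1] for e in log
                       if e.rule == "delete_intron"}
        essential_introns = [f.id for f in toy_genome.features
                             if f.kind == "intron"
                             and f.attributes.get("essential_intron")]
        assert essential_introns  # the fixture provides at least one
        assert not deleted_ids & set(essential_introns)


def gene_locus(strand="+", upstream_motif=None, cen_at=None, pad=300):
    """One non-essential gene in a padded locus; optionally a Puf3 motif in
    the 3' window or a centromere ``cen_at`` bp downstream of the stop."""
    cds = "ATGGCTAAACCCGGGAAGCTTGCTTAA"
    left = "AC" * (pad // 2)
    right = list("GT" * (pad // 2))
    if upstream_motif:
        right[20:28] = upstream_motif
    right = "".join(right)
    coding = cds if strand == "+" else revcomp(cds)
    if strand == "+":
        seq = left + coding + right
        g0, g1 = len(left), len(left) + len(cds)
    else:
        seq = right[::-1] + coding + left  # motif window precedes the gene
        g0, g1 = pad, pad + len(cds)
    feats = [Feature("g1", "gene", g0, g1, strand, {"essential": False}),
             Feature("g1.c1", "CDS_block", g0, g1, strand, {"parent": "g1"})]
    if cen_at is not None:
        cs = g1 + cen_at if strand == "+" else g0 - cen_at - 120
        feats.append(Feature("CEN", "centromere", cs, cs + 120, "+"))
        if strand == "+":
            seq = seq + "ACGT" * 60
    return Genome("locus", seq, features=feats)


class TestInsertLoxpsym:
    def test_plus_strand_offset(self):
        g = gene_locus("+")
        log = insert_loxpsym(g, _bare_rules())
        assert len(log) == 1
        e = log.edits[0]
        gene = g.feature_by_id("g1")
        assert e.kind == "insertion" and e.orig_start == gene.end + 3

    def test_minus_strand_offset(self):
        g = gene_locus("-")
        log = insert_loxpsym(g, _bare_rules())
        gene = g.feature_by_id("g1")
        assert log.edits[0].orig_start == gene.start - 3

    def test_centromere_buffer_guard(self):
        from chromoforge.design_engine import DesignReport
        g = gene_locus("+", cen_at=40)  # insertion point 37 bp from CEN
        report = DesignReport()
        log = insert_loxpsym(g, _bare_rules(), report=report)
        assert len(log) == 0
        assert any("centromere" in r for _, _, r in report.guard_skips)

    def test_puf3_guard_skips_mitochondrial_gene(self):
        from chromoforge.design_engine import DesignReport
        g = gene_locus("+", upstream_motif="TGTAAATA")
        g.feature_by_id("g1").attributes["mitochondrial_function"] = True
        report = DesignReport()
        log = insert_loxpsym(g, _bare_rules(), report=report)
        assert len(log) == 0
        assert any("puf3" in r for _, _, r in report.guard_skips)

    def test_puf3_warns_but_inserts_for_non_mito_gene(self):
        from chromoforge.design_engine import DesignReport
        g = gene_locus("+", upstream_motif="TGTACATA")
        report = DesignReport()
        log = insert_loxpsym(g, _bare_rules(), report=report)
        assert len(log) == 1
        assert any("Puf3" in w for w in report.warnings)

    def test_essential_gene_skipped(self):
        g = gene_locus("+")
        g.feature_by_id("g1").attributes["essential"] = True
        assert len(insert_loxpsym(g, _bare_rules())) == 0

    def test_puf3_consensus_degeneracy(self):
        assert puf3_sites("TGTAAATA") and puf3_sites("TGTACATA") \
            and puf3_sites("TGTATATA")
        assert not puf3_sites("TGTAGATA")  # H excludes G


class TestCapTelomeres:
    def test_both_ends_capped_right_arm_revcomp(self):
        seed = "ACGGTTTACCCTGTG"
        seq = "T" * 100 + "ACGT" * 200 + "A" * 100
        g = Genome("tel", seq, features=[
            Feature("TEL_L", "telomere", 0, 100, "+"),
            Feature("TEL_R", "telomere", 900, 1000, "+")])
        log = cap_telomeres(g, _bare_rules(telomere_seed=seed))
        assert len(log) == 2
        left, right = log.edits
        assert left.replacement == seed
        assert right.replacement == revcomp(seed)
        designed = apply_edits(seq, log)
        assert designed.startswith(seed) and designed.endswith(revcomp(seed))

    def test_circular_topology_rejected(self):
        g = Genome("circ", "ACGT" * 100, topology="circular")
        with pytest.raises(DesignError, match="circular"):
            cap_telomeres(g, _bare_rules(telomere_seed="ACGT"))

    def test_missing_annotation_warns_no_edit(self):
        from chromoforge.design_engine import DesignReport
        g = Genome("bare", "ACGT" * 100)
        report = DesignReport()
        log = cap_telomeres(g, _bare_rules(telomere_seed="ACGT"),
                            report=report)
        assert len(log) == 0 and report.warnings


class TestRunDesign:
    def test_all_rules_off_identity(self, toy_genome):
        rules = DesignRuleSet(
            delete_trna=False, delete_ltr=False, delete_subtelomeric=False,
            delete_nonessential_introns=False, swap_tag=False,
            insert_loxpsym=False, pcrtag_params=None, chunk_params=None)
        designed, log, report = run_design(toy_genome, rules)
        assert designed.sequence == toy_genome.sequence
        assert len(log) == 0

    def test_report_counts_match_census(self, toy_genome, design_bundle):
        designed, log, report = design_bundle
        n_trna = len(toy_genome.features_of_kind("tRNA"))
        n_ltr = len(toy_genome.features_of_kind("LTR"))
        introns = toy_genome.features_of_kind("intron")
        n_del_introns = sum(
            not f.attributes.get("essential_intron") for f in introns)
        n_tag = sum(spliced_cds(toy_genome, g.id)[-3:] == "TAG"
                    for g in toy_genome.genes())
        assert report.counts["trna_deleted"] == n_trna
        assert report.counts["ltr_deleted"] == n_ltr
        assert report.counts["intron_deleted"] == n_del_introns
        assert report.counts["tag_swaps"] == n_tag
        nonessential = sum(not g.attributes.get("essential")
                           for g in toy_genome.genes())
        lox_skips = sum(1 for _, rule, _ in report.guard_skips
                        if rule == "loxpsym_utr")
        merges = report.counts.get("loxpsym_merged", 0)
        assert report.counts["loxpsym_utr"] == nonessential - lox_skips - merges

    def test_length_arithmetic(self, toy_genome, design_bundle):
        designed, log, _ = design_bundle
        delta = sum(e.delta for e in log)
        assert len(designed) == len(toy_genome) + delta

    def test_counts_equal_log_grouped_by_rule(self, design_bundle):
        _, log, report = design_bundle
        assert report.counts["loxpsym_utr"] == len(log.by_rule("loxpsym_utr"))
        assert report.counts["tag_swaps"] == len(log.by_rule("tag_swap"))
        assert report.counts["intron_deleted"] == \
            len(log.by_rule("delete_intron"))

    def test_determinism(self, toy_genome, default_rules, design_bundle):
        designed2, _, _ = run_design(toy_genome, default_rules)
        assert designed2.sequence == design_bundle[0].sequence

    def test_disabling_a_rule_zeroes_its_count(self, toy_genome,
                                               default_rules):
        rules = DesignRuleSet(telomere_seed=default_rules.telomere_seed,
                              insert_loxpsym=False,
                              pcrtag_params=None, chunk_params=None)
        _, _, report = run_design(toy_genome, rules)
        assert report.counts["loxpsym_utr"] == 0

    def test_translation_preserved_genome_wide(self, toy_genome,
                                               design_bundle):
        designed, _, _ = design_bundle
        checked = 0
        for gene in designed.genes():
            if gene.attributes.get("invalid"):
                continue
            a = translate(spliced_cds(toy_genome, gene.id))
            b = translate(spliced_cds(designed, gene.id))
            assert a[:-1] == b[:-1], gene.id
            checked += 1
        assert checked == len(toy_genome.genes())


class TestVerifyDesign:
    def test_clean_design_no_violations(self, toy_genome, default_rules,
                                        design_bundle):
        designed, _, _ = design_bundle
        assert verify_design(toy_genome, designed, default_rules) == []

    def test_centromere_spacing_error_flagged(self):
        """A loxPsym landing 66 bp from the centromere after an erroneous
        34-bp spacer deletion (instead of the intended 100-bp spacing) is
        caught by the 100-bp buffer."""
        g = gene_locus("+", cen_at=250)
        cen = g.feature_by_id("CEN")
        err_start = cen.end + 66
        log = EditLog([Edit("substitution", err_start, err_start + 34,
                            LOXPSYM, rule="loxpsym_error")])
        designed = derive_designed_genome(g, log)
        assert len(designed) == len(g)  # 34 bp out, 34 bp in
        violations = verify_design(g, designed, _bare_rules())
        assert any(v.kind == "centromere_buffer_edit" for v in violations)

    def test_nonsynonymous_edit_flagged(self, toy_genome):
        gene = next(g for g in toy_genome.genes()
                    if g.strand == "+" and not toy_genome.introns(g.id))
        pos = gene.start + 4  # inside codon 2
        base = toy_genome.sequence[pos]
        new = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        log = EditLog([Edit("substitution", pos, pos + 1, new, rule="damage")])
        designed = derive_designed_genome(toy_genome, log)
        violations = verify_design(toy_genome, designed, _bare_rules())
        kinds = {v.kind for v in violations}
        assert "translation_changed" in kinds or "residual_tag_stop" in kinds
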