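"""Spliced CDS access, intron-aware stop swapping, synonymous recoding."""

import pytest
from hypothesis import given, settings, strategies as st

from chromoforge.annotation_io import Feature, Genome, apply_edits
from chromoforge.recoding import (
    RecodingError, brute_force_max_mismatch, naive_tag_scan, revcomp,
    spliced_cds, swap_tag_stops, synonymous_recode, translate,
)


def single_gene_genome(coding, strand="+", intron=None, intron_at=None,
                       pad=20):
    """Build a one-gene genome from a coding-orientation CDS; optionally
    interrupt it with an intron at coding position ``intron_at``."""
    if intron is None:
        genomic = coding
    else:
        genomic = coding[:intron_at] + intron + coding[intron_at:]
    if strand == "-":
        genomic = revcomp(genomic)
    left = "ACGT" * (pad // 4)
    seq = left + genomic + left
    g0, g1 = len(left), len(left) + len(genomic)
    feats = [Feature("g1", "gene", g0, g1, strand, {"essential": False})]
    if intron is None:
        feats.append(Feature("g1.c1", "CDS_block", g0, g1, strand,
                             {"parent": "g1"}))
    else:
        total = g1 - g0
        ilen = len(intron)
        if strand == "+":
            i0, i1 = g0 + intron_at, g0 + intron_at + ilen
        else:
            i0 = g0 + (total - intron_at - ilen)
            i1 = g0 + (total - intron_at)
        feats += [
            Feature("g1.c1", "CDS_block", g0, i0, strand, {"parent": "g1"}),
            Feature("g1.i1", "intron", i0, i1, strand,
                    {"parent": "g1", "essential_intron": False}),
            Feature("g1.c2", "CDS_block", i1, g1, strand, {"parent": "g1"}),
        ]
    return Genome("mini", seq, features=feats)


class TestSplicedCds:
    def test_plus_strand_is_substring(self):
        g = single_gene_genome("ATGGCTGCTTAA")
        assert spliced_cds(g, "g1") == "ATGGCTGCTTAA"
        assert spliced_cds(g, "g1") in g.sequence

    def test_minus_strand_is_revcomp(self):
        cds = "ATGGCTGCTTAA"
        g = single_gene_genome(cds, strand="-")
        gene = g.feature_by_id("g1")
        assert spliced_cds(g, "g1") == cds
        assert g.sequence[gene.start:gene.end] == revcomp(cds)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_intron_excised(self, strand):
        cds = "ATGGCTAAACCCGGGTAA"
        g = single_gene_genome(cds, strand=strand,
                               intron="GTAAGTTTTTTTAG", intron_at=9)
        assert spliced_cds(g, "g1") == cds

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_stop_codon_read_through_intron(self, strand):
        # the stop codon is split by the intron: TAG must still be seen
        cds = "ATGGCTAAATAG"
        g = single_gene_genome(cds, strand=strand,
                               intron="GTCCCCCCCCAG", intron_at=len(cds) - 2)
        assert spliced_cds(g, "g1")[-3:] == "TAG"


class TestSwapTagStops:
    def test_taa_stop_untouched(self):
        g = single_gene_genome("ATGGCTGCTTAA")
        log, report = swap_tag_stops(g)
        assert len(log) == 0 and report["tag_stops"] == 0

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_tag_swapped_single_base(self, strand):
        g = single_gene_genome("ATGGCTGCTTAG", strand=strand)
        log, report = swap_tag_stops(g)
        assert len(log) == 1 and report["edited"] == 1
        e = log.edits[0]
        assert e.orig_end - e.orig_start == 1
        designed = apply_edits(g.sequence, log)
        g2 = Genome("mini", designed, features=list(g.features))
        assert spliced_cds(g2, "g1")[-3:] == "TAA"

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_intron_split_stop_found_where_naive_scan_misses(self, strand):
        """Regression for the annotation pitfall: a TAG whose codon is
        interrupted by an intron is invisible to an intron-naive window
        scan but must be recoded from the spliced sequence."""
        cds = "ATGGCTAAATAG"
        g = single_gene_genome(cds, strand=strand,
                               intron="GTCCCCCCCCAG", intron_at=len(cds) - 2)
        assert naive_tag_scan(g) == []          # the naive scan misses it
        log, report = swap_tag_stops(g)
        assert report["edited"] == 1
        designed = apply_edits(g.sequence, log)
        g2 = Genome("mini", designed, features=list(g.features))
        assert spliced_cds(g2, "g1")[-3:] == "TAA"

    def test_count_matches_brute_force_scan(self, toy_genome):
        expected = sum(
            spliced_cds(toy_genome, g.id)[-3:] == "TAG"
            for g in toy_genome.genes() if not g.attributes.get("invalid"))
        log, report = swap_tag_stops(toy_genome)
        assert expected > 0
        assert report["edited"] == expected == len(log)

    def test_idempotent(self, toy_genome):
        log, _ = swap_tag_stops(toy_genome)
        designed = apply_edits(toy_genome.sequence, log)
        # all edits are single-base substitutions: features keep coordinates
        g2 = Genome(toy_genome.id, designed,
                    features=list(toy_genome.features))
        log2, report2 = swap_tag_stops(g2)
        assert len(log2) == 0 and report2["tag_stops"] == 0


class TestSynonymousRecode:
    def test_remove_motif_example(self):
        res = synonymous_recode("GGTACC", 0, "remove_motif",
                                {"motif": "GGTACC"})
        assert "GGTACC" not in res.recoded_fragment
        assert "GGTACC" not in revcomp(res.recoded_fragment)
        assert translate(res.recoded_fragment) == translate("GGTACC")

    def test_absent_motif_identity(self):
        res = synonymous_recode("ATGGCT", 0, "remove_motif",
                                {"motif": "GGTACC"})
        assert res.recoded_fragment == "ATGGCT"
        assert res.substitutions == []

    def test_remove_motif_infeasible_reports_blocker(self):
        # Met-Trp has no synonymous codons at all
        with pytest.raises(RecodingError, match="ATG|TGG"):
            synonymous_recode("ATGTGG", 0, "remove_motif",
                              {"motif": "ATGTGG"})

    def test_maximize_mismatch_matches_exhaustive_oracle(self):
        frag = "CTGCTGCTG"  # Leu x3: 6^3 synonymous combinations
        res = synonymous_recode(frag, 0, "maximize_mismatch")
        assert res.objective_value == brute_force_max_mismatch(frag) == 6
        assert translate(res.recoded_fragment) == translate(frag)

    @pytest.mark.parametrize("frag", ["ATGAAACGTTGG", "GCTGCAAGAAGG",
                                      "TTATCAGGTGGA"])
    def test_maximize_mismatch_oracle_various(self, frag):
        res = synonymous_recode(frag, 0, "maximize_mismatch")
        assert res.objective_value == brute_force_max_mismatch(frag)

    def test_introduce_motif(self):
        # Gly-Thr window can carry GGTACC (KpnI) synonymously
        res = synonymous_recode("GGAACA", 0, "introduce_motif",
                                {"motif": "GGTACC", "offset": 0})
        assert res.recoded_fragment == "GGTACC"
        assert translate(res.recoded_fragment) == translate("GGAACA")

    def test_frame_offset_protects_partial_codons(self):
        # fragment starts at codon position 1: first two bases are locked
        res = synonymous_recode("TGCTGCTG", 1, "maximize_mismatch")
        assert res.recoded_fragment[:2] == "TG"
        # complete codons are [2,5) and [5,8)
        assert translate(res.recoded_fragment[2:8]) == translate("CTGCTG")

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.sampled_from(
        [c for c in ("GCT", "CGT", "AAT", "GAT", "TGT", "CAA", "GGT",
                     "CTG", "TCT", "ACG", "TAT", "TTC")]),
        min_size=2, max_size=8))
    def test_protein_always_preserved(self, codons):
        frag = "".join(codons)
        res = synonymous_recode(frag, 0, "maximize_mismatch")
        assert len(res.recoded_fragment) == len(frag)
        assert translate(res.recoded_fragment) == translate(frag)
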