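"""loxPsym recombination enumeration and eccDNA inheritance dynamics."""

from collections import Counter

import numpy as np
import pytest

from chromoforge.eccdna import (
    LOX, EccError, EccParams, Element, LoxLocus, classify_specc,
    enumerate_products, gap1_syn_locus, simulate_inheritance,
)


def element_census(items):
    return Counter(x.id for x in items if x != LOX)


def two_site_locus():
    return LoxLocus("linear", (
        Element("up", "spacer", 100),
        LOX,
        Element("rep", "reporter", 700),
        Element("gene", "gene", 1500),
        Element("ori", "ARS", 200),
        LOX,
        Element("down", "spacer", 100),
    ))


def n_site_locus(n):
    items = [Element("e0", "spacer", 50)]
    for i in range(n):
        items.append(LOX)
        items.append(Element(f"e{i + 1}", "gene", 100))
    return LoxLocus("linear", tuple(items))


class TestEnumerate:
    @pytest.mark.parametrize("n_sites", [0, 1])
    def test_too_few_sites_no_products(self, n_sites):
        assert enumerate_products(n_site_locus(n_sites)) == []

    def test_two_sites_excision_circle_structure(self):
        """Excision across the two sites yields the canonical circle:
        reporter + gene + ARS + exactly one loxPsym, with the residual
        molecule keeping the other recombinant site."""
        products = enumerate_products(two_site_locus())
        excisions = [p for p in products if p.type == "excision"]
        assert len(excisions) == 1
        circle, residual = excisions[0].molecules
        assert circle.topology == "circular"
        assert circle.lox_count == 1
        assert element_census(circle.items) == Counter(
            {"rep": 1, "gene": 1, "ori": 1})
        assert residual.topology == "linear"
        assert residual.lox_count == 1
        assert element_census(residual.items) == Counter(
            {"up": 1, "down": 1})

    def test_inversion_preserves_elements_and_sites(self):
        products = enumerate_products(two_site_locus())
        inv = [p for p in products if p.type == "inversion"]
        assert len(inv) == 1
        (mol,) = inv[0].molecules
        assert mol.lox_count == 2
        assert element_census(mol.items) == element_census(
            two_site_locus().items)
        # interval orientation flipped
        inner = [x for x in mol.items if x != LOX][1:-1]
        assert all(e.orientation == "-" for e in inner)

    def test_four_sites_pair_enumeration(self):
        """4 sites -> 6 unordered pairs -> 12 intramolecular products
        (one excision + one inversion each) before deduplication."""
        locus = n_site_locus(4)
        raw_pairs = 4 * 3 // 2
        products = enumerate_products(locus)
        by_type = Counter(p.type for p in products)
        # this locus has distinct element content per interval: nothing dedups
        assert by_type["excision"] == raw_pairs
        assert by_type["inversion"] == raw_pairs
        assert len(products) == 2 * raw_pairs

    def test_element_conservation_every_event(self):
        locus = n_site_locus(4)
        parent = element_census(locus.items)
        for p in enumerate_products(locus, sister_chromatid=True):
            if p.type == "duplication":
                # the gained copy is accounted against the sister molecule
                gained, lost = p.molecules
                assert element_census(gained.items) - parent == \
                    parent - element_census(lost.items)
            else:
                combined = Counter()
                for m in p.molecules:
                    combined += element_census(m.items)
                assert combined == parent

    def test_excision_element_multiset_union(self):
        locus = n_site_locus(4)
        parent = element_census(locus.items)
        for p in enumerate_products(locus):
            if p.type != "excision":
                continue
            combined = Counter()
            for m in p.molecules:
                combined += element_census(m.items)
            assert combined == parent

    def test_reversal_invariance(self):
        locus = two_site_locus()
        rev = LoxLocus("linear", tuple(
            x if x == LOX else x.flipped() for x in reversed(locus.items)))
        a = {p.canonical() for p in enumerate_products(locus)}
        b = {p.canonical() for p in enumerate_products(rev)}
        assert a == b

    def test_duplication_gains_interval_and_site(self):
        products = enumerate_products(two_site_locus(), sister_chromatid=True)
        dup = [p for p in products if p.type == "duplication"]
        assert len(dup) == 1
        gained, lost = dup[0].molecules
        assert gained.lox_count == 3   # parent's 2 + 1 extra
        assert element_census(gained.items)["gene"] == 2
        assert element_census(lost.items)["gene"] == 0


class TestClassify:
    def test_ars_circle_is_propagable_specc(self):
        speccs = classify_specc(enumerate_products(gap1_syn_locus()))
        assert len(speccs) == 1
        s = speccs[0]
        assert s.has_ars and s.propagable and s.has_reporter
        assert s.payload_genes == ("GAP1",)

    def test_circle_without_ars_not_propagable(self):
        locus = LoxLocus("linear", (
            Element("a", "spacer", 10), LOX,
            Element("g", "gene", 100), LOX,
            Element("b", "spacer", 10)))
        speccs = classify_specc(enumerate_products(locus))
        assert len(speccs) == 1
        assert not speccs[0].has_ars and not speccs[0].propagable

    def test_linear_molecules_excluded(self):
        speccs = classify_specc(enumerate_products(two_site_locus()))
        assert all(s.molecule.topology == "circular" for s in speccs)


class TestInheritance:
    def test_heterogeneity_with_doubling_and_unbiased_segregation(self):
        params = EccParams(replication="ars_doubling", segregation_bias=0.5)
        traj = simulate_inheritance(1, params, 10, 5000, seed=1)
        last = traj.iloc[-1]
        assert 0.0 < last.carrier_fraction < 1.0
        assert last.var_copies > 0.0

    def test_no_replication_full_mother_bias_dilutes(self):
        params = EccParams(replication="none", segregation_bias=1.0)
        traj = simulate_inheritance(1, params, 6, 1000, seed=2)
        # daughters never receive a copy: carrier fraction halves per
        # generation as the pedigree doubles
        fracs = traj.carrier_fraction.to_numpy()
        assert fracs[0] == 1.0
        assert np.allclose(fracs, 1.0 / 2 ** np.arange(len(fracs)))

    def test_mean_total_copies_conserved_without_replication(self):
        params = EccParams(replication="none", segregation_bias=0.5)
        traj = simulate_inheritance(3, params, 10, 2000, seed=3)
        assert traj.total_copies.nunique() == 1

    def test_selection_increases_carrier_fraction_every_generation(self):
        base = EccParams(replication="ars_doubling", segregation_bias=0.5)
        sel = EccParams(replication="ars_doubling", segregation_bias=0.5,
                        selection="dropout")
        t0 = simulate_inheritance(1, base, 8, 3000, seed=4)
        t1 = simulate_inheritance(1, sel, 8, 3000, seed=4)
        merged = t0.merge(t1, on="generation", suffixes=("_none", "_sel"))
        assert (merged.carrier_fraction_sel >=
                merged.carrier_fraction_none).all()

    def test_reproducible_given_seed(self):
        params = EccParams()
        a = simulate_inheritance(2, params, 6, 500, seed=9)
        b = simulate_inheritance(2, params, 6, 500, seed=9)
        assert a.equals(b)

    def test_invalid_bias_rejected(self):
        with pytest.raises(EccError):
            EccParams(segregation_bias=1.5)
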