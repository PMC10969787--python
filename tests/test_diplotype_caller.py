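"""Diplotype calling: dosage consistency, ranking, and oracle equivalence.

The independent oracle enumerates, for every unordered allele pair, the
per-locus allele-membership counts and checks them against the observed
dosages — written from the definition, separately from the caller.
"""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from pgxkit.diplotype_caller import call_all_genes, call_diplotype, pair_consistent
from pgxkit.variant_io import GenotypeObservation, SampleGenotypes

from conftest import make_synthetic_kb

STATES = {0: "hom_ref", 1: "het", 2: "hom_alt", None: "no_call"}


def make_sg(kb, gene, dosages: dict[str, int | None]) -> SampleGenotypes:
    """Observations for a gene; unspecified catalog loci are hom_ref."""
    sg = SampleGenotypes("S", "GRCh38")
    for v in kb.gene_variants(gene):
        d = dosages.get(v.rsid, 0)
        sg.obs[(gene, v.rsid)] = GenotypeObservation(STATES[d])
    return sg


def oracle_candidates(allele_rsids: dict[str, frozenset], dosages: dict):
    """Brute-force enumeration over all unordered pairs (the oracle)."""
    out = set()
    for a, b in itertools.combinations_with_replacement(sorted(allele_rsids), 2):
        ok = True
        for rsid, dose in dosages.items():
            if dose is None:
                continue
            if (rsid in allele_rsids[a]) + (rsid in allele_rsids[b]) != dose:
                ok = False
                break
        if ok:
            out.add(frozenset([a, b]) if a != b else frozenset([a]))
    return out


class TestPairConsistent:
    def test_all_hom_ref_matches_reference_pair(self, kb):
        sg = make_sg(kb, "CYP2C19", {})
        a1 = kb.allele("CYP2C19", "*1")
        assert pair_consistent(sg, "CYP2C19", a1, a1)

    def test_het_matches_het_pair_not_hom_pair(self, kb):
        sg = make_sg(kb, "CYP2C19", {"rs4244285": 1})
        a1 = kb.allele("CYP2C19", "*1")
        a2 = kb.allele("CYP2C19", "*2")
        assert pair_consistent(sg, "CYP2C19", a1, a2)
        assert not pair_consistent(sg, "CYP2C19", a2, a2)

    def test_double_het_compound_diplotype(self, kb):
        sg = make_sg(kb, "CYP2C19", {"rs4244285": 1, "rs4986893": 1})
        a2 = kb.allele("CYP2C19", "*2")
        a3 = kb.allele("CYP2C19", "*3")
        assert pair_consistent(sg, "CYP2C19", a2, a3)

    def test_symmetry(self, kb):
        sg = make_sg(kb, "CYP2D6", {"rs1065852": 2, "rs3892097": 1, "rs1135840": 1})
        for s1, s2 in itertools.product(["*1", "*4", "*10", "*41"], repeat=2):
            a1, a2 = kb.allele("CYP2D6", s1), kb.allele("CYP2D6", s2)
            assert pair_consistent(sg, "CYP2D6", a1, a2) == pair_consistent(
                sg, "CYP2D6", a2, a1
            )

    def test_no_call_loci_impose_no_constraint(self, kb):
        sg = make_sg(kb, "CYP2C19", {"rs4244285": None})
        a1 = kb.allele("CYP2C19", "*1")
        a2 = kb.allele("CYP2C19", "*2")
        assert pair_consistent(sg, "CYP2C19", a1, a1)
        assert pair_consistent(sg, "CYP2C19", a1, a2)


class TestCallDiplotype:
    def test_all_hom_ref_is_reference_exact(self, kb):
        call = call_diplotype(make_sg(kb, "CYP2C19", {}), kb, "CYP2C19")
        assert (call.alias, call.quality) == ("*1/*1", "exact")

    def test_hom_alt_forces_homozygous_diplotype(self, kb):
        call = call_diplotype(
            make_sg(kb, "CYP2C19", {"rs4244285": 2}), kb, "CYP2C19"
        )
        assert (call.alias, call.quality) == ("*2/*2", "exact")

    def test_nested_defining_sets_resolved_like_oracle(self):
        # *4's defining set strictly contains *2's
        alleles = {
            "*1": frozenset(),
            "*2": frozenset({"rs901"}),
            "*4": frozenset({"rs901", "rs902"}),
        }
        skb = make_synthetic_kb(alleles)
        dosages = {"rs901": 2, "rs902": 1}
        call = call_diplotype(make_sg(skb, "GENE", dosages), skb, "GENE")
        expected = oracle_candidates(alleles, dosages)
        got = {frozenset(p) for p in call.candidates}
        assert got == expected
        assert call.alias == "*2/*4"
        assert call.quality == "exact"

    def test_unresolved_when_no_pair_fits(self, kb):
        # het at *2's locus and hom-alt at *3's: needs three alt alleles
        sg = make_sg(kb, "CYP2C19", {"rs4244285": 1, "rs4986893": 2})
        call = call_diplotype(sg, kb, "CYP2C19")
        assert call.quality == "unresolved"
        assert call.allele_pair is None and call.candidates == []

    def test_no_call_quality_when_all_loci_dark(self, kb):
        sg = make_sg(
            kb, "CYP2C19",
            {"rs4244285": None, "rs4986893": None, "rs12248560": None},
        )
        call = call_diplotype(sg, kb, "CYP2C19")
        assert call.quality == "no_call"
        assert set(call.uncovered) == {"rs4244285", "rs4986893", "rs12248560"}

    def test_incomplete_when_chosen_pair_has_dark_locus(self, kb):
        # *4 observed only at one of its two defining loci
        sg = make_sg(kb, "CYP2D6", {"rs3892097": 1, "rs1065852": None})
        call = call_diplotype(sg, kb, "CYP2D6")
        assert call.quality == "incomplete"
        assert "rs1065852" in call.uncovered

    def test_ambiguity_surfaced_not_resolved(self):
        # two alleles could each explain a het at their own dark locus
        alleles = {
            "*1": frozenset(),
            "*2": frozenset({"rs901"}),
            "*3": frozenset({"rs902"}),
        }
        skb = make_synthetic_kb(alleles)
        sg = make_sg(skb, "GENE", {"rs901": 1, "rs902": None})
        call = call_diplotype(sg, skb, "GENE")
        # (*1,*2) and (*2,*3) both consistent; parsimony picks *1/*2 but the
        # alternatives stay visible
        assert len(call.candidates) > 1
        assert call.alias == "*1/*2"
        assert call.quality in ("ambiguous", "incomplete")

    def test_monotone_candidates_under_information_removal(self, kb):
        full = make_sg(kb, "CYP2D6", {"rs1065852": 1, "rs3892097": 1})
        masked = make_sg(
            kb, "CYP2D6", {"rs1065852": 1, "rs3892097": None}
        )
        c_full = {frozenset(p) for p in call_diplotype(full, kb, "CYP2D6").candidates}
        c_masked = {frozenset(p) for p in call_diplotype(masked, kb, "CYP2D6").candidates}
        assert c_full <= c_masked


class TestCallAllGenes:
    def test_reference_sample_yields_13_reference_calls(self, kb):
        sg = SampleGenotypes("S", "GRCh38")
        for gene in kb.genes:
            for v in kb.gene_variants(gene):
                sg.obs[(gene, v.rsid)] = GenotypeObservation("hom_ref")
        calls = call_all_genes(sg, kb)
        assert len(calls) == 13
        assert [c.gene for c in calls] == list(kb.genes)
        assert all(c.alias == "*1/*1" and c.quality == "exact" for c in calls)

    def test_variant_in_one_gene_is_local(self, kb):
        sg = SampleGenotypes("S", "GRCh38")
        for gene in kb.genes:
            for v in kb.gene_variants(gene):
                sg.obs[(gene, v.rsid)] = GenotypeObservation("hom_ref")
        sg.obs[("TPMT", "rs1800462")] = GenotypeObservation("het")
        calls = {c.gene: c for c in call_all_genes(sg, kb)}
        assert calls["TPMT"].alias == "*1/*2"
        assert all(c.alias == "*1/*1" for g, c in calls.items() if g != "TPMT")

    def test_determinism(self, kb):
        sg = make_sg(kb, "CYP2D6", {"rs1065852": 1, "rs1135840": 1})
        a = call_diplotype(sg, kb, "CYP2D6")
        b = call_diplotype(sg, kb, "CYP2D6")
        assert (a.alias, a.quality, a.candidates) == (b.alias, b.quality, b.candidates)


@st.composite
def catalog_and_observations(draw):
    n_loci = draw(st.integers(1, 6))
    loci = [f"rs{i}" for i in range(n_loci)]
    n_alleles = draw(st.integers(1, 7))
    alleles = {"*1": frozenset()}
    for i in range(n_alleles):
        s = frozenset(draw(st.sets(st.sampled_from(loci), min_size=1)))
        alleles.setdefault(f"*{i + 2}", s)
    # drop alleles with duplicate defining sets (catalog invariant)
    seen, unique = set(), {}
    for name, s in alleles.items():
        if s not in seen:
            seen.add(s)
            unique[name] = s
    used_loci = sorted({r for s in unique.values() for r in s})
    dosages = {
        r: draw(st.sampled_from([0, 1, 2, None])) for r in used_loci
    }
    return unique, dosages


@settings(max_examples=200, deadline=None, derandomize=True)
@given(catalog_and_observations())
def test_candidate_set_equals_brute_force_oracle(case):
    """Property: the caller's candidate set equals exhaustive enumeration."""
    alleles, dosages = case
    skb = make_synthetic_kb(alleles)
    sg = make_sg(skb, "GENE", dosages)
    call = call_diplotype(sg, skb, "GENE")
    got = {frozenset(p) for p in call.candidates}
    assert got == oracle_candidates(alleles, dosages)
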