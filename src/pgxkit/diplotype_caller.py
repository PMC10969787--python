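"""Star-allele diplotype assignment from unphased catalog genotypes.

The model is dosage-based: an unordered allele pair (a1, a2) is consistent
with the observations when, at every catalog locus of the gene with a usable
genotype, the number of the two alleles whose defining set contains that
locus equals the observed alternate-allele dosage.  No-call loci impose no
constraint, so removing information can only enlarge the candidate set.

Ranking among multiple consistent candidates (all of which, by construction,
explain every observed alt-bearing locus) is by parsimony — fewest
non-reference alleles — with a final deterministic tie-break on the
normalized alias.  Ambiguity is surfaced in the call quality, never resolved
silently.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

from .knowledgebase import AlleleDefinition, KnowledgeBase, normalize_alias, star_sort_key
from .variant_io import SampleGenotypes

_DOSAGE_BY_STATE = {"hom_ref": 0, "het": 1, "hom_alt": 2}

Quality = str  # exact | ambiguous | incomplete | no_call | unresolved


@dataclass
class DiplotypeCall:
    """The called allele pair for one gene, with match quality."""

    gene: str
    allele_pair: tuple[str, str] | None
    quality: Quality
    candidates: list[tuple[str, str]] = field(default_factory=list)
    uncovered: list[str] = field(default_factory=list)

    @property
    def alias(self) -> str | None:
        if self.allele_pair is None:
            return None
        return normalize_alias("/".join(self.allele_pair))


def _pair_key(pair: tuple[str, str]) -> tuple:
    return tuple(star_sort_key(s) for s in sorted(pair, key=star_sort_key))


def _normalize_pair(a1: str, a2: str) -> tuple[str, str]:
    a, b = sorted((a1, a2), key=star_sort_key)
    return (a, b)


def pair_consistent(
    sg: SampleGenotypes, gene: str, a1: AlleleDefinition, a2: AlleleDefinition
) -> bool:
    """True iff (a1, a2) reproduces every observed dosage at the gene's loci."""
    states = sg.gene_states(gene)
    for rsid, state in states.items():
        if state == "no_call":
            continue
        expected = (rsid in a1.rsids) + (rsid in a2.rsids)
        if expected != _DOSAGE_BY_STATE[state]:
            return False
    return True


def call_diplotype(sg: SampleGenotypes, kb: KnowledgeBase, gene: str) -> DiplotypeCall:
    """Enumerate all unordered allele pairs and pick the best consistent one."""
    gene = kb.resolve_gene(gene)
    alleles = kb.genes[gene]
    states = sg.gene_states(gene)
    uncovered = sorted(r for r, s in states.items() if s == "no_call")

    candidates = [
        _normalize_pair(a1.star_name, a2.star_name)
        for a1, a2 in itertools.combinations_with_replacement(alleles, 2)
        if pair_consistent(sg, gene, a1, a2)
    ]
    candidates.sort(key=_pair_key)

    # every defining locus of every non-reference allele unobserved?
    nonref_loci = {
        r for a in alleles for r in a.rsids
    }
    all_dark = bool(nonref_loci) and all(
        states.get(r, "no_call") == "no_call" for r in nonref_loci
    )
    if all_dark:
        return DiplotypeCall(gene, None, "no_call", candidates, uncovered)
    if not candidates:
        return DiplotypeCall(gene, None, "unresolved", [], uncovered)

    def rank(pair: tuple[str, str]) -> tuple:
        rsids = {r for s in pair for r in kb.allele(gene, s).rsids}
        explained = sum(
            1 for r, st in states.items()
            if st in ("het", "hom_alt") and r in rsids
        )
        n_nonref = sum(1 for s in pair if s != "*1")
        return (-explained, n_nonref, _pair_key(pair))

    best = min(candidates, key=rank)
    chosen_loci = {r for s in best for r in kb.allele(gene, s).rsids}
    if any(states.get(r, "no_call") == "no_call" for r in chosen_loci):
        quality = "incomplete"
    elif len(candidates) == 1:
        quality = "exact"
    else:
        quality = "ambiguous"
    return DiplotypeCall(gene, best, quality, candidates, uncovered)


def call_all_genes(sg: SampleGenotypes, kb: KnowledgeBase) -> list[DiplotypeCall]:
    """One DiplotypeCall per catalog gene, in catalog (panel) order."""
    return [call_diplotype(sg, kb, gene) for gene in kb.genes]
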