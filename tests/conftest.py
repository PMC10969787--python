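import itertools

import pytest

from pgxkit.knowledgebase import (
    AlleleDefinition,
    DefiningVariant,
    KnowledgeBase,
    load_packaged_catalog,
)


@pytest.fixture(scope="session")
def kb():
    return load_packaged_catalog()


@pytest.fixture(scope="session")
def all_diplotypes(kb):
    """Every diplotype constructible from the packaged catalog, per gene."""
    out = {}
    for gene, alleles in kb.genes.items():
        names = [a.star_name for a in alleles]
        out[gene] = [
            f"{a}/{b}"
            for a, b in itertools.combinations_with_replacement(names, 2)
        ]
    return out


def make_synthetic_kb(allele_rsids: dict[str, frozenset[str]]) -> KnowledgeBase:
    """Build an in-memory single-gene ('GENE') knowledge base for the caller.

    ``allele_rsids`` maps star name -> rsids; loci are laid out at
    consecutive positions on chromosome 1.
    """
    all_rsids = sorted({r for s in allele_rsids.values() for r in s})
    variants = {
        r: DefiningVariant(
            rsid=r, chrom="1",
            pos_grch37=1000 + i, pos_grch38=2000 + i,
            ref="A", alt="G",
        )
        for i, r in enumerate(all_rsids)
    }
    alleles = tuple(
        AlleleDefinition(
            gene="GENE",
            star_name=star,
            defining_variants=frozenset(variants[r] for r in rsids),
        )
        for star, rsids in allele_rsids.items()
    )
    return KnowledgeBase(version="synthetic", genes={"GENE": alleles}, records=[])
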