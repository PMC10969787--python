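"""Diplotype-to-phenotype translation.

Two rule paths exist:

* **Activity score** (CYP2D6 in the packaged configuration): each allele
  carries a non-negative activity value; the diplotype score is their sum and
  is binned into metabolizer categories using the current CPIC consensus
  cut-offs — ultrarapid strictly above 2.25, normal on [1.25, 2.25],
  intermediate on the open interval (0, 1.25), poor at exactly 0.
* **Table lookup** (all other genes): the phenotype category is read from
  the knowledge-base diplotype row, whose interpretation body begins with the
  category text.

The mechanism is generic: any gene whose alleles all carry activity values
may opt into the score path via ``activity_genes``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .diplotype_caller import DiplotypeCall
from .knowledgebase import (
    KnowledgeBase,
    RECORD_NOT_FOUND,
    lookup_record,
    normalize_alias,
)

#: Genes translated through the activity-score system by default.
DEFAULT_ACTIVITY_GENES = frozenset({"CYP2D6"})

POOR = "Poor metabolizer"
INTERMEDIATE = "Intermediate metabolizer"
NORMAL = "Normal metabolizer"
ULTRARAPID = "Ultrarapid metabolizer"

#: Normal-metabolizer bin edges (inclusive); above the upper edge is UM.
NORMAL_RANGE = (1.25, 2.25)


@dataclass(frozen=True)
class PhenotypeAssignment:
    """The phenotype category assigned to one gene's called diplotype."""

    gene: str
    genotype_alias: str
    category: str
    rule_source: Literal["activity_score", "table_lookup"]
    activity_score: float | None = None
    indeterminate: bool = False

    def __post_init__(self):
        if (self.activity_score is not None) != (
            self.rule_source == "activity_score"
        ):
            raise ValueError(
                "activity_score present iff rule_source=activity_score"
            )


def allele_activity_value(kb: KnowledgeBase, gene: str, star_name: str) -> float | None:
    """Activity value of one allele, or None if the allele is unscored."""
    return kb.allele(gene, star_name).activity_value


def diplotype_activity_score(
    kb: KnowledgeBase, gene: str, allele_pair: tuple[str, str]
) -> float | None:
    """Sum of the two alleles' activity values; None if either is unscored."""
    values = [allele_activity_value(kb, gene, s) for s in allele_pair]
    if any(v is None for v in values):
        return None
    return sum(values)


def classify_activity_score(score: float) -> str:
    """Bin an activity score into a metabolizer category.

    Poor at exactly 0; intermediate on (0, 1.25); normal on [1.25, 2.25];
    ultrarapid strictly above 2.25.
    """
    if score < 0:
        raise ValueError(f"activity score must be non-negative, got {score}")
    if score == 0:
        return POOR
    if score < NORMAL_RANGE[0]:
        return INTERMEDIATE
    if score <= NORMAL_RANGE[1]:
        return NORMAL
    return ULTRARAPID


def assign_phenotype(
    kb: KnowledgeBase,
    call: DiplotypeCall,
    drug: str | None = None,
    *,
    activity_genes: frozenset[str] = DEFAULT_ACTIVITY_GENES,
) -> PhenotypeAssignment:
    """Translate a diplotype call into a phenotype category.

    ``call.quality`` must not be ``no_call``.  Failure to resolve either rule
    path yields an indeterminate assignment, not an error.
    """
    if call.quality == "no_call":
        raise ValueError(f"{call.gene}: cannot assign a phenotype to a no-call")
    gene = kb.resolve_gene(call.gene)
    if call.allele_pair is None:
        return PhenotypeAssignment(
            gene=gene, genotype_alias="", category="",
            rule_source="table_lookup", indeterminate=True,
        )
    alias = normalize_alias("/".join(call.allele_pair))

    if gene in activity_genes:
        score = diplotype_activity_score(kb, gene, call.allele_pair)
        if score is not None:
            return PhenotypeAssignment(
                gene=gene,
                genotype_alias=alias,
                category=classify_activity_score(score),
                rule_source="activity_score",
                activity_score=score,
            )

    drugs = [drug] if drug is not None else kb.gene_drugs.get(gene, [])
    for d in drugs:
        rec = lookup_record(kb, gene, alias, d)
        if rec is not RECORD_NOT_FOUND:
            return PhenotypeAssignment(
                gene=gene,
                genotype_alias=alias,
                category=rec.phenotype_category,
                rule_source="table_lookup",
            )
    return PhenotypeAssignment(
        gene=gene, genotype_alias=alias, category="",
        rule_source="table_lookup", indeterminate=True,
    )
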