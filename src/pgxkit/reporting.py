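"""Clinical PGx report rendering and serialization.

Three formats mirror the operator workflow:

* ``single_gene_drug`` — full detail for one gene-drug pair.
* ``summary`` — one row per gene across the panel; deliberately omits
  interpretation and dosing recommendations (pre-emptive screening view).
* ``full`` — per-gene blocks, each at single-gene detail level, for every
  selected drug of every selected gene.

Ambiguous or incomplete diplotype calls are surfaced in the document's
caveats, never silently dropped.  Timestamps are injectable so identical
inputs serialize byte-identically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

from .diplotype_caller import DiplotypeCall
from .errors import UnknownDrugError
from .knowledgebase import (
    KnowledgeBase,
    RECORD_NOT_FOUND,
    lookup_record,
)
from .phenotype_engine import PhenotypeAssignment

REPORT_FORMATS = ("single_gene_drug", "summary", "full")
SERIALIZATION_STYLES = ("tsv", "json", "text")

TSV_HEADER = [
    "gene", "drug", "genotype_alias", "nucleotide_change", "aa_change",
    "phenotype_category", "interpretation", "dosing_recommendation",
    "references",
]


@dataclass(frozen=True)
class ReportRow:
    gene: str
    drug: str | None
    genotype_alias: str
    nucleotide_change: str
    aa_change: str
    phenotype_category: str
    interpretation: str | None = None
    dosing_recommendation: str | None = None
    references: tuple[str, ...] = ()


@dataclass
class ReportDocument:
    format: str
    sample_id: str
    build: str
    created: str
    catalog_version: str
    rows: list[ReportRow] = field(default_factory=list)
    caveats: list[str] = field(default_factory=list)


def _changes(kb: KnowledgeBase, gene: str, pair: tuple[str, str]) -> tuple[str, str]:
    """cDNA and amino-acid change summaries for the called allele pair."""
    cdna, aa = [], []
    for star in dict.fromkeys(pair):  # stable, deduplicated
        allele = kb.allele(gene, star)
        for v in sorted(allele.defining_variants, key=lambda v: v.rsid):
            if v.cdna and v.cdna not in cdna:
                cdna.append(v.cdna)
            if v.aa_change not in ("", "none") and v.aa_change not in aa:
                aa.append(v.aa_change)
    return ("; ".join(cdna) or "none", "; ".join(aa) or "none")


def _detail_row(
    kb: KnowledgeBase,
    call: DiplotypeCall,
    phenotype: PhenotypeAssignment,
    drug: str,
) -> ReportRow:
    alias = call.alias or "indeterminate"
    nt, aa = (
        _changes(kb, call.gene, call.allele_pair)
        if call.allele_pair
        else ("none", "none")
    )
    rec = (
        lookup_record(kb, call.gene, alias, drug)
        if call.allele_pair
        else RECORD_NOT_FOUND
    )
    if rec is RECORD_NOT_FOUND:
        return ReportRow(
            gene=call.gene,
            drug=drug,
            genotype_alias=alias,
            nucleotide_change=nt,
            aa_change=aa,
            phenotype_category=phenotype.category or "indeterminate",
        )
    return ReportRow(
        gene=call.gene,
        drug=drug,
        genotype_alias=alias,
        nucleotide_change=nt,
        aa_change=aa,
        phenotype_category=phenotype.category or rec.phenotype_category,
        interpretation=rec.interpretation,
        dosing_recommendation=rec.dosing_recommendation,
        references=rec.references,
    )


def _caveats(calls: Sequence[DiplotypeCall]) -> list[str]:
    out = []
    for c in calls:
        if c.quality == "exact":
            continue
        msg = f"{c.gene}: call quality {c.quality}"
        if c.quality == "ambiguous":
            msg += " (candidates: " + ", ".join(
                "/".join(p) for p in c.candidates
            ) + ")"
        if c.uncovered:
            msg += f"; uncovered loci: {', '.join(c.uncovered)}"
        out.append(msg)
    return out


def render_report(
    calls: Sequence[DiplotypeCall],
    phenotypes: Mapping[str, PhenotypeAssignment],
    kb: KnowledgeBase,
    format: str,
    gene_selection: Sequence[str] | None = None,
    drug_selection: Mapping[str, Sequence[str]] | None = None,
    *,
    sample_id: str,
    build: str,
    created: str | None = None,
) -> ReportDocument:
    """Assemble a report document for one sample.

    ``gene_selection`` defaults to every catalog gene; ``drug_selection``
    maps gene to the drugs to report (default: all drugs of that gene).  A
    drug not associated with its gene raises :class:`UnknownDrugError`
    listing the valid drugs.
    """
    if format not in REPORT_FORMATS:
        raise ValueError(f"format must be one of {REPORT_FORMATS}")
    genes = [kb.resolve_gene(g) for g in (gene_selection or kb.gene_order)]
    gene_drugs = kb.gene_drugs
    selected_drugs: dict[str, list[str]] = {}
    for gene in genes:
        wanted = list((drug_selection or {}).get(gene, gene_drugs[gene]))
        for d in wanted:
            if d not in gene_drugs[gene]:
                raise UnknownDrugError(
                    f"{d!r} is not a {gene} drug; valid drugs: "
                    f"{', '.join(gene_drugs[gene])}"
                )
        selected_drugs[gene] = wanted
    if format == "single_gene_drug":
        if len(genes) != 1 or len(selected_drugs[genes[0]]) != 1:
            raise ValueError(
                "single_gene_drug format requires exactly one gene and one drug"
            )

    calls_by_gene = {c.gene: c for c in calls}
    sel_calls = [calls_by_gene[g] for g in genes if g in calls_by_gene]
    rows: list[ReportRow] = []
    for gene in genes:
        call = calls_by_gene.get(gene)
        if call is None:
            continue
        phen = phenotypes.get(gene)
        if phen is None:
            continue
        if format == "summary":
            nt, aa = (
                _changes(kb, gene, call.allele_pair)
                if call.allele_pair
                else ("none", "none")
            )
            rows.append(
                ReportRow(
                    gene=gene,
                    drug=None,
                    genotype_alias=call.alias or "indeterminate",
                    nucleotide_change=nt,
                    aa_change=aa,
                    phenotype_category=phen.category or "indeterminate",
                )
            )
        else:
            for drug in selected_drugs[gene]:
                rows.append(_detail_row(kb, call, phen, drug))

    return ReportDocument(
        format=format,
        sample_id=sample_id,
        build=build,
        created=created or datetime.now(timezone.utc).isoformat(),
        catalog_version=kb.version,
        rows=rows,
        caveats=_caveats(sel_calls),
    )


# ---------------------------------------------------------------------------
# serialization


def _row_to_fields(row: ReportRow) -> list[str]:
    return [
        row.gene,
        row.drug or "",
        row.genotype_alias,
        row.nucleotide_change,
        row.aa_change,
        row.phenotype_category,
        row.interpretation or "",
        row.dosing_recommendation or "",
        "|".join(row.references),
    ]


def serialize_report(
    doc: ReportDocument, sink: str | Path, style: str = "text"
) -> None:
    """Write a report document as TSV, JSON, or a human-readable text layout."""
    if style not in SERIALIZATION_STYLES:
        raise ValueError(f"style must be one of {SERIALIZATION_STYLES}")
    sink = Path(sink)
    sink.parent.mkdir(parents=True, exist_ok=True)
    if style == "tsv":
        lines = ["\t".join(TSV_HEADER)]
        lines += ["\t".join(_row_to_fields(r)) for r in doc.rows]
        sink.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif style == "json":
        sink.write_text(report_to_json(doc), encoding="utf-8")
    else:
        sink.write_text(_render_text(doc), encoding="utf-8")


def report_to_json(doc: ReportDocument) -> str:
    return json.dumps(dataclasses.asdict(doc), indent=2, sort_keys=True) + "\n"


def report_from_json(text: str) -> ReportDocument:
    raw = json.loads(text)
    rows = [
        ReportRow(**{**r, "references": tuple(r["references"])})
        for r in raw.pop("rows")
    ]
    return ReportDocument(rows=rows, **raw)


def _render_text(doc: ReportDocument) -> str:
    lines = [
        "PGx report",
        f"  sample:  {doc.sample_id}",
        f"  build:   {doc.build}",
        f"  catalog: {doc.catalog_version}",
        f"  format:  {doc.format}",
        f"  created: {doc.created}",
        "",
    ]
    current_gene = None
    for row in doc.rows:
        if row.gene != current_gene:
            lines.append(f"== {row.gene} ==")
            current_gene = row.gene
        lines.append(f"  genotype:          {row.genotype_alias}")
        lines.append(f"  nucleotide change: {row.nucleotide_change}")
        lines.append(f"  amino acid change: {row.aa_change}")
        lines.append(f"  phenotype:         {row.phenotype_category}")
        if row.drug:
            lines.append(f"  drug:              {row.drug}")
        if row.interpretation:
            lines.append(f"  interpretation:    {row.interpretation}")
        if row.dosing_recommendation:
            lines.append(f"  recommendation:    {row.dosing_recommendation}")
        if row.references:
            lines.append(f"  references:        {'; '.join(row.references)}")
        lines.append("")
    if doc.caveats:
        lines.append("Caveats:")
        lines += [f"  - {c}" for c in doc.caveats]
        lines.append("")
    return "\n".join(lines)
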