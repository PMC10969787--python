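"""Concordance harness: compare calls against truth sets.

Two truth-set kinds are supported: per-sample per-gene *variant sets*
(exact set equality of catalog-locus variant keys, no partial credit) and
*consensus diplotypes* (normalized alias equality).  Discordance triage
tallies per-variant adjudications into five categories.

Percentages are reported at fixed precision: concordance to 2 decimals,
triage to 1 decimal (so a triage breakdown may total slightly off 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .knowledgebase import normalize_alias

log = logging.getLogger(__name__)

VariantKey = tuple[str, int, str, str]

TRUTH_KINDS = ("variant_sets", "consensus_diplotypes")

TRIAGE_CATEGORIES = (
    "caller_only_correct",
    "truth_only_correct",
    "both_correct",
    "neither_correct",
    "no_contig",
)


@dataclass
class TruthSet:
    """Per-sample truth: variant sets or consensus diplotypes per gene."""

    kind: str
    data: dict[str, dict[str, set[VariantKey] | str]]

    def __post_init__(self):
        if self.kind not in TRUTH_KINDS:
            raise ValueError(f"kind must be one of {TRUTH_KINDS}")

    @property
    def genes(self) -> set[str]:
        return {g for per_gene in self.data.values() for g in per_gene}


@dataclass(frozen=True)
class ConcordanceResult:
    gene: str
    n_samples: int
    n_concordant: int

    def __post_init__(self):
        if self.n_concordant > self.n_samples:
            raise ValueError("n_concordant cannot exceed n_samples")

    @property
    def percent(self) -> float:
        return round(100.0 * self.n_concordant / self.n_samples, 2)


@dataclass
class DiscordanceTriage:
    """Counts and 1-decimal percentages per adjudication category."""

    counts: dict[str, int]
    total: int = field(init=False)

    def __post_init__(self):
        unknown = set(self.counts) - set(TRIAGE_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown triage categories: {sorted(unknown)}")
        self.total = sum(self.counts.values())
        if self.total == 0:
            raise ValueError("no adjudications to triage")

    @property
    def percentages(self) -> dict[str, float]:
        return {
            cat: round(100.0 * self.counts.get(cat, 0) / self.total, 1)
            for cat in TRIAGE_CATEGORIES
        }


# ---------------------------------------------------------------------------
# operations


def sample_variant_concordant(
    called: set[VariantKey], truth: set[VariantKey]
) -> bool:
    """Exact set equality; two empty sets agree vacuously."""
    return called == truth


def concordance_table(
    cohort: Mapping[str, Mapping[str, set[VariantKey]]],
    truth: TruthSet,
) -> list[ConcordanceResult]:
    """Per-gene sample-level concordance over the shared sample ids."""
    if truth.kind != "variant_sets":
        raise ValueError("concordance_table needs a variant_sets truth set")
    shared = sorted(set(cohort) & set(truth.data))
    if not shared:
        raise ValueError("no overlapping sample ids between cohort and truth")
    genes = sorted(
        {g for s in shared for g in cohort[s]} | truth.genes
    )
    results = []
    for gene in genes:
        n_conc = sum(
            sample_variant_concordant(
                set(cohort[s].get(gene, set())),
                set(truth.data[s].get(gene, set())),
            )
            for s in shared
        )
        results.append(ConcordanceResult(gene, len(shared), n_conc))
    return results


def diplotype_concordance(
    calls: Mapping[str, Mapping[str, str]],
    truth: TruthSet,
) -> list[ConcordanceResult]:
    """Per-gene diplotype concordance; genes absent from the truth panel are
    skipped with a logged note (they cannot be adjudicated)."""
    if truth.kind != "consensus_diplotypes":
        raise ValueError(
            "diplotype_concordance needs a consensus_diplotypes truth set"
        )
    shared = sorted(set(calls) & set(truth.data))
    if not shared:
        raise ValueError("no overlapping sample ids between calls and truth")
    called_genes = sorted({g for s in shared for g in calls[s]})
    truth_genes = truth.genes
    skipped = [g for g in called_genes if g not in truth_genes]
    for g in skipped:
        log.info("%s not in the truth panel; skipped", g)
    results = []
    for gene in called_genes:
        if gene in skipped:
            continue
        n_conc = sum(
            gene in truth.data[s]
            and gene in calls[s]
            and normalize_alias(calls[s][gene])
            == normalize_alias(truth.data[s][gene])
            for s in shared
        )
        results.append(ConcordanceResult(gene, len(shared), n_conc))
    return results


def triage_discordances(labels: Sequence[str]) -> DiscordanceTriage:
    """Tally per-variant adjudications into the five triage categories."""
    if not labels:
        raise ValueError("no adjudications to triage")
    unknown = set(labels) - set(TRIAGE_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown triage categories: {sorted(unknown)}")
    counts = {cat: 0 for cat in TRIAGE_CATEGORIES}
    for lab in labels:
        counts[lab] += 1
    return DiscordanceTriage(counts)


# ---------------------------------------------------------------------------
# truth-set TSV I/O (columns: sample_id, gene, payload)


def _format_variant_key(k: VariantKey) -> str:
    return f"{k[0]}:{k[1]}:{k[2]}:{k[3]}"


def _parse_variant_key(s: str) -> VariantKey:
    chrom, pos, ref, alt = s.split(":")
    return (chrom, int(pos), ref, alt)


def write_truth_set(truth: TruthSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tgene\tpayload\n")
        for sample in sorted(truth.data):
            for gene in sorted(truth.data[sample]):
                value = truth.data[sample][gene]
                if truth.kind == "variant_sets":
                    payload = ";".join(
                        _format_variant_key(k)
                        for k in sorted(value)
                    )
                else:
                    payload = value
                fh.write(f"{sample}\t{gene}\t{payload}\n")


def load_truth_set(path: str | Path, kind: str) -> TruthSet:
    if kind not in TRUTH_KINDS:
        raise ValueError(f"kind must be one of {TRUTH_KINDS}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    data: dict[str, dict] = {}
    for _, row in df.iterrows():
        per_gene = data.setdefault(row["sample_id"], {})
        if kind == "variant_sets":
            payload = {
                _parse_variant_key(tok)
                for tok in row["payload"].split(";")
                if tok
            }
        else:
            payload = normalize_alias(row["payload"])
        per_gene[row["gene"]] = payload
    return TruthSet(kind=kind, data=data)
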