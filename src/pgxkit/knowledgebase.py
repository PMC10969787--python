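"""PGx knowledge base: gene catalog, star-allele definitions and diplotype rows.

The catalog is a UTF-8 TSV with one header row.  Two record types share the
same column set and are distinguished by ``record_type``:

* ``allele`` rows define star alleles.  One row per defining variant; the
  reference allele ``*1`` has a single row with empty variant fields and an
  empty defining-variant set.
* ``diplotype`` rows carry the clinical interpretation for one
  (gene, drug, diplotype) combination.  The interpretation text starts with a
  bracketed CPIC evidence strength, and by package convention its first
  sentence is the phenotype category (e.g. "Rapid metabolizer.").
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import CatalogValidationError, UnknownGeneError

log = logging.getLogger(__name__)

#: CPIC evidence strengths allowed in bracketed interpretation prefixes.
EVIDENCE_STRENGTHS = ("Strong", "Moderate", "Optional", "No recommendation")

#: The 13 pharmacogenes covered by the packaged catalog, in report order.
PANEL_GENES = (
    "COMT", "CYP2B6", "CYP2C9", "CYP2C19", "CYP2D6", "CYP3A5", "CYP4F2",
    "DPYD", "IL28B", "NUDT15", "SLCO1B1", "TPMT", "VKORC1",
)

#: Alternate symbols accepted for catalog genes (IL28B was renamed IFNL3).
GENE_ALIASES = {"IFNL3": "IL28B"}

GENOME_BUILDS = ("GRCh37", "GRCh38")

CATALOG_COLUMNS = [
    "gene", "drug", "genotype_alias", "genotype_code", "star_name", "rsid",
    "chrom", "pos_grch37", "pos_grch38", "ref", "alt", "cdna", "aa_change",
    "activity_value", "function_label", "tier", "variants_result",
    "interpretation", "dosing_recommendation", "references", "record_type",
]

_RSID_RE = re.compile(r"^rs\d+$")
_STAR_RE = re.compile(r"^\*(\d+)([A-Za-z0-9]*)$")
_INTERP_RE = re.compile(
    r"^\[(Strong|Moderate|Optional|No recommendation)\]\s*(.*)$", re.S
)


class _RecordNotFound:
    """Sentinel returned by :func:`lookup_record` for absent diplotypes."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "RECORD_NOT_FOUND"

    def __bool__(self) -> bool:
        return False


RECORD_NOT_FOUND = _RecordNotFound()


def star_sort_key(star_name: str) -> tuple:
    """Deterministic ordering key for star alleles.

    Numeric star value ascending, then lexicographic suffix (so *2 < *2A < *10).
    Names that do not look like star alleles sort after all star alleles.
    """
    m = _STAR_RE.match(star_name)
    if m:
        return (0, int(m.group(1)), m.group(2))
    return (1, 0, star_name)


def normalize_alias(alias: str) -> str:
    """Normalize a diplotype alias ``*a/*b`` to canonical allele order."""
    parts = [p.strip() for p in alias.split("/")]
    if len(parts) != 2 or not all(p.startswith("*") for p in parts):
        raise ValueError(f"not a diplotype alias: {alias!r}")
    parts.sort(key=star_sort_key)
    return "/".join(parts)


def parse_interpretation(text: str) -> tuple[str, str]:
    """Split an interpretation into (evidence strength, body)."""
    m = _INTERP_RE.match(text)
    if not m:
        raise ValueError(
            f"interpretation must start with a bracketed strength "
            f"{EVIDENCE_STRENGTHS}: {text!r}"
        )
    return m.group(1), m.group(2)


@dataclass(frozen=True)
class DefiningVariant:
    """One variant that (with others) defines a star allele.

    Positions are 1-based and may be present on either or both genome builds.
    """

    rsid: str
    chrom: str
    pos_grch37: int | None
    pos_grch38: int | None
    ref: str
    alt: str
    cdna: str = ""
    aa_change: str = "none"

    def __post_init__(self):
        if not _RSID_RE.match(self.rsid):
            raise CatalogValidationError(f"invalid rsid: {self.rsid!r}")
        if self.pos_grch37 is None and self.pos_grch38 is None:
            raise CatalogValidationError(
                f"{self.rsid}: needs a position on at least one build"
            )
        if self.ref == self.alt:
            raise CatalogValidationError(f"{self.rsid}: ref equals alt")

    def pos(self, build: str) -> int | None:
        return self.pos_grch37 if build == "GRCh37" else self.pos_grch38

    def key(self, build: str) -> tuple[str, int, str, str] | None:
        """(chrom, pos, ref, alt) on the given build, or None if unplaced."""
        p = self.pos(build)
        if p is None:
            return None
        return (self.chrom, p, self.ref, self.alt)


@dataclass(frozen=True)
class AlleleDefinition:
    """A star allele: a set of defining variants plus functional annotation."""

    gene: str
    star_name: str
    defining_variants: frozenset[DefiningVariant]
    activity_value: float | None = None
    function_label: str = ""
    tier: int = 1

    def __post_init__(self):
        if self.activity_value is not None and self.activity_value < 0:
            raise CatalogValidationError(
                f"{self.gene}{self.star_name}: negative activity value"
            )
        if self.tier not in (1, 2):
            raise CatalogValidationError(
                f"{self.gene}{self.star_name}: tier must be 1 or 2"
            )

    @property
    def rsids(self) -> frozenset[str]:
        return frozenset(v.rsid for v in self.defining_variants)

    def is_reference(self) -> bool:
        return not self.defining_variants


@dataclass(frozen=True)
class DiplotypeRecord:
    """One knowledge-base row: interpretation of a diplotype for one drug."""

    gene: str
    drug: str
    genotype_alias: str
    genotype_code: str
    variants_result: str
    interpretation: str
    dosing_recommendation: str
    references: tuple[str, ...] = ()

    def __post_init__(self):
        parse_interpretation(self.interpretation)  # raises if malformed
        object.__setattr__(
            self, "genotype_alias", normalize_alias(self.genotype_alias)
        )

    @property
    def strength(self) -> str:
        return parse_interpretation(self.interpretation)[0]

    @property
    def phenotype_category(self) -> str:
        """First sentence of the interpretation body (package convention)."""
        body = parse_interpretation(self.interpretation)[1]
        return body.split(".")[0].strip()


@dataclass
class KnowledgeBase:
    """Validated PGx catalog: alleles per gene plus diplotype records."""

    version: str
    genes: dict[str, tuple[AlleleDefinition, ...]]
    records: list[DiplotypeRecord]
    gene_aliases: dict[str, str] = field(default_factory=dict)

    @property
    def gene_order(self) -> tuple[str, ...]:
        return tuple(self.genes)

    @property
    def gene_drugs(self) -> dict[str, list[str]]:
        """Drugs per gene, in first-appearance order of the records."""
        out: dict[str, list[str]] = {g: [] for g in self.genes}
        for rec in self.records:
            if rec.drug not in out[rec.gene]:
                out[rec.gene].append(rec.drug)
        return out

    def resolve_gene(self, gene: str) -> str:
        gene = self.gene_aliases.get(gene, gene)
        if gene not in self.genes:
            raise UnknownGeneError(f"gene {gene!r} not in knowledge base")
        return gene

    def allele(self, gene: str, star_name: str) -> AlleleDefinition:
        from .errors import UnknownAlleleError

        gene = self.resolve_gene(gene)
        for a in self.genes[gene]:
            if a.star_name == star_name:
                return a
        raise UnknownAlleleError(f"{gene}{star_name} not in knowledge base")

    def gene_variants(self, gene: str) -> list[DefiningVariant]:
        """All distinct defining variants of a gene, stable order."""
        seen: dict[str, DefiningVariant] = {}
        for allele in self.genes[self.resolve_gene(gene)]:
            for v in sorted(allele.defining_variants, key=_variant_sort_key):
                seen.setdefault(v.rsid, v)
        return list(seen.values())

    def variant_index(self, build: str) -> dict[tuple, tuple[str, str]]:
        """Map (chrom,pos,ref,alt) on a build -> (gene, rsid)."""
        idx: dict[tuple, tuple[str, str]] = {}
        for gene in self.genes:
            for v in self.gene_variants(gene):
                k = v.key(build)
                if k is not None:
                    idx[k] = (gene, v.rsid)
        return idx


def _variant_sort_key(v: DefiningVariant):
    return (
        v.pos_grch38 if v.pos_grch38 is not None else 10**10,
        v.pos_grch37 if v.pos_grch37 is not None else 10**10,
        v.rsid,
    )


# ---------------------------------------------------------------------------
# loading / validation


def _opt_int(s: str) -> int | None:
    return int(s) if s != "" else None


def _opt_float(s: str) -> float | None:
    return float(s) if s != "" else None


def load_knowledgebase(
    path: str | Path, *, version: str | None = None, require_panel: bool = False
) -> KnowledgeBase:
    """Load and validate a knowledge-base TSV.

    ``require_panel`` additionally checks that the gene set equals the
    packaged 13-gene panel (used for the shipped catalog).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(df.columns) != CATALOG_COLUMNS:
        raise CatalogValidationError(
            f"{path}: columns must be exactly {CATALOG_COLUMNS}, "
            f"got {list(df.columns)}"
        )
    if df.empty:
        raise CatalogValidationError(f"{path}: no records")

    dup = df[df.duplicated(keep=False)]
    if not dup.empty:
        i = int(dup.index[0]) + 2  # 1-based file line incl. header
        raise CatalogValidationError(
            f"{path}: duplicate row at line {i}: "
            f"{dup.iloc[0]['gene']} {dup.iloc[0]['genotype_alias'] or dup.iloc[0]['star_name']}"
        )

    genes: dict[str, dict[str, list[DefiningVariant]]] = {}
    allele_meta: dict[tuple[str, str], dict] = {}
    records: list[DiplotypeRecord] = []

    for i, row in df.iterrows():
        line = int(i) + 2
        rtype = row["record_type"]
        if rtype == "allele":
            gene, star = row["gene"], row["star_name"]
            if not _STAR_RE.match(star):
                raise CatalogValidationError(
                    f"{path}:{line}: bad star name {star!r}"
                )
            genes.setdefault(gene, {}).setdefault(star, [])
            meta = allele_meta.setdefault(
                (gene, star),
                {
                    "activity_value": _opt_float(row["activity_value"]),
                    "function_label": row["function_label"],
                    "tier": int(row["tier"]) if row["tier"] else 1,
                },
            )
            if row["rsid"]:
                genes[gene][star].append(
                    DefiningVariant(
                        rsid=row["rsid"],
                        chrom=row["chrom"],
                        pos_grch37=_opt_int(row["pos_grch37"]),
                        pos_grch38=_opt_int(row["pos_grch38"]),
                        ref=row["ref"],
                        alt=row["alt"],
                        cdna=row["cdna"],
                        aa_change=row["aa_change"] or "none",
                    )
                )
            _ = meta
        elif rtype == "diplotype":
            try:
                rec = DiplotypeRecord(
                    gene=row["gene"],
                    drug=row["drug"],
                    genotype_alias=row["genotype_alias"],
                    genotype_code=row["genotype_code"],
                    variants_result=row["variants_result"],
                    interpretation=row["interpretation"],
                    dosing_recommendation=row["dosing_recommendation"],
                    references=tuple(
                        r for r in row["references"].split("|") if r
                    ),
                )
            except ValueError as e:
                raise CatalogValidationError(f"{path}:{line}: {e}") from e
            records.append(rec)
        else:
            raise CatalogValidationError(
                f"{path}:{line}: unknown record_type {rtype!r}"
            )

    allele_map: dict[str, tuple[AlleleDefinition, ...]] = {}
    for gene, stars in genes.items():
        defs = []
        for star in sorted(stars, key=star_sort_key):
            meta = allele_meta[(gene, star)]
            defs.append(
                AlleleDefinition(
                    gene=gene,
                    star_name=star,
                    defining_variants=frozenset(stars[star]),
                    **meta,
                )
            )
        allele_map[gene] = tuple(defs)

    kb = KnowledgeBase(
        version=version or path.stem,
        genes=allele_map,
        records=records,
        gene_aliases=dict(GENE_ALIASES),
    )
    validate_knowledgebase(kb, require_panel=require_panel)
    return kb


def validate_knowledgebase(kb: KnowledgeBase, *, require_panel: bool = False):
    """Check the cross-record invariants of a knowledge base."""
    if not kb.genes:
        raise CatalogValidationError("no allele definitions")
    for gene, alleles in kb.genes.items():
        names = [a.star_name for a in alleles]
        if len(names) != len(set(names)):
            raise CatalogValidationError(f"{gene}: duplicate star names")
        ref = [a for a in alleles if a.star_name == "*1"]
        if not ref:
            raise CatalogValidationError(f"{gene}: missing reference allele *1")
        if ref[0].defining_variants:
            raise CatalogValidationError(
                f"{gene}: *1 must have an empty defining-variant set"
            )
        sets = {}
        for a in alleles:
            key = frozenset(v.rsid for v in a.defining_variants)
            if key in sets:
                raise CatalogValidationError(
                    f"{gene}: alleles {sets[key]} and {a.star_name} have "
                    f"identical defining-variant sets"
                )
            sets[key] = a.star_name
    seen = set()
    for rec in kb.records:
        if rec.gene not in kb.genes:
            raise CatalogValidationError(
                f"diplotype record for unknown gene {rec.gene}"
            )
        key = (rec.gene, rec.drug, rec.genotype_alias)
        if key in seen:
            raise CatalogValidationError(f"duplicate diplotype record {key}")
        seen.add(key)
    if require_panel and set(kb.genes) != set(PANEL_GENES):
        raise CatalogValidationError(
            f"packaged catalog must contain exactly the genes {PANEL_GENES}"
        )


_PACKAGED_VERSION = "2024.1"


def packaged_catalog_path() -> Path:
    return Path(__file__).parent / "data" / "catalog.tsv"


def load_packaged_catalog() -> KnowledgeBase:
    """Load the catalog shipped with the package (13-gene panel)."""
    return load_knowledgebase(
        packaged_catalog_path(), version=_PACKAGED_VERSION, require_panel=True
    )


# ---------------------------------------------------------------------------
# queries


def lookup_record(
    kb: KnowledgeBase, gene: str, diplotype: str, drug: str
) -> DiplotypeRecord | _RecordNotFound:
    """Find the record for (gene, diplotype, drug); alias order-insensitive.

    Raises :class:`UnknownGeneError` for genes absent from the catalog, so an
    unknown gene is distinguishable from an uncatalogued diplotype.
    """
    gene = kb.resolve_gene(gene)
    alias = normalize_alias(diplotype)
    for rec in kb.records:
        if rec.gene == gene and rec.drug == drug and rec.genotype_alias == alias:
            return rec
    return RECORD_NOT_FOUND


def catalog_regions(
    kb: KnowledgeBase, build: str, *, margin: int = 0
) -> list[tuple[str, int, int]]:
    """One (chrom, start, end) region per gene spanning its defining variants.

    1-based inclusive coordinates, padded by ``margin``.  A gene whose
    variants lack positions on the requested build is omitted with a warning.
    """
    if build not in GENOME_BUILDS:
        raise ValueError(f"unknown build {build!r}")
    regions = []
    for gene in kb.genes:
        variants = kb.gene_variants(gene)
        if not variants:
            log.warning("%s: no defining variants; no region on %s", gene, build)
            continue
        positions = [v.pos(build) for v in variants]
        if any(p is None for p in positions):
            log.warning(
                "%s: defining variants lack %s positions; gene omitted",
                gene, build,
            )
            continue
        chroms = {v.chrom for v in variants}
        if len(chroms) != 1:
            raise CatalogValidationError(
                f"{gene}: defining variants on multiple chromosomes {chroms}"
            )
        start = max(1, min(positions) - margin)
        end = max(positions) + margin
        regions.append((chroms.pop(), start, end))
    if not regions:
        log.warning("no catalog regions available on %s", build)
    return regions


# ---------------------------------------------------------------------------
# serialization (canonical form; load→serialize round-trips byte-identically)


def _fmt_opt(x) -> str:
    return "" if x is None else str(x)


def serialize_knowledgebase(kb: KnowledgeBase, path: str | Path) -> None:
    """Write the knowledge base as a canonical TSV (stable row/field order)."""
    rows: list[dict[str, str]] = []
    empty = {c: "" for c in CATALOG_COLUMNS}

    for gene in kb.genes:
        for allele in sorted(kb.genes[gene], key=lambda a: star_sort_key(a.star_name)):
            base = dict(
                empty,
                record_type="allele",
                gene=gene,
                star_name=allele.star_name,
                activity_value=_fmt_opt(allele.activity_value),
                function_label=allele.function_label,
                tier=str(allele.tier),
            )
            variants = sorted(allele.defining_variants, key=_variant_sort_key)
            if not variants:
                rows.append(base)
            for v in variants:
                rows.append(
                    dict(
                        base,
                        rsid=v.rsid,
                        chrom=v.chrom,
                        pos_grch37=_fmt_opt(v.pos_grch37),
                        pos_grch38=_fmt_opt(v.pos_grch38),
                        ref=v.ref,
                        alt=v.alt,
                        cdna=v.cdna,
                        aa_change=v.aa_change,
                    )
                )

    drug_order = kb.gene_drugs
    for gene in kb.genes:
        recs = [r for r in kb.records if r.gene == gene]
        recs.sort(
            key=lambda r: (
                drug_order[gene].index(r.drug),
                [star_sort_key(p) for p in r.genotype_alias.split("/")],
            )
        )
        for rec in recs:
            rows.append(
                dict(
                    empty,
                    record_type="diplotype",
                    gene=rec.gene,
                    drug=rec.drug,
                    genotype_alias=rec.genotype_alias,
                    genotype_code=rec.genotype_code,
                    variants_result=rec.variants_result,
                    interpretation=rec.interpretation,
                    dosing_recommendation=rec.dosing_recommendation,
                    references="|".join(rec.references),
                )
            )

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(CATALOG_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(row[c] for c in CATALOG_COLUMNS) + "\n")
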