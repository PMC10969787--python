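"""Synthetic per-sample VCFs and truth sets for any catalog diplotype.

The generator realizes a chosen diplotype per gene as the exact set of
alternate-allele records implied by the union of the two alleles' defining
variants (dosage 2 where both alleles share a variant, else 1), written as a
standard VCF 4.2 file on the requested build.  Optional noise is applied
after construction:

* ``drop_rate`` — each record is deleted independently,
* ``spurious_rate`` — per catalog record, a non-catalog record is added at a
  random position inside a catalog region (so it stresses region filtering
  and catalog matching),
* ``nocall_rate`` — each record's GT is rewritten to ``./.``.

All randomness flows from a single ``random.Random(seed)`` threaded through
draws in a fixed order, so outputs are byte-identical across runs and
platforms.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .errors import UnknownAlleleError
from .knowledgebase import KnowledgeBase, catalog_regions, normalize_alias
from .concordance import TruthSet, VariantKey, write_truth_set

_BASES = "ACGT"


@dataclass(frozen=True)
class NoiseModel:
    drop_rate: float = 0.0
    spurious_rate: float = 0.0
    nocall_rate: float = 0.0

    def __post_init__(self):
        for name in ("drop_rate", "spurious_rate", "nocall_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic sample: diplotypes per gene plus noise."""

    sample_id: str
    build: str
    diplotypes: dict[str, str] = field(default_factory=dict)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0


@dataclass(frozen=True)
class EmittedRecord:
    chrom: str
    pos: int
    rsid: str
    ref: str
    alt: str
    gt: str
    origin: str  # catalog | spurious

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)


def _catalog_records(
    spec: FixtureSpec, kb: KnowledgeBase
) -> list[EmittedRecord]:
    records: list[EmittedRecord] = []
    for gene, alias in spec.diplotypes.items():
        gene = kb.resolve_gene(gene)
        a, b = normalize_alias(alias).split("/")
        try:
            alleles = (kb.allele(gene, a), kb.allele(gene, b))
        except UnknownAlleleError:
            raise
        dosage: dict[str, int] = {}
        variants = {}
        for allele in alleles:
            for v in allele.defining_variants:
                dosage[v.rsid] = dosage.get(v.rsid, 0) + 1
                variants[v.rsid] = v
        for rsid, d in dosage.items():
            v = variants[rsid]
            pos = v.pos(spec.build)
            if pos is None:
                raise ValueError(
                    f"{gene} {rsid} has no position on {spec.build}"
                )
            records.append(
                EmittedRecord(
                    chrom=v.chrom,
                    pos=pos,
                    rsid=rsid,
                    ref=v.ref,
                    alt=v.alt,
                    gt="1/1" if d == 2 else "0/1",
                    origin="catalog",
                )
            )
    return records


def _spurious_record(
    rng: random.Random,
    regions: Sequence[tuple[str, int, int]],
    taken: set[tuple[str, int]],
) -> EmittedRecord:
    while True:
        chrom, start, end = regions[rng.randrange(len(regions))]
        pos = rng.randint(start, end)
        if (chrom, pos) in taken:
            continue
        ref = _BASES[rng.randrange(4)]
        alt = rng.choice([b for b in _BASES if b != ref])
        return EmittedRecord(
            chrom=chrom, pos=pos, rsid=".", ref=ref, alt=alt,
            gt="0/1", origin="spurious",
        )


def generate_sample_vcf(
    spec: FixtureSpec, kb: KnowledgeBase, sink: str | Path
) -> list[EmittedRecord]:
    """Write the VCF realizing ``spec`` and return the emitted records.

    The returned manifest lists the records actually written (after noise),
    sorted by position — the ground truth for the written file.
    """
    rng = random.Random(spec.seed)
    records = _catalog_records(spec, kb)
    regions = catalog_regions(kb, spec.build, margin=500)
    taken = {(r.chrom, r.pos) for r in records}

    noise = spec.noise
    final: list[EmittedRecord] = []
    # fixed draw order per catalog record: drop, spurious, nocall
    for rec in sorted(records, key=lambda r: (r.chrom, r.pos, r.alt)):
        if noise.drop_rate and rng.random() < noise.drop_rate:
            continue
        if noise.spurious_rate and rng.random() < noise.spurious_rate:
            sp = _spurious_record(rng, regions, taken)
            taken.add((sp.chrom, sp.pos))
            final.append(sp)
        if noise.nocall_rate and rng.random() < noise.nocall_rate:
            rec = EmittedRecord(
                rec.chrom, rec.pos, rec.rsid, rec.ref, rec.alt, "./.",
                rec.origin,
            )
        final.append(rec)

    final.sort(key=lambda r: (_chrom_order(r.chrom), r.pos, r.alt))
    _write_vcf(final, spec, sink)
    return final


def _chrom_order(chrom: str) -> tuple[int, str]:
    return (0, f"{int(chrom):02d}") if chrom.isdigit() else (1, chrom)


def _write_vcf(
    records: Sequence[EmittedRecord], spec: FixtureSpec, sink: str | Path
) -> None:
    sink = Path(sink)
    sink.parent.mkdir(parents=True, exist_ok=True)
    contigs = sorted({r.chrom for r in records}, key=_chrom_order)
    lines = [
        "##fileformat=VCFv4.2",
        "##source=pgxkit-fixtures",
        f"##reference={spec.build}",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + spec.sample_id
    )
    for r in records:
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.rsid}\t{r.ref}\t{r.alt}\t.\tPASS\t.\tGT\t{r.gt}"
        )
    sink.write_text("\n".join(lines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# cohorts


@dataclass
class CohortManifest:
    specs: list[FixtureSpec]
    vcf_paths: list[Path]
    truth_variants_path: Path
    truth_diplotypes_path: Path


def sample_diplotype(
    rng: random.Random,
    kb: KnowledgeBase,
    gene: str,
    weights: Mapping[str, float] | None = None,
) -> str:
    """Draw one diplotype for a gene, uniformly or from an alias weight table."""
    if weights:
        aliases = sorted(weights, key=lambda a: normalize_alias(a))
        cum = [weights[a] for a in aliases]
        return normalize_alias(rng.choices(aliases, weights=cum, k=1)[0])
    stars = [a.star_name for a in kb.genes[gene]]
    a = stars[rng.randrange(len(stars))]
    b = stars[rng.randrange(len(stars))]
    return normalize_alias(f"{a}/{b}")


def generate_cohort(
    n: int,
    kb: KnowledgeBase,
    out_dir: str | Path,
    *,
    seed: int = 0,
    build: str = "GRCh38",
    noise: NoiseModel | None = None,
    weights: Mapping[str, Mapping[str, float]] | None = None,
) -> CohortManifest:
    """Generate ``n`` sample VCFs plus matching truth sets of both kinds.

    ``weights`` optionally maps gene -> {alias: weight} for the diplotype
    sampler; genes without a weight table are drawn uniformly over allele
    pairs.
    """
    if n < 1:
        raise ValueError("cohort size must be at least 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = random.Random(seed)
    noise = noise or NoiseModel()
    var_index = kb.variant_index(build)

    specs: list[FixtureSpec] = []
    vcf_paths: list[Path] = []
    truth_var: dict[str, dict[str, set[VariantKey]]] = {}
    truth_dip: dict[str, dict[str, str]] = {}

    for i in range(n):
        sample_id = f"SYN{i:04d}"
        diplotypes = {
            gene: sample_diplotype(
                rng, kb, gene, (weights or {}).get(gene)
            )
            for gene in kb.genes
        }
        spec = FixtureSpec(
            sample_id=sample_id,
            build=build,
            diplotypes=diplotypes,
            noise=noise,
            seed=rng.randrange(2**31),
        )
        vcf_path = out_dir / f"{sample_id}.vcf"
        generate_sample_vcf(spec, kb, vcf_path)
        specs.append(spec)
        vcf_paths.append(vcf_path)
        # truth reflects the intended (pre-noise) diplotypes
        truth_dip[sample_id] = dict(diplotypes)
        per_gene: dict[str, set[VariantKey]] = {}
        for rec in _catalog_records(spec, kb):
            gene, _ = var_index[rec.key]
            per_gene.setdefault(gene, set()).add(rec.key)
        for gene in kb.genes:
            per_gene.setdefault(gene, set())
        truth_var[sample_id] = per_gene

    tv_path = out_dir / "truth_variants.tsv"
    td_path = out_dir / "truth_diplotypes.tsv"
    write_truth_set(TruthSet("variant_sets", truth_var), tv_path)
    write_truth_set(TruthSet("consensus_diplotypes", truth_dip), td_path)
    return CohortManifest(specs, vcf_paths, tv_path, td_path)
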