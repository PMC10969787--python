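"""VCF input: region-restricted reading and projection onto catalog loci.

Coordinates are 1-based throughout (VCF convention); regions are 1-based
inclusive.  Contig names are normalized by stripping a leading ``chr`` so
that GRCh37-style (``22``) and GRCh38-style (``chr22``) files both match the
catalog.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import pysam

from .errors import VcfParseError
from .knowledgebase import KnowledgeBase

log = logging.getLogger(__name__)

GenotypeState = Literal["hom_ref", "het", "hom_alt", "no_call"]

_STATE_BY_DOSAGE = {0: "hom_ref", 1: "het", 2: "hom_alt"}


@dataclass(frozen=True)
class VariantCall:
    """One alternate allele observed (or genotyped ref) for one sample.

    ``dosage=None`` marks a record whose GT is missing (``./.``): the site
    was assayed but not callable, which must not be mistaken for hom-ref.
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    rsid: str | None
    dosage: int | None
    filter_pass: bool = True

    def __post_init__(self):
        if self.dosage not in (0, 1, 2, None):
            raise ValueError(f"dosage must be 0/1/2/None, got {self.dosage}")
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenotypeObservation:
    """Genotype state at one catalog locus, with its provenance."""

    state: GenotypeState
    source: Literal["observed", "assumed_ref"] = "observed"

    def __post_init__(self):
        if self.state == "no_call" and self.source != "observed":
            raise ValueError("no_call observations cannot be assumed_ref")


@dataclass
class SampleGenotypes:
    """One sample's genotype state at every catalog-defining locus."""

    sample_id: str
    build: str
    obs: dict[tuple[str, str], GenotypeObservation] = field(default_factory=dict)

    def state(self, gene: str, rsid: str) -> GenotypeState:
        return self.obs[(gene, rsid)].state

    def gene_states(self, gene: str) -> dict[str, GenotypeState]:
        return {
            rsid: o.state for (g, rsid), o in self.obs.items() if g == gene
        }


def normalize_contig(name: str) -> str:
    return name[3:] if name.lower().startswith("chr") else name


def _in_regions(
    chrom: str, pos: int, regions: Sequence[tuple[str, int, int]]
) -> bool:
    c = normalize_contig(chrom)
    return any(
        normalize_contig(rc) == c and start <= pos <= end
        for rc, start, end in regions
    )


def read_vcf(
    path: str | Path,
    regions: Sequence[tuple[str, int, int]],
    *,
    samples: Iterable[str] | None = None,
) -> list[VariantCall]:
    """Read VCF records overlapping ``regions`` into per-alt VariantCalls.

    Multi-allelic records are split into one call per alternate allele, with
    the dosage computed for that allele alone.  Records failing FILTER are
    returned with ``filter_pass=False``; downstream extraction decides
    whether to use them.
    """
    path = Path(path)
    wanted = set(samples) if samples is not None else None
    calls: list[VariantCall] = []
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as e:
        raise VcfParseError(f"{path}: cannot open VCF: {e}") from e
    n_header = str(vf.header).count("\n")
    rec_idx = 0
    with vf:
        it = iter(vf)
        while True:
            try:
                rec = next(it)
            except StopIteration:
                break
            except Exception as e:  # htslib parse failure
                raise VcfParseError(
                    f"{path}: unparseable VCF record near line "
                    f"{n_header + rec_idx + 1}: {e}"
                ) from e
            rec_idx += 1
            if rec.alts is None:
                continue
            if not _in_regions(rec.chrom, rec.pos, regions):
                continue
            filters = list(rec.filter.keys())
            filter_pass = not filters or filters == ["PASS"]
            rsid = rec.id if rec.id and rec.id.startswith("rs") else None
            chrom = normalize_contig(rec.chrom)
            for sample_id, sample in rec.samples.items():
                if wanted is not None and sample_id not in wanted:
                    continue
                gt = sample.get("GT")
                missing = gt is None or all(a is None for a in gt)
                for alt_idx, alt in enumerate(rec.alts, start=1):
                    dosage = (
                        None if missing
                        else sum(1 for a in gt if a == alt_idx)
                    )
                    calls.append(
                        VariantCall(
                            sample_id=sample_id,
                            chrom=chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            rsid=rsid,
                            dosage=dosage,
                            filter_pass=filter_pass,
                        )
                    )
    return calls


def extract_catalog_genotypes(
    calls: Sequence[VariantCall],
    kb: KnowledgeBase,
    build: str,
    sample_id: str,
    *,
    genotype_complete: bool = False,
    include_filtered: bool = False,
) -> SampleGenotypes:
    """Project a sample's calls onto genotype states at catalog loci.

    For a locus with no record in the VCF, ``genotype_complete=True`` means
    the file asserts genotypes everywhere (typical of WGS-derived genotyped
    VCFs), so absence is read as hom_ref (``assumed_ref``); otherwise the
    locus is a no-call.  A reference-allele mismatch between the VCF and the
    catalog at the same position is never silently accepted: it yields a
    warning and a no-call.
    """
    usable = [
        c for c in calls
        if c.sample_id == sample_id and (include_filtered or c.filter_pass)
    ]
    by_key = {c.key: c for c in usable}
    by_pos: dict[tuple[str, int], list[VariantCall]] = {}
    for c in usable:
        by_pos.setdefault((c.chrom, c.pos), []).append(c)
    by_rsid: dict[str, list[VariantCall]] = {}
    for c in usable:
        if c.rsid:
            by_rsid.setdefault(c.rsid, []).append(c)

    sg = SampleGenotypes(sample_id=sample_id, build=build)
    for gene in kb.genes:
        for v in kb.gene_variants(gene):
            key = v.key(build)
            obs = None
            if key is not None and key in by_key:
                d = by_key[key].dosage
                obs = GenotypeObservation(
                    "no_call" if d is None else _STATE_BY_DOSAGE[d]
                )
            elif key is not None and (v.chrom, key[1]) in by_pos:
                site = by_pos[(v.chrom, key[1])]
                if any(c.ref != v.ref for c in site):
                    log.warning(
                        "%s %s at %s:%d: VCF ref %s != catalog ref %s; "
                        "treating as no-call",
                        gene, v.rsid, v.chrom, key[1], site[0].ref, v.ref,
                    )
                    obs = GenotypeObservation("no_call")
                else:
                    # site genotyped, this alt not listed -> no alt copies
                    obs = GenotypeObservation("hom_ref")
            elif v.rsid in by_rsid:
                # positions differ (e.g. other build or liftover); match by rsid
                c = by_rsid[v.rsid][0]
                if (c.ref, c.alt) == (v.ref, v.alt):
                    log.info(
                        "%s %s matched by rsid at %s:%d (catalog pos %s)",
                        gene, v.rsid, c.chrom, c.pos, key and key[1],
                    )
                    obs = GenotypeObservation(
                        "no_call" if c.dosage is None
                        else _STATE_BY_DOSAGE[c.dosage]
                    )
            if obs is None:
                if genotype_complete:
                    obs = GenotypeObservation("hom_ref", source="assumed_ref")
                else:
                    obs = GenotypeObservation("no_call")
            sg.obs[(gene, v.rsid)] = obs
    return sg
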