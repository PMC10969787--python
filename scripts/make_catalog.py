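"""Regenerate the packaged knowledge-base TSV (src/pgxkit/data/catalog.tsv).

The catalog covers the 13-gene panel with clinically prominent star alleles,
dual-build (GRCh37/GRCh38) coordinates, CYP2D6 activity values, AMP-style
tiers, and one interpretation row per constructible diplotype for each gene's
primary drug (plus reference rows for the remaining drugs).  Allele content
is seeded from CPIC/PharmVar-published definitions; interpretation text is
illustrative clinical phrasing that follows the CPIC evidence-strength
bracket convention.

Run from the repository root:  python scripts/make_catalog.py
"""

from __future__ import annotations

import itertools
from pathlib import Path

from pgxkit.knowledgebase import (
    AlleleDefinition,
    DefiningVariant,
    DiplotypeRecord,
    KnowledgeBase,
    GENE_ALIASES,
    normalize_alias,
    serialize_knowledgebase,
    star_sort_key,
    validate_knowledgebase,
)

V = DefiningVariant

# rsid, chrom, pos37, pos38, ref, alt, cdna, aa_change
VARIANTS = {
    "rs4680":      V("rs4680", "22", 19951271, 19963748, "G", "A", "c.472G>A", "V158M"),
    "rs3745274":   V("rs3745274", "19", 41512841, 41006936, "G", "T", "c.516G>T", "Q172H"),
    "rs2279343":   V("rs2279343", "19", 41515263, 41009358, "A", "G", "c.785A>G", "K262R"),
    "rs1799853":   V("rs1799853", "10", 96702047, 94942290, "C", "T", "c.430C>T", "R144C"),
    "rs1057910":   V("rs1057910", "10", 96741053, 94981296, "A", "C", "c.1075A>C", "I359L"),
    "rs4244285":   V("rs4244285", "10", 96541616, 94781859, "G", "A", "c.681G>A", "P227P"),
    "rs4986893":   V("rs4986893", "10", 96540410, 94780653, "G", "A", "c.636G>A", "W212X"),
    "rs12248560":  V("rs12248560", "10", 96521657, 94761900, "C", "T", "c.-806C>T", "none"),
    "rs1065852":   V("rs1065852", "22", 42526694, 42130692, "G", "A", "c.100C>T", "P34S"),
    "rs1135840":   V("rs1135840", "22", 42522613, 42126611, "C", "G", "c.1457G>C", "S486T"),
    "rs3892097":   V("rs3892097", "22", 42524947, 42128945, "C", "T", "c.506-1G>A", "splice defect"),
    "rs28371725":  V("rs28371725", "22", 42523805, 42127803, "C", "T", "c.985+39G>A", "none"),
    "rs776746":    V("rs776746", "7", 99270539, 99672916, "T", "C", "c.219-237A>G", "splice defect"),
    "rs10264272":  V("rs10264272", "7", 99262835, 99665212, "C", "T", "c.624G>A", "splice defect"),
    "rs2108622":   V("rs2108622", "19", 15990431, 15879621, "C", "T", "c.1297G>A", "V433M"),
    "rs3918290":   V("rs3918290", "1", 97915614, 97450058, "C", "T", "c.1905+1G>A", "splice defect"),
    "rs55886062":  V("rs55886062", "1", 97981343, 97515839, "A", "C", "c.1679T>G", "I560S"),
    "rs12979860":  V("rs12979860", "19", 39738787, 39248147, "C", "T", "c.-3180C>T", "none"),
    "rs116855232": V("rs116855232", "13", 48619855, 48045719, "C", "T", "c.415C>T", "R139C"),
    "rs4149056":   V("rs4149056", "12", 21331549, 21178615, "T", "C", "c.521T>C", "V174A"),
    "rs1800462":   V("rs1800462", "6", 18143724, 18143493, "C", "G", "c.238G>C", "A80P"),
    "rs1800460":   V("rs1800460", "6", 18139228, 18138997, "C", "T", "c.460G>A", "A154T"),
    "rs1142345":   V("rs1142345", "6", 18130918, 18130687, "T", "C", "c.719A>G", "Y240C"),
    "rs9923231":   V("rs9923231", "16", 31107689, 31096368, "C", "T", "c.-1639G>A", "none"),
}

# gene -> star -> (rsids, activity_value, function_label, tier)
ALLELES = {
    "COMT": {
        "*1": ([], None, "normal activity", 1),
        "*2": (["rs4680"], None, "reduced activity (Met158)", 1),
    },
    "CYP2B6": {
        "*1": ([], None, "normal function", 1),
        "*6": (["rs3745274", "rs2279343"], None, "decreased function", 1),
        "*9": (["rs3745274"], None, "decreased function", 2),
    },
    "CYP2C9": {
        "*1": ([], None, "normal function", 1),
        "*2": (["rs1799853"], None, "decreased function", 1),
        "*3": (["rs1057910"], None, "no function", 1),
    },
    "CYP2C19": {
        "*1": ([], None, "normal function", 1),
        "*2": (["rs4244285"], None, "no function", 1),
        "*3": (["rs4986893"], None, "no function", 1),
        "*17": (["rs12248560"], None, "increased function", 1),
    },
    "CYP2D6": {
        "*1": ([], 1.0, "normal function", 1),
        "*4": (["rs1065852", "rs3892097"], 0.0, "no function", 1),
        "*10": (["rs1065852", "rs1135840"], 0.25, "decreased function", 1),
        "*41": (["rs28371725"], 0.5, "decreased function", 1),
    },
    "CYP3A5": {
        "*1": ([], None, "normal function (expresser)", 1),
        "*3": (["rs776746"], None, "no function", 1),
        "*6": (["rs10264272"], None, "no function", 2),
    },
    "CYP4F2": {
        "*1": ([], None, "normal function", 1),
        "*3": (["rs2108622"], None, "decreased function", 2),
    },
    "DPYD": {
        "*1": ([], None, "normal function", 1),
        "*2A": (["rs3918290"], None, "no function", 1),
        "*13": (["rs55886062"], None, "no function", 1),
    },
    "IL28B": {
        "*1": ([], None, "favorable response (C allele)", 1),
        "*2": (["rs12979860"], None, "unfavorable response (T allele)", 1),
    },
    "NUDT15": {
        "*1": ([], None, "normal function", 1),
        "*3": (["rs116855232"], None, "no function", 1),
    },
    "SLCO1B1": {
        "*1": ([], None, "normal function", 1),
        "*5": (["rs4149056"], None, "decreased function", 1),
    },
    "TPMT": {
        "*1": ([], None, "normal function", 1),
        "*2": (["rs1800462"], None, "no function", 1),
        "*3A": (["rs1800460", "rs1142345"], None, "no function", 1),
        "*3C": (["rs1142345"], None, "no function", 2),
    },
    "VKORC1": {
        "*1": ([], None, "normal warfarin sensitivity", 1),
        "*2": (["rs9923231"], None, "increased warfarin sensitivity", 1),
    },
}

# gene -> (primary drug, other drugs)
DRUGS = {
    "COMT": ("Opioid", []),
    "CYP2B6": ("Efavirenz", []),
    "CYP2C9": ("Warfarin", []),
    "CYP2C19": (
        "Clopidogrel",
        ["Omeprazole", "Lansoprazole", "Pantoprazole", "Dexlansoprazole",
         "Citalopram", "Escitalopram", "Sertraline", "Amitriptyline",
         "Clomipramine", "Doxepin", "Imipramine", "Trimipramine",
         "Voriconazole"],
    ),
    "CYP2D6": (
        "Codeine",
        ["Tramadol", "Hydrocodone", "Ondansetron", "Tropisetron",
         "Paroxetine", "Fluvoxamine", "Atomoxetine", "Amitriptyline",
         "Nortriptyline", "Tamoxifen"],
    ),
    "CYP3A5": ("Tacrolimus", []),
    "CYP4F2": ("Warfarin", []),
    "DPYD": ("5-Fluorouracil", ["Capecitabine"]),
    "IL28B": ("PEG Interferon-alpha", []),
    "NUDT15": ("Thiopurine", []),
    "SLCO1B1": ("Simvastatin", []),
    "TPMT": ("Thioguanine", ["Mercaptopurine", "Azathioprine"]),
    "VKORC1": ("Warfarin", []),
}


def cyp2d6_category(score: float) -> str:
    if score == 0:
        return "Poor metabolizer"
    if score < 1.25:
        return "Intermediate metabolizer"
    if score <= 2.25:
        return "Normal metabolizer"
    return "Ultrarapid metabolizer"


def metabolizer_by_defect(n_no_function: int, n_decreased: int) -> str:
    """Generic metabolizer bin from counts of defective alleles."""
    if n_no_function == 2:
        return "Poor metabolizer"
    if n_no_function + n_decreased == 2:
        if n_no_function == 1:
            return "Poor metabolizer"
        return "Intermediate metabolizer"
    if n_no_function + n_decreased == 1:
        return "Intermediate metabolizer"
    return "Normal metabolizer"


def categorize(gene: str, a: str, b: str) -> str:
    """Phenotype category text for one diplotype."""
    funcs = [ALLELES[gene][s][2] for s in (a, b)]
    n_no = sum(f.startswith("no function") for f in funcs)
    n_dec = sum(f.startswith("decreased") for f in funcs)
    if gene == "CYP2D6":
        return cyp2d6_category(sum(ALLELES[gene][s][1] for s in (a, b)))
    if gene == "CYP2C19":
        inc = sum(s == "*17" for s in (a, b))
        if inc == 2:
            return "Ultrarapid metabolizer"
        if inc == 1 and n_no == 0:
            return "Rapid metabolizer"
        if inc == 1:  # *2/*17, *3/*17
            return "Intermediate metabolizer"
        return metabolizer_by_defect(n_no, n_dec)
    if gene == "COMT":
        n = sum(s == "*2" for s in (a, b))
        return ["Normal COMT activity", "Intermediate COMT activity",
                "Low COMT activity"][n]
    if gene == "CYP3A5":
        if n_no == 2:
            return "Poor metabolizer (CYP3A5 non-expresser)"
        if n_no == 1:
            return "Intermediate metabolizer (CYP3A5 expresser)"
        return "Normal metabolizer (CYP3A5 expresser)"
    if gene == "CYP4F2":
        n = sum(s == "*3" for s in (a, b))
        return ["Normal CYP4F2 activity", "Decreased CYP4F2 activity",
                "Low CYP4F2 activity"][n]
    if gene == "IL28B":
        n = sum(s == "*2" for s in (a, b))
        return ["Favorable response genotype (CC)",
                "Unfavorable response genotype (CT)",
                "Unfavorable response genotype (TT)"][n]
    if gene == "SLCO1B1":
        n = sum(s == "*5" for s in (a, b))
        return ["Normal function", "Decreased function", "Poor function"][n]
    if gene == "VKORC1":
        n = sum(s == "*2" for s in (a, b))
        return ["Normal warfarin sensitivity", "Increased warfarin sensitivity",
                "Greatly increased warfarin sensitivity"][n]
    # CYP2B6, CYP2C9, DPYD, NUDT15, TPMT: count defective alleles
    if n_no == 1 and n_dec == 1:
        return "Poor metabolizer"
    if n_no == 2:
        return "Poor metabolizer"
    if n_no == 1 or n_dec == 2:
        return "Intermediate metabolizer" if n_dec == 2 else "Intermediate metabolizer"
    if n_dec == 1:
        return "Intermediate metabolizer"
    return "Normal metabolizer"


STRENGTH_BY_GENE = {
    # COMT-opioid evidence is weak; CYP4F2's warfarin contribution is optional.
    "COMT": "No recommendation",
    "CYP4F2": "Optional",
}


def strength_for(gene: str, category: str) -> str:
    if gene in STRENGTH_BY_GENE:
        return STRENGTH_BY_GENE[gene]
    lowered = category.lower()
    if any(w in lowered for w in ("poor", "ultrarapid", "greatly")):
        return "Strong"
    if any(w in lowered for w in ("intermediate", "rapid", "decreased",
                                  "unfavorable", "increased", "low")):
        return "Moderate"
    return "Strong"


DOSING = {
    "Normal": "Use standard dosing per drug label.",
    "Rapid": "Use standard dosing; monitor for reduced exposure to substrates.",
    "Ultrarapid": "Avoid standard dosing; select an alternative agent or adjust dose with therapeutic monitoring.",
    "Intermediate": "Consider a dose reduction or an alternative agent; monitor response.",
    "Poor": "Avoid the drug or use a substantially reduced dose with close monitoring.",
    "Other": "Interpret in the context of the gene-specific guideline; adjust therapy accordingly.",
}


def dosing_for(category: str) -> str:
    for key in ("Ultrarapid", "Rapid", "Poor", "Intermediate", "Normal"):
        if category.startswith(key):
            return DOSING[key]
    return DOSING["Other"]


def variants_result(gene: str, a: str, b: str) -> str:
    parts = []
    for star in sorted({a, b}, key=star_sort_key):
        rsids = ALLELES[gene][star][0]
        if not rsids:
            continue
        zyg = "hom" if a == b else "het"
        for r in rsids:
            parts.append(f"{VARIANTS[r].cdna} ({r}) {zyg}")
    return "; ".join(parts) or "no catalog variants detected"


def explanation(gene: str, a: str, b: str, category: str) -> str:
    funcs = sorted(ALLELES[gene][s][2] for s in (a, b))
    if gene == "CYP2D6":
        score = sum(ALLELES[gene][s][1] for s in (a, b))
        return (f"Diplotype {a}/{b} has an activity score of {score:g} "
                f"({' + '.join(f'{ALLELES[gene][s][1]:g}' for s in sorted((a, b), key=star_sort_key))}).")
    return f"Diplotype {a}/{b} combines alleles with {funcs[0]} and {funcs[1]}."


def build() -> KnowledgeBase:
    genes = {}
    for gene, stars in ALLELES.items():
        defs = []
        for star in sorted(stars, key=star_sort_key):
            rsids, act, func, tier = stars[star]
            defs.append(AlleleDefinition(
                gene=gene,
                star_name=star,
                defining_variants=frozenset(VARIANTS[r] for r in rsids),
                activity_value=act,
                function_label=func,
                tier=tier,
            ))
        genes[gene] = tuple(defs)

    records = []
    for gene, stars in ALLELES.items():
        primary, others = DRUGS[gene]
        names = sorted(stars, key=star_sort_key)
        for a, b in itertools.combinations_with_replacement(names, 2):
            alias = normalize_alias(f"{a}/{b}")
            cat = categorize(gene, a, b)
            strength = strength_for(gene, cat)
            records.append(DiplotypeRecord(
                gene=gene,
                drug=primary,
                genotype_alias=alias,
                genotype_code=f"{gene}-{a.lstrip('*')}-{b.lstrip('*')}",
                variants_result=variants_result(gene, a, b),
                interpretation=f"[{strength}] {cat}. {explanation(gene, a, b, cat)}",
                dosing_recommendation=dosing_for(cat),
                references=(f"CPIC guideline for {primary} and {gene}",),
            ))
        for drug in others:
            cat = categorize(gene, "*1", "*1")
            records.append(DiplotypeRecord(
                gene=gene,
                drug=drug,
                genotype_alias="*1/*1",
                genotype_code=f"{gene}-1-1",
                variants_result=variants_result(gene, "*1", "*1"),
                interpretation=(f"[{strength_for(gene, cat)}] {cat}. "
                                f"{explanation(gene, '*1', '*1', cat)}"),
                dosing_recommendation=dosing_for(cat),
                references=(f"CPIC guideline for {drug} and {gene}",),
            ))

    kb = KnowledgeBase(version="2024.1", genes=genes, records=records,
                       gene_aliases=dict(GENE_ALIASES))
    validate_knowledgebase(kb, require_panel=True)
    return kb


if __name__ == "__main__":
    out = Path(__file__).resolve().parents[1] / "src" / "pgxkit" / "data" / "catalog.tsv"
    serialize_knowledgebase(build(), out)
    print(f"wrote {out}")
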