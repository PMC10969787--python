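# Methods

## Scope and data flow

`pgxkit` performs tertiary PGx analysis only: its entry point is a VCF of
per-sample variant calls. Alignment and variant calling (BAM/CRAM secondary
analysis) are upstream of the package; an external caller can be slotted in
front of `read_vcf` as an extension point. The stages are:

1. `knowledgebase` — load and validate the catalog (genes, star-allele
   definitions with dual-build coordinates, diplotype interpretation rows).
2. `variant_io` — read VCF records overlapping per-gene catalog regions and
   project each sample onto genotype states at catalog loci.
3. `diplotype_caller` — enumerate unordered allele pairs and select the
   best dosage-consistent candidate.
4. `phenotype_engine` — activity score (CYP2D6) or table lookup.
5. `reporting` — single-gene-drug, summary, or full report documents.
6. `concordance` / `fixtures` — validation harness and synthetic data.

## The matching model and its assumptions

Matching is **unphased and dosage-based**: a pair of alleles is consistent
when the number of the two alleles containing each observed locus equals the
observed alternate dosage there. This assumes (a) the input VCF's genotypes
are diploid and bi-allelic per split record, (b) star alleles are fully
characterized by the catalog's defining SNVs, and (c) phase is unavailable —
standard for short-read germline VCFs. Consequences:

- Distinct diplotypes with identical dosage profiles (classic example:
  TPMT \*1/\*3A versus \*3B/\*3C) cannot be separated without phase. The
  caller surfaces such cases as `ambiguous` with all candidates listed; it
  never picks silently. The packaged catalog is curated so that every
  constructible diplotype has a unique dosage profile (see below).
- No-call loci only remove constraints, so degrading input can widen the
  candidate set or downgrade quality, but never flips a fully observed call
  to a different exact diplotype (tested property).

Candidate ranking is (1) maximize observed alt-bearing loci explained — a
no-op among strictly consistent candidates, kept for forward compatibility
with partial matching; (2) minimize the number of non-reference alleles
(parsimony, so \*1/\*2 beats exotic multi-variant pairs when both fit);
(3) numeric-aware lexicographic order of the normalized alias. Determinism
of the full pipeline is a hard requirement for a clinical report and is
tested at byte level.

Call quality: `exact` = single candidate, all its defining loci observed;
`ambiguous` = several candidates; `incomplete` = the chosen pair relies on
an unobserved locus; `no_call` = every defining locus of every
non-reference allele is unobserved; `unresolved` = no pair fits (reported,
never raised).

## Genotype extraction semantics

- Coordinates are 1-based; regions 1-based inclusive. Contig names are
  normalized by stripping a leading `chr`, since GRCh37- and GRCh38-era
  files differ in convention.
- A **genotype-complete** flag states whether absence of a record implies
  hom-ref (WGS-derived genotyped VCFs) or a no-call (sparse/targeted call
  sets). An explicit `./.` genotype is always a no-call, even under the
  flag — a site asserted untypeable must not become assumed-ref. For this
  the internal `VariantCall.dosage` admits `None` ("assayed, not callable")
  alongside 0/1/2.
- A reference-allele mismatch between VCF and catalog at the same position
  is a warning plus no-call, never silent acceptance. If a record's
  position differs from the catalog but its rsID, ref and alt agree, the
  rsID match is used and logged (tolerates coordinate slippage between
  annotation releases).
- Records failing FILTER are excluded from extraction by default
  (conservative clinical posture); `include_filtered=True` overrides.

## Phenotype translation

CYP2D6 uses the activity-score system with the current consensus cut-offs:
poor at exactly 0, intermediate on the open interval (0, 1.25), normal on
the closed interval [1.25, 2.25], ultrarapid strictly above 2.25. The
reference allele \*1 carries activity 1.0 (standard convention); \*10
carries 0.25 under the revised consensus, so \*10/\*10 scores 0.5 —
an intermediate metabolizer. The score path is generic: any gene whose
alleles all carry activity values can opt in via `activity_genes`.

All other genes resolve by table lookup. CYP2C19 \*1/\*17 is fixed to
*Rapid metabolizer* (guidelines disagree historically; the rapid designation
follows the pharmacokinetic evidence, and CPIC dosing for normal and rapid
metabolizers coincides, so the choice does not alter recommendations);
\*17/\*17 remains *Ultrarapid*. By package convention the interpretation
body's first sentence is the phenotype category, so the category is always
recoverable from a record without a separate column.

## The packaged catalog

Content is data, not code: a TSV with one `record_type=allele` row per
defining variant (both GRCh37 and GRCh38 positions) and one
`record_type=diplotype` row per (gene, drug, diplotype). Allele definitions
are seeded from CPIC/PharmVar-published content for clinically prominent
alleles; interpretation and dosing text is illustrative clinical phrasing
following the CPIC bracketed-strength convention. Structural invariants are
enforced at load time: \*1 present per gene with an empty defining set, no
two alleles of a gene with identical defining sets, unique
(gene, drug, alias) rows, four-class evidence strengths. Loading and
re-serializing the packaged file is byte-identical (canonical row order).

Catalog-content choices worth noting:

- TPMT ships \*2, \*3A and \*3C but not \*3B (\*3A's other component
  variant alone), keeping every constructible diplotype uniquely
  identifiable from unphased dosages. \*3B is rare in isolation; a site
  deploying it can add the allele row and accept the documented ambiguity.
- IL28B is carried under that symbol with an `IFNL3` alias accepted on
  input. Its rs12979860 haplotype is encoded as pseudo-allele \*2 so the
  gene fits the star-allele machinery.
- CYP2D6 structural variants (\*5 deletion, hybrids, xN duplications) are
  out of scope; the caller is SNV-only by design.

## Synthetic data

`fixtures` realizes any catalog diplotype as the exact record set implied by
the union of the two alleles' defining variants (GT `1/1` where shared,
`0/1` otherwise) in a standard VCF 4.2. Noise models three artifact classes:
dropped records (missing alignments), spurious non-catalog records inside
catalog regions (stresses region filtering and matching; records outside
regions would be invisible by construction), and `./.` rewrites. A single
`random.Random(seed)` is threaded through all draws in a fixed order, so
cohorts are byte-reproducible across platforms.

What the generator does **not** emulate: read-level errors, coverage
gradients and ambiguous contigs (the dominant real-world failure mode around
CYP2D6), multi-allelic records, indels, phased genotypes, or reference-build
liftover artifacts. Passing the round-trip suite therefore demonstrates the
correctness of the catalog → caller → phenotype chain, not robustness to
alignment-level noise.

## Concordance harness

Sample-level variant concordance is exact set equality of catalog-locus
variant keys per gene (no partial credit); diplotype concordance is
normalized-alias equality. Genes absent from a truth panel are skipped with
a note rather than scored. Percentages are recomputed from counts at fixed
precision — 2 decimals for concordance, 1 decimal for triage — so a
five-way triage breakdown may total 99.9 due to rounding. Triage categories:
caller-only correct, truth-only correct, both, neither, no contig.

## Numerical and problem-size choices

- Activity-score bin edges are compared with exact floating-point equality
  at the stated boundaries (0, 1.25, 2.25); scores are sums of catalog
  values with at most two decimals, so no tolerance is needed.
- The oracle-equivalence suite runs 1000 randomized single-gene catalogs
  (≤ 8 alleles over ≤ 6 loci) against brute-force enumeration, plus a
  derandomized property-based layer; the round-trip suite covers all
  constructible catalog diplotypes on alternating builds. Both complete in
  seconds at these sizes while exhausting the combinatorics that matter
  (nested, overlapping and disjoint defining sets).
- Ties in ranking cannot occur between distinct parsimony counts; the final
  alias tie-break makes the remaining order total.

## Known limitations

- SNV-only calling: no CNVs, hybrids, HLA typing, or variants lacking rsIDs.
- Phenotype rows exist for diplotypes constructible from the packaged
  alleles; uncatalogued (gene, drug, diplotype) combinations report as
  indeterminate rather than guessed.
- Drug–drug interaction phenoconversion is out of scope.
- The knowledge base is amended manually; there is no automated
  synchronization with CPIC/PharmVar releases.
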