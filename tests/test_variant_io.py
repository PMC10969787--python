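"""VCF reading, region restriction and catalog genotype extraction."""

import pytest

from pgxkit.errors import VcfParseError
from pgxkit.variant_io import (
    GenotypeObservation,
    VariantCall,
    extract_catalog_genotypes,
    normalize_contig,
    read_vcf,
)

VCF_HEADER = """\
##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=10>
##contig=<ID=22>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1
"""


def write_vcf(tmp_path, body, header=VCF_HEADER, name="toy.vcf"):
    p = tmp_path / name
    p.write_text(header + body)
    return p


REGION = [("10", 100, 200)]


class TestReadVcf:
    def test_region_filter(self, tmp_path):
        p = write_vcf(
            tmp_path,
            "10\t150\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\n"
            "10\t160\trs2\tC\tT\t.\tPASS\t.\tGT\t1/1\n"
            "10\t500\trs3\tC\tT\t.\tPASS\t.\tGT\t0/1\n",
        )
        calls = read_vcf(p, REGION)
        assert [c.pos for c in calls] == [150, 160]

    def test_region_filter_idempotent(self, tmp_path):
        p = write_vcf(tmp_path, "10\t150\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\n")
        once = read_vcf(p, REGION)
        # filtering already-filtered calls changes nothing
        kept = [c for c in once if ("10", 100, 200) and 100 <= c.pos <= 200]
        assert kept == once

    def test_multiallelic_split_each_dosage_one(self, tmp_path):
        p = write_vcf(tmp_path, "10\t150\trs1\tG\tA,C\t.\tPASS\t.\tGT\t1/2\n")
        calls = read_vcf(p, REGION)
        assert [(c.alt, c.dosage) for c in calls] == [("A", 1), ("C", 1)]

    @pytest.mark.parametrize(
        "gt, total",
        [("0/1", 1), ("1/1", 2), ("1/2", 2), ("0/2", 1), ("2/2", 2), ("0/0", 0)],
    )
    def test_split_conserves_total_alt_dosage(self, tmp_path, gt, total):
        p = write_vcf(tmp_path, f"10\t150\trs1\tG\tA,C\t.\tPASS\t.\tGT\t{gt}\n")
        calls = read_vcf(p, REGION)
        assert sum(c.dosage for c in calls) == total

    def test_truncated_record_names_line(self, tmp_path):
        p = write_vcf(tmp_path, "10\t150\trs1\n")
        with pytest.raises(VcfParseError, match="line"):
            read_vcf(p, REGION)

    def test_chr_prefix_normalized(self, tmp_path):
        header = VCF_HEADER.replace("<ID=10>", "<ID=chr10>")
        p = write_vcf(tmp_path, "chr10\t150\trs1\tG\tA\t.\tPASS\t.\tGT\t0/1\n",
                      header=header)
        calls = read_vcf(p, REGION)
        assert len(calls) == 1 and calls[0].chrom == "10"

    def test_filter_fail_flagged_not_dropped(self, tmp_path):
        header = VCF_HEADER.replace(
            "##contig=<ID=10>", '##FILTER=<ID=q10,Description="low">\n##contig=<ID=10>'
        )
        p = write_vcf(tmp_path, "10\t150\trs1\tG\tA\t.\tq10\t.\tGT\t0/1\n",
                      header=header)
        calls = read_vcf(p, REGION)
        assert len(calls) == 1 and not calls[0].filter_pass

    def test_missing_genotype_carried_as_none_dosage(self, tmp_path):
        p = write_vcf(tmp_path, "10\t150\trs1\tG\tA\t.\tPASS\t.\tGT\t./.\n")
        calls = read_vcf(p, REGION)
        assert len(calls) == 1 and calls[0].dosage is None


class TestVariantCall:
    def test_dosage_validated(self):
        with pytest.raises(ValueError):
            VariantCall("S", "1", 10, "A", "G", None, dosage=3)

    def test_nocall_observation_cannot_be_assumed(self):
        with pytest.raises(ValueError):
            GenotypeObservation("no_call", source="assumed_ref")


class TestExtraction:
    def test_genotype_complete_all_hom_ref(self, kb):
        sg = extract_catalog_genotypes([], kb, "GRCh38", "S1",
                                       genotype_complete=True)
        assert all(o.state == "hom_ref" and o.source == "assumed_ref"
                   for o in sg.obs.values())

    def test_sparse_vcf_gives_no_call(self, kb):
        sg = extract_catalog_genotypes([], kb, "GRCh38", "S1",
                                       genotype_complete=False)
        assert all(o.state == "no_call" for o in sg.obs.values())

    def test_het_call_at_cyp2c19_star2_locus(self, kb):
        call = VariantCall("S1", "10", 94781859, "G", "A", "rs4244285", 1)
        sg = extract_catalog_genotypes([call], kb, "GRCh38", "S1",
                                       genotype_complete=True)
        assert sg.state("CYP2C19", "rs4244285") == "het"
        others = [o for k, o in sg.obs.items() if k != ("CYP2C19", "rs4244285")]
        assert all(o.state == "hom_ref" for o in others)

    def test_ref_mismatch_warns_and_no_calls(self, kb, caplog):
        call = VariantCall("S1", "10", 94781859, "T", "A", "rs4244285", 1)
        with caplog.at_level("WARNING"):
            sg = extract_catalog_genotypes([call], kb, "GRCh38", "S1",
                                           genotype_complete=True)
        assert sg.state("CYP2C19", "rs4244285") == "no_call"
        assert any("ref" in r.message for r in caplog.records)

    def test_rsid_fallback_when_position_differs(self, kb, caplog):
        # GRCh37 coordinate presented while extracting on GRCh38
        call = VariantCall("S1", "10", 96541616, "G", "A", "rs4244285", 2)
        with caplog.at_level("INFO"):
            sg = extract_catalog_genotypes([call], kb, "GRCh38", "S1",
                                           genotype_complete=True)
        assert sg.state("CYP2C19", "rs4244285") == "hom_alt"
        assert any("matched by rsid" in r.message for r in caplog.records)

    def test_filtered_calls_excluded_by_default(self, kb):
        call = VariantCall("S1", "10", 94781859, "G", "A", "rs4244285", 1,
                           filter_pass=False)
        sg = extract_catalog_genotypes([call], kb, "GRCh38", "S1",
                                       genotype_complete=True)
        assert sg.state("CYP2C19", "rs4244285") == "hom_ref"
        sg2 = extract_catalog_genotypes([call], kb, "GRCh38", "S1",
                                        genotype_complete=True,
                                        include_filtered=True)
        assert sg2.state("CYP2C19", "rs4244285") == "het"

    def test_missing_genotype_record_is_no_call_even_when_complete(self, kb):
        call = VariantCall("S1", "10", 94781859, "G", "A", "rs4244285", None)
        sg = extract_catalog_genotypes([call], kb, "GRCh38", "S1",
                                       genotype_complete=True)
        assert sg.state("CYP2C19", "rs4244285") == "no_call"

    def test_dosage_zero_record_is_observed_hom_ref(self, kb):
        call = VariantCall("S1", "10", 94781859, "G", "A", "rs4244285", 0)
        sg = extract_catalog_genotypes([call], kb, "GRCh38", "S1",
                                       genotype_complete=False)
        obs = sg.obs[("CYP2C19", "rs4244285")]
        assert obs.state == "hom_ref" and obs.source == "observed"


def test_normalize_contig():
    assert normalize_contig("chr22") == "22"
    assert normalize_contig("22") == "22"
    assert normalize_contig("chrX") == "X"
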