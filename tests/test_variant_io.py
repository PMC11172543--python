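"""Input parsing, validation and round-trip behaviour."""

import warnings

import numpy as np
import pytest

from burdenscan.variant_io import (
    MISSING,
    GenotypeMatrix,
    Locus,
    VariantIOError,
    read_annotations,
    read_constraint,
    read_genotypes,
    read_passport,
    write_genotypes,
)

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "##contig=<ID=1H>\n"
)


def _write_vcf(tmp_path, body, samples=("A",)):
    path = tmp_path / "g.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + body)
    return path


class TestReadGenotypes:
    def test_single_homozygous_alt_call(self, tmp_path):
        path = _write_vcf(tmp_path, "1H\t100\t.\tA\tG\t.\t.\t.\tGT\t1/1\n")
        m = read_genotypes(path)
        assert m.dosage.tolist() == [[2]]
        assert m.loci == [Locus("1H", 100, "A", "G")]

    def test_gt_to_dosage_map_including_missing_and_phased(self, tmp_path):
        # enumerated by hand: 0/0 -> 0, 0/1 -> 1, ./. -> MISSING, 1/1 -> 2,
        # and phased separators behave identically to unphased
        body = "1H\t100\t.\tA\tG\t.\t.\t.\tGT\t0/0\t0|1\t./.\t1|1\n"
        path = _write_vcf(tmp_path, body, samples=("A", "B", "C", "D"))
        m = read_genotypes(path)
        assert m.dosage[:, 0].tolist() == [0, 1, MISSING, 2]

    def test_multiallelic_record_is_an_error_by_default(self, tmp_path):
        body = "1H\t100\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
        path = _write_vcf(tmp_path, body)
        with pytest.raises(VariantIOError, match="1H:100"):
            read_genotypes(path)

    def test_skip_nonbiallelic_downgrades_to_warning(self, tmp_path):
        body = (
            "1H\t100\t.\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
            "1H\t200\t.\tC\tT\t.\t.\t.\tGT\t1/1\n"
        )
        path = _write_vcf(tmp_path, body)
        with pytest.warns(UserWarning, match="skipped"):
            m = read_genotypes(path, skip_nonbiallelic=True)
        assert [loc.pos for loc in m.loci] == [200]

    def test_roundtrip_preserves_matrix(self, small_bundle, tmp_path):
        _, bundle = small_bundle
        out = tmp_path / "rt.vcf"
        write_genotypes(bundle.genotypes, out)
        assert read_genotypes(out) == bundle.genotypes

    def test_dosage_codes_partition_samples(self, small_bundle):
        _, bundle = small_bundle
        d = bundle.genotypes.dosage
        counts = sum((d == v).sum(axis=0) for v in (0, 1, 2, MISSING))
        assert (counts == bundle.genotypes.n_samples).all()


class TestLocusValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="1H", pos=0, ref="A", alt="G"),
            dict(chrom="1H", pos=5, ref="A", alt="A"),
            dict(chrom="1H", pos=5, ref="AT", alt="G"),
        ],
    )
    def test_invalid_loci_rejected(self, kwargs):
        with pytest.raises(VariantIOError):
            Locus(**kwargs)

    def test_matrix_rejects_out_of_range_dosage(self):
        loci = [Locus("1H", 1, "A", "G")]
        with pytest.raises(VariantIOError, match="invalid dosage"):
            GenotypeMatrix(["A"], loci, np.array([[3]]))


ANNOTATION_FIXTURE = """Location\tAllele\tGene\tFeature\tConsequence\tCANONICAL\tSIFT
1H:100\tG\tG1\tG1.1\tmissense_variant\tYES\tdeleterious(0.01)
1H:200\tT\tG2\tG2.1\tmissense_variant\t-\ttolerated(0.3)
2H:50\tA\tG3\tG3.1\tsynonymous_variant\tYES\t-
2H:60\tC\tG4\tG4.1\tintron_variant\t-\t-
3H:10\tG\tG5\tG5.2\tmissense_variant\t-\tdeleterious_low_confidence(0.04)
"""


class TestReadAnnotations:
    def test_five_row_fixture_parses_field_by_field(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(ANNOTATION_FIXTURE)
        recs = read_annotations(path)
        assert len(recs) == 5
        first = recs[0]
        assert first.locus_key == ("1H", 100, "G")
        assert first.sift_class == "deleterious"
        assert first.sift_score == 0.01
        assert first.canonical
        assert recs[1].canonical is False
        assert recs[2].sift_score is None and recs[2].sift_class is None
        assert recs[4].transcript_id == "G5.2"

    def test_malformed_sift_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "Location\tAllele\tGene\tFeature\tConsequence\tCANONICAL\tSIFT\n"
            "1H:1\tG\tG1\tG1.1\tmissense_variant\tYES\tdeleterious[0.01]\n"
        )
        with pytest.raises(VariantIOError, match="line 2"):
            read_annotations(path)

    def test_unknown_consequence_maps_to_other_with_warning(self, tmp_path):
        path = tmp_path / "odd.tsv"
        path.write_text(
            "Location\tAllele\tGene\tFeature\tConsequence\tCANONICAL\tSIFT\n"
            "1H:1\tG\tG1\tG1.1\tfrobnication_variant\tYES\t-\n"
        )
        with pytest.warns(UserWarning, match="frobnication"):
            recs = read_annotations(path)
        assert recs[0].consequence == "other"


class TestConstraintAndPassport:
    def test_lookup_hit_and_miss(self, tmp_path):
        path = tmp_path / "rs.tsv"
        path.write_text("chrom\tpos\tscore\n1H\t100\t1.5\n")
        track = read_constraint(path)
        assert track.get("1H", 100) == 1.5
        assert track.get("1H", 101) is None

    def test_conflicting_duplicate_scores_rejected(self, tmp_path):
        path = tmp_path / "rs.tsv"
        path.write_text("chrom\tpos\tscore\n1H\t100\t1.5\n1H\t100\t2.0\n")
        with pytest.raises(VariantIOError, match="conflicting"):
            read_constraint(path)

    def test_region_filled_from_country_mapping(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text(
            "sample,panel,material_type,growth_habit,row_type,country,region,core_flag\n"
            "S1,P,Landrace,Spring,Two-rowed,Ethiopia,,Core\n"
        )
        table = read_passport(path, country_to_region={"Ethiopia": "Ethiopian Centre"})
        assert table.get("S1")["region"] == "Ethiopian Centre"

    def test_grouped_counts_from_fixture(self, tmp_path):
        path = tmp_path / "p.csv"
        rows = ["sample,country,region"]
        for i, region in enumerate(["A"] * 4 + ["B"] * 2):
            rows.append(f"S{i},X,{region}")
        path.write_text("\n".join(rows) + "\n")
        table = read_passport(path)
        labels = table.labels([f"S{i}" for i in range(6)], "region")
        assert {r: labels.count(r) for r in set(labels)} == {"A": 4, "B": 2}

    def test_passport_sample_missing_from_genotypes_warns_but_keeps(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("sample,country\nS1,X\nS2,Y\n")
        with pytest.warns(UserWarning, match="S2"):
            table = read_passport(path, genotyped_samples=["S1"])
        assert table.get("S2") is not None
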