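import numpy as np
import pytest

from diploidalign import (
    Reference,
    Variant,
    Zygosity,
    apply_variants,
    build_truth_diploid,
    diploid_align,
)
from diploidalign.io import (
    parse_variants_tsv,
    parse_variants_vcf,
    write_variants_tsv,
    write_variants_vcf,
)

from conftest import (
    HET,
    HOM,
    INVARIANCE_DONOR,
    INVARIANCE_ENCODING_A,
    INVARIANCE_ENCODING_B,
    INVARIANCE_REFERENCE,
    WORKED_HAPLOID_ALL,
    WORKED_REFERENCE,
)


class TestApplyVariants:
    def test_worked_example_single_haploid(self, worked_variants):
        """All five calls are mutually compatible, so one haploid carries them all."""
        res = apply_variants(Reference("P", WORKED_REFERENCE), worked_variants)
        assert res.haploids == [WORKED_HAPLOID_ALL]
        assert res.skipped == []
        assert len(res.applied[0]) == 5

    @pytest.mark.parametrize(
        "variants", [INVARIANCE_ENCODING_A, INVARIANCE_ENCODING_B]
    )
    def test_invariance_encodings_agree(self, variants):
        """Two different indel encodings of the same donor produce one genome."""
        res = apply_variants(Reference("P", INVARIANCE_REFERENCE), variants)
        assert res.haploids == [INVARIANCE_DONOR]

    def test_empty_variant_list_echoes_reference(self):
        res = apply_variants(Reference("r", "ACGTACGT"), [])
        assert res.haploids == ["ACGTACGT"]

    def test_anchor_trimmed_variants_are_compatible(self):
        # after prefix trimming these occupy [1,2) and [2,3): no conflict
        res = apply_variants(
            Reference("r", "AAAA"),
            [Variant(1, "A", "C", HET), Variant(1, "AA", "A", HET)],
        )
        assert res.haploids == ["ACA"]

    def test_conflicting_het_calls_split_into_haploids(self):
        res = apply_variants(
            Reference("r", "AAAA"),
            [Variant(1, "A", "C", HET), Variant(1, "A", "G", HET)],
        )
        assert res.haploids == ["ACAA", "AGAA"]

    def test_extra_haploids_receive_homozygous_calls(self):
        res = apply_variants(
            Reference("r", "AAAAAA"),
            [
                Variant(1, "A", "C", HET),
                Variant(1, "A", "G", HET),
                Variant(4, "A", "T", HOM),
            ],
        )
        assert res.haploids == ["ACAATA", "AGAATA"]

    def test_unplaceable_homozygous_call_is_skipped(self):
        res = apply_variants(
            Reference("r", "AAAA"),
            [Variant(1, "A", "C", HOM), Variant(1, "A", "G", HOM)],
        )
        assert res.haploids == ["ACAA"]
        assert len(res.skipped) == 1

    def test_ref_mismatch_names_position(self):
        with pytest.raises(ValueError, match="position 2"):
            apply_variants(Reference("r", "AAAA"), [Variant(2, "G", "C", HOM)])

    def test_out_of_range_position(self):
        with pytest.raises(ValueError, match="past the reference end"):
            apply_variants(Reference("r", "AAAA"), [Variant(3, "AA", "A", HOM)])


class TestBuildTruthDiploid:
    def test_worked_example_reproduces_printed_alignment(self, worked_variants):
        truth = build_truth_diploid(Reference("P", WORKED_REFERENCE), worked_variants)
        assert truth.allele1.sequence == "ACCTGATCACG"
        assert truth.allele1.mapping.tolist() == [0, 1, 2, 3, 4, 5, 6, 6, 7, 7, 8]
        assert truth.allele2.sequence == "ACCTGCTACC"
        assert truth.allele2.mapping.tolist() == [0, 1, 2, 3, 4, 5, 6, 7, 7, 8]

    def test_empty_variants_give_reference_alleles(self):
        truth = build_truth_diploid(Reference("r", "ACGT"), [])
        for allele in (truth.allele1, truth.allele2):
            assert allele.sequence == "ACGT"
            assert (np.diff(allele.mapping) > 0).all()

    def test_homozygous_deletion(self):
        truth = build_truth_diploid(Reference("r", "ACG"), [Variant(0, "AC", "A", HOM)])
        for allele in (truth.allele1, truth.allele2):
            assert allele.sequence == "AG"
            assert allele.mapping.tolist() == [0, 2]

    def test_unphased_het_goes_to_allele1(self):
        truth = build_truth_diploid(Reference("r", "ACGT"), [Variant(1, "C", "T", HET)])
        assert truth.allele1.sequence == "ATGT"
        assert truth.allele2.sequence == "ACGT"

    def test_overlap_on_same_allele_is_an_error(self):
        with pytest.raises(ValueError, match="overlap"):
            build_truth_diploid(
                Reference("r", "ACGT"),
                [Variant(1, "CG", "C", HOM), Variant(2, "G", "T", HOM)],
            )

    def test_roundtrip_distance_zero_for_separated_variants(self, worked_variants):
        """Feeding the truth variants back as predictions scores zero."""
        ref = Reference("P", WORKED_REFERENCE)
        truth = build_truth_diploid(ref, worked_variants)
        res = apply_variants(ref, worked_variants)
        for hap in res.haploids:
            assert diploid_align(
                hap, truth.allele1, truth.allele2, ref.length
            ).distance == 0


class TestParsing:
    def test_tsv_rows(self):
        variants = parse_variants_tsv("3\tC\tCC\thet\n0\tA\tT\thom\n5\tG\t.\thet2\n")
        assert variants[0] == Variant(3, "C", "CC", HET)
        assert variants[1] == Variant(0, "A", "T", HOM)
        assert variants[2] == Variant(5, "G", "", HET, allele=2)

    def test_tsv_error_carries_line_number(self):
        with pytest.raises(ValueError, match="line 2"):
            parse_variants_tsv("0\tA\tT\thom\nnot-a-position\tA\tT\thom\n")
        with pytest.raises(ValueError, match="zygosity"):
            parse_variants_tsv("0\tA\tT\tmaybe\n")

    def test_vcf_round_trip(self, tmp_path, worked_variants):
        path = tmp_path / "truth.vcf"
        write_variants_vcf(path, worked_variants, Reference("P", WORKED_REFERENCE))
        parsed = parse_variants_vcf(path)
        assert len(parsed) == len(worked_variants)
        ref = Reference("P", WORKED_REFERENCE)
        original = build_truth_diploid(ref, worked_variants)
        rebuilt = build_truth_diploid(ref, parsed)
        assert rebuilt.allele1.sequence == original.allele1.sequence
        assert rebuilt.allele2.sequence == original.allele2.sequence

    def test_vcf_fields_and_genotypes(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=ref,length=10>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "ref\t1\t.\tA\tT\t.\t.\t.\tGT\t1/1\n"
            "ref\t4\t.\tC\tG\t.\t.\t.\tGT\t0/1\n"
        )
        path = tmp_path / "calls.vcf"
        path.write_text(text)
        v1, v2 = parse_variants_vcf(path)
        assert v1 == Variant(0, "A", "T", HOM)
        assert v2 == Variant(3, "C", "G", HET)

    def test_vcf_multiallelic_split(self, tmp_path):
        text = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=ref,length=10>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "ref\t2\t.\tA\tT,G\t.\t.\t.\tGT\t1/2\n"
        )
        path = tmp_path / "multi.vcf"
        path.write_text(text)
        parsed = parse_variants_vcf(path)
        assert parsed == [
            Variant(1, "A", "T", HET),
            Variant(1, "A", "G", HET),
        ]
        # the two conflicting heterozygous alts go to different haploids
        res = apply_variants(Reference("ref", "AAAAAAAAAA"), parsed)
        assert sorted(res.haploids) == ["AGAAAAAAAA", "ATAAAAAAAA"]

    def test_tsv_round_trip(self, tmp_path, worked_variants):
        path = tmp_path / "v.tsv"
        write_variants_tsv(path, worked_variants)
        parsed = parse_variants_tsv(path.read_text())
        assert parsed == worked_variants
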