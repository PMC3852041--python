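import random

import edlib
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from diploidalign import (
    align_to_diploid,
    diploid_align,
    levenshtein,
    nonoverlap_shortcut,
)
from diploidalign.oracle import random_instance

from conftest import INVARIANCE_DONOR, WORKED_HAPLOID, WORKED_HAPLOID_ALL, make_allele

dna = st.text(alphabet="ACGT", max_size=12)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "x, y, d",
        [("ACGT", "ACGT", 0), ("", "ACGT", 4), ("ACGT", "AGT", 1), ("", "", 0)],
    )
    def test_examples(self, x, y, d):
        assert levenshtein(x, y) == d

    @settings(derandomize=True, max_examples=100)
    @given(dna, dna)
    def test_matches_edlib(self, x, y):
        if not x or not y:
            assert levenshtein(x, y) == max(len(x), len(y))
        else:
            assert levenshtein(x, y) == edlib.align(x, y, task="distance")["editDistance"]


class TestDiploidAlign:
    def test_worked_example_scores_zero(self, worked_truth):
        """The printed haploid aligns to the printed diploid with no errors,
        even though it matches neither allele alone."""
        b1, b2, n = worked_truth
        res = diploid_align(WORKED_HAPLOID, b1, b2, n)
        assert res.distance == 0
        assert res.distance == min(res.per_matrix_final)
        assert levenshtein(WORKED_HAPLOID, b1.sequence) > 0
        assert levenshtein(WORKED_HAPLOID, b2.sequence) > 0

    def test_literal_application_also_scores_zero(self, worked_truth):
        b1, b2, n = worked_truth
        assert diploid_align(WORKED_HAPLOID_ALL, b1, b2, n).distance == 0

    def test_invariance_donor_scores_zero(self, invariance_truth):
        b1, b2, n = invariance_truth
        assert diploid_align(INVARIANCE_DONOR, b1, b2, n).distance == 0

    def test_empty_haploid_equals_allele_length(self):
        allele = make_allele("ACG", [0, 1, 2])
        assert diploid_align("", allele, allele, 3).distance == 3

    def test_degenerates_to_levenshtein_when_alleles_identical(self):
        rng = random.Random(11)
        for _ in range(60):
            _, b1, _, n = random_instance(rng)
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, n + 3)))
            assert diploid_align(a, b1, b1, n).distance == levenshtein(a, b1.sequence)

    def test_allele_symmetry(self):
        rng = random.Random(12)
        for _ in range(60):
            a, b1, b2, n = random_instance(rng)
            assert (
                diploid_align(a, b1, b2, n).distance
                == diploid_align(a, b2, b1, n).distance
            )

    def test_upper_bounded_by_single_allele_distances(self):
        rng = random.Random(13)
        for _ in range(60):
            a, b1, b2, n = random_instance(rng)
            d = diploid_align(a, b1, b2, n).distance
            assert d <= min(levenshtein(a, b1.sequence), levenshtein(a, b2.sequence))

    def test_rejects_invalid_mapping(self):
        bad = make_allele("AC", [1, 0])
        good = make_allele("AC", [0, 1])
        with pytest.raises(ValueError, match="decreases"):
            diploid_align("AC", bad, good, 2)

    def test_column_values_adjacent_within_one(self, worked_truth):
        """Within any DP column, neighbouring cells differ by at most 1."""
        b1, b2, n = worked_truth
        res = diploid_align(WORKED_HAPLOID, b1, b2, n, record_columns=True)
        for matrix in res.columns:
            for column in matrix:
                assert (column >= 0).all()
                if len(column) > 1:
                    assert (np.abs(np.diff(column)) <= 1).all()


class TestNonoverlapShortcut:
    def test_disjoint_alleles_concatenate(self):
        b1 = make_allele("AC", [0, 1])
        b2 = make_allele("GT", [2, 3])
        res = nonoverlap_shortcut("ACGT", b1, b2)
        assert res is not None and res.distance == 0
        assert res.cutoff_used == "shortcut"

    def test_overlapping_alleles_not_applicable(self):
        assert (
            nonoverlap_shortcut("AC", make_allele("AC", [0, 1]), make_allele("GT", [1, 2]))
            is None
        )

    def test_reverse_order_concatenation(self):
        b2 = make_allele("AC", [0, 1])
        b1 = make_allele("GT", [2, 3])
        res = nonoverlap_shortcut("ACG", b1, b2)
        assert res is not None and res.distance == 1

    def test_entry_point_uses_shortcut(self):
        b1 = make_allele("AC", [0, 1])
        b2 = make_allele("GT", [2, 3])
        res = align_to_diploid("ACGT", b1, b2, 4)
        assert res.cutoff_used == "shortcut" and res.distance == 0


class TestEntryPoint:
    @pytest.mark.parametrize("engine", ["full", "doubling"])
    def test_engines_agree_on_worked_example(self, worked_truth, engine):
        b1, b2, n = worked_truth
        assert align_to_diploid(WORKED_HAPLOID, b1, b2, n, engine=engine).distance == 0

    def test_unknown_engine_rejected(self, worked_truth):
        b1, b2, n = worked_truth
        with pytest.raises(ValueError, match="unknown engine"):
            align_to_diploid("A", b1, b2, n, engine="quantum")
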