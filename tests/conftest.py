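import numpy as np
import pytest

from diploidalign import (
    Allele,
    Reference,
    Variant,
    Zygosity,
    derive_mappings,
)

HET, HOM = Zygosity.HETEROZYGOUS, Zygosity.HOMOZYGOUS

# the running example: reference AGCTGATAC mutated into a diploid by one
# homozygous and three heterozygous substitutions/insertions plus one
# homozygous insertion, printed as a three-row multiple alignment
WORKED_P_ROW = "AGCTGAT-A-C"
WORKED_B1_ROW = "ACCTGATCACG"
WORKED_B2_ROW = "ACCTGCT-ACC"
WORKED_REFERENCE = "AGCTGATAC"
WORKED_HAPLOID = "ACCTGCTCACC"  # as printed alongside the alignment
# applying all five variants literally also realises the final substitution
WORKED_HAPLOID_ALL = "ACCTGCTCACG"


@pytest.fixture(scope="session")
def worked_truth() -> tuple[Allele, Allele, int]:
    b1, b2 = derive_mappings(WORKED_P_ROW, WORKED_B1_ROW, WORKED_B2_ROW)
    return b1, b2, len(WORKED_REFERENCE)


@pytest.fixture(scope="session")
def worked_variants() -> list[Variant]:
    return [
        Variant(1, "G", "C", HOM),
        Variant(5, "A", "C", HET, allele=2),
        Variant(6, "T", "TC", HET, allele=1),
        Variant(7, "A", "AC", HOM),
        Variant(8, "C", "G", HET, allele=1),
    ]


# the indel-invariance example: two different variant encodings against
# GATCAATGAG that both produce the donor genome GTCCCATAAG
INVARIANCE_REFERENCE = "GATCAATGAG"
INVARIANCE_DONOR = "GTCCCATAAG"
INVARIANCE_ENCODING_B = [
    Variant(0, "GA", "G"),
    Variant(3, "C", "CC"),
    Variant(4, "A", "C"),
    Variant(7, "G", "A"),
]
INVARIANCE_ENCODING_A = [
    Variant(1, "A", "T"),
    Variant(2, "T", "C"),
    Variant(3, "C", "CC"),
    Variant(3, "CA", "C"),
    Variant(7, "G", "A"),
]


@pytest.fixture(scope="session")
def invariance_truth() -> tuple[Allele, Allele, int]:
    """The invariance example's single diploid: both alleles equal the donor."""
    b, _ = derive_mappings("GATC-AATGAG", "G-TCCCATAAG", "G-TCCCATAAG")
    return b, Allele(b.sequence, b.mapping.copy()), len(INVARIANCE_REFERENCE)


def make_allele(sequence: str, mapping: list[int]) -> Allele:
    return Allele(sequence, np.array(mapping, dtype=np.int64))
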