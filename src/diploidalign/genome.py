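"""Core domain types: reference sequence, alleles with mapping tables, diploid truth.

A diploid truth consists of two allele sequences ``B1`` and ``B2`` derived from a
reference ``P`` by substitutions, insertions and deletions.  Each allele carries a
*mapping table*: for every character of the allele, the 0-based reference position
it is aligned to.  Substituted characters keep their reference position, inserted
characters repeat the reference position of the nearest preceding
reference-aligned character of the same row, and deleted reference positions are
simply skipped.  Mapping tables are therefore non-decreasing integer arrays
bounded by the reference length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GAP = "-"
#: gap characters accepted on input; normalised to '-'
_GAP_CHARS = {"-", "."}


def _normalise_seq(seq: str) -> str:
    return seq.upper()


@dataclass(frozen=True)
class Reference:
    """A reference (consensus) DNA sequence.

    Characters are uppercased on construction.  ``N`` is an ordinary symbol:
    it matches only another ``N`` (plain character equality is used throughout).
    """

    id: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalise_seq(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Allele:
    """One truth haplotype: a sequence plus its per-character reference mapping."""

    sequence: str
    mapping: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalise_seq(self.sequence))
        m = np.asarray(self.mapping, dtype=np.int64)
        object.__setattr__(self, "mapping", m)
        if len(self.sequence) != len(m):
            raise ValueError(
                f"sequence length {len(self.sequence)} != mapping length {len(m)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DiploidTruth:
    """A truth diploid: two alleles against a common reference."""

    reference_id: str
    allele1: Allele
    allele2: Allele
    reference_length: int

    def validate(self) -> None:
        for name, allele in (("allele1", self.allele1), ("allele2", self.allele2)):
            verdict = validate_allele(allele, self.reference_length)
            if not verdict.valid:
                raise ValueError(f"{name}: {verdict.reason}")


@dataclass(frozen=True)
class ValidityVerdict:
    valid: bool
    reason: str = ""
    index: int | None = None

    def __bool__(self) -> bool:
        return self.valid


def validate_allele(allele: Allele, reference_length: int) -> ValidityVerdict:
    """Check the Allele invariants, returning the first violation found.

    Checks: mapping length equals sequence length (enforced at construction),
    entries within ``[0, reference_length)`` and non-decreasing.
    """
    m = allele.mapping
    if len(m) == 0:
        return ValidityVerdict(True)
    lo = int(m.min())
    hi = int(m.max())
    if lo < 0:
        idx = int(np.argmax(m < 0))
        return ValidityVerdict(False, f"mapping value {m[idx]} < 0 at index {idx}", idx)
    if hi >= reference_length:
        idx = int(np.argmax(m >= reference_length))
        return ValidityVerdict(
            False,
            f"mapping value {m[idx]} at index {idx} exceeds reference length "
            f"{reference_length}",
            idx,
        )
    diffs = np.diff(m)
    if len(diffs) and diffs.min() < 0:
        idx = int(np.argmax(diffs < 0)) + 1
        return ValidityVerdict(False, f"mapping decreases at index {idx}", idx)
    return ValidityVerdict(True)


def derive_mappings(
    p_row: str, b1_row: str, b2_row: str
) -> tuple[Allele, Allele]:
    """Derive allele mapping tables from a 3-row gapped alignment (P, B1, B2).

    Each allele character in a column where the reference row has a character
    maps to that reference position; characters in insertion columns (reference
    row gapped) map to the position of the nearest preceding reference-aligned
    column.  Insertions before the first reference character are rejected.
    """
    rows = [p_row, b1_row, b2_row]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("alignment rows must have equal length")
    p_row, b1_row, b2_row = (_normalise_seq(r) for r in rows)

    alleles: list[Allele] = []
    for b_row in (b1_row, b2_row):
        chars: list[str] = []
        mapping: list[int] = []
        ref_pos = -1  # position of the last reference-aligned column seen
        for col, (pc, bc) in enumerate(zip(p_row, b_row)):
            p_gap = pc in _GAP_CHARS
            b_gap = bc in _GAP_CHARS
            if not p_gap:
                ref_pos += 1
            if b_gap:
                continue
            if p_gap and ref_pos < 0:
                raise ValueError(
                    f"insertion before the first reference character "
                    f"(column {col}) is unsupported"
                )
            chars.append(bc)
            mapping.append(ref_pos)
        alleles.append(Allele("".join(chars), np.array(mapping, dtype=np.int64)))
    return alleles[0], alleles[1]


def project_alignment(
    reference: Reference, allele1: Allele, allele2: Allele
) -> tuple[str, str, str]:
    """Project a diploid back to three gapped alignment rows (P, B1, B2).

    Inverse of :func:`derive_mappings` up to column placement of insertions:
    each allele's insertion run after reference position ``j`` is emitted in its
    own columns (allele 1's run first), so two homozygous insertions occupy
    separate columns rather than one shared column.  ``derive_mappings`` on the
    result reproduces the input mapping tables exactly.
    """
    for allele in (allele1, allele2):
        verdict = validate_allele(allele, reference.length)
        if not verdict.valid:
            raise ValueError(verdict.reason)
    p_out: list[str] = []
    b_out = [[], []]  # type: list[list[str]]
    cursors = [0, 0]
    alleles = (allele1, allele2)

    def emit(column_chars: list[str | None]) -> None:
        p_out.append(column_chars[0] or GAP)
        b_out[0].append(column_chars[1] or GAP)
        b_out[1].append(column_chars[2] or GAP)

    for j in range(reference.length):
        # reference-aligned column: allele char present iff it maps to j here
        col: list[str | None] = [reference.sequence[j], None, None]
        for a_i, allele in enumerate(alleles):
            c = cursors[a_i]
            if c < len(allele) and allele.mapping[c] == j:
                col[a_i + 1] = allele.sequence[c]
                cursors[a_i] = c + 1
        emit(col)
        # insertion columns: remaining chars still mapping to j
        for a_i, allele in enumerate(alleles):
            while cursors[a_i] < len(allele) and allele.mapping[cursors[a_i]] == j:
                col = [None, None, None]
                col[a_i + 1] = allele.sequence[cursors[a_i]]
                cursors[a_i] += 1
                emit(col)
    return "".join(p_out), "".join(b_out[0]), "".join(b_out[1])


def mapping_to_tsv(allele_id: str, allele: Allele) -> str:
    """Serialise a mapping table as one integer per line, preceded by an id header."""
    lines = [allele_id]
    lines.extend(str(int(v)) for v in allele.mapping)
    return "\n".join(lines) + "\n"


def mapping_from_tsv(text: str) -> tuple[str, np.ndarray]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ValueError("empty mapping table")
    return lines[0], np.array([int(v) for v in lines[1:]], dtype=np.int64)
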