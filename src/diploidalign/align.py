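"""Recombination-aware haploid-to-diploid edit distance (full dynamic program).

The distance computed here is the minimum unit-cost (Levenshtein) edit distance
between a haploid sequence ``A`` and *any valid reference-guided recombination*
of the two truth alleles ``B1`` and ``B2`` — a mosaic string that may switch
between the alleles only at positions they share in common with the reference.

Two edit-distance matrices are filled simultaneously, one per allele; matrix k
cell ``(col, i)`` holds the least distance between ``A[:i]`` and a recombination
ending at allele k's character ``col-1``.  Columns are driven by a single sweep
over reference positions ``j``: each matrix advances by one column whenever its
next allele character maps to ``j``; the two matrix tips are then minimised into
each other wherever a switch between alleles is possible at ``j``; finally any
insertion columns (further characters still mapping to ``j``) are consumed.  The
answer is the minimum of the two bottom-right cells.  Only the current column of
each matrix is retained, giving linear space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Allele, validate_allele

__all__ = [
    "AlignmentResult",
    "diploid_align",
    "levenshtein",
    "nonoverlap_shortcut",
    "align_to_diploid",
]


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a haploid-to-diploid alignment.

    ``distance`` is the minimum recombination-aware edit distance;
    ``per_matrix_final`` holds the two bottom-right cell values (one per
    allele-ending matrix); ``cells_computed`` counts DP cells filled (summed
    over all rounds for the doubling engine); ``cutoff_used`` is the final
    band cutoff, or ``"full"`` for the unbanded engine, or ``"shortcut"``
    when the non-overlap concatenation shortcut applied.
    """

    distance: int
    per_matrix_final: tuple[int, int]
    cells_computed: int
    cutoff_used: int | str


def _seq_to_bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)


def levenshtein(x: str, y: str) -> int:
    """Standard unit-cost edit distance between two strings."""
    xb = _seq_to_bytes(x)
    yb = _seq_to_bytes(y)
    if len(xb) == 0:
        return len(yb)
    if len(yb) == 0:
        return len(xb)
    rows = len(xb) + 1
    idx = np.arange(rows, dtype=np.int64)
    cur = idx.copy()
    for col in range(1, len(yb) + 1):
        prev = cur
        cand = np.empty(rows, dtype=np.int64)
        cand[0] = col
        delta = (xb != yb[col - 1]).astype(np.int64)
        np.minimum(prev[1:] + 1, prev[:-1] + delta, out=cand[1:])
        # vertical pass: cur[i] = min_{h<=i} cand[h] + (i - h)
        cur = np.minimum.accumulate(cand - idx) + idx
    return int(cur[-1])


def _mget(m: np.ndarray, idx: int, big: int) -> int:
    """Mapping access with sentinels: -1 left of the table, ``big`` past its end.

    -1 can never equal a reference position j >= 0, and ``big`` (chosen larger
    than any j+1) can never satisfy the switch or while-loop conditions, which
    makes the column-sweep conditions well defined at both edges.
    """
    if idx < 0:
        return -1
    if idx >= len(m):
        return big
    return int(m[idx])


def _calc_column(prev: np.ndarray, b_char: int, a_bytes: np.ndarray,
                 idx: np.ndarray) -> np.ndarray:
    """One column of the unit-cost recurrence, vectorised.

    Horizontal/diagonal candidates come from ``prev``; the in-column vertical
    dependency is resolved with a running minimum over ``cand[h] + (i - h)``.

    Row 0 extends the previous column's row 0 (equal to the plain Levenshtein
    boundary ``col`` until a tip exchange lowers it: its invariant meaning is
    the length of the shortest recombination ending at this column's character,
    which the boundary must track for deletion-only paths to be priced right).
    """
    cand = np.empty(len(prev), dtype=np.int64)
    cand[0] = prev[0] + 1
    if len(prev) > 1:
        delta = (a_bytes != b_char).astype(np.int64)
        np.minimum(prev[1:] + 1, prev[:-1] + delta, out=cand[1:])
    return np.minimum.accumulate(cand - idx) + idx


def diploid_align(
    a: str,
    b1: Allele,
    b2: Allele,
    reference_length: int,
    *,
    record_columns: bool = False,
) -> AlignmentResult:
    """Full-matrix recombination-aware edit distance between ``a`` and (B1, B2).

    ``record_columns`` keeps every computed column of both matrices on the
    result (attribute ``columns``) for inspection in tests; it does not change
    the distance.
    """
    for name, allele in (("B1", b1), ("B2", b2)):
        verdict = validate_allele(allele, reference_length)
        if not verdict.valid:
            raise ValueError(f"{name}: {verdict.reason}")

    a_bytes = _seq_to_bytes(a)
    rows = len(a_bytes) + 1
    idx = np.arange(rows, dtype=np.int64)
    big = reference_length + 5

    seqs = (_seq_to_bytes(b1.sequence), _seq_to_bytes(b2.sequence))
    maps = (b1.mapping, b2.mapping)
    cur = [idx.copy(), idx.copy()]  # column 0 of each matrix
    cols = [1, 1]  # next column to fill, per matrix
    cells = 0
    recorded: tuple[list, list] = ([idx.copy()], [idx.copy()])

    def advance(k: int) -> None:
        nonlocal cells
        c = cols[k]
        cur[k] = _calc_column(cur[k], seqs[k][c - 1], a_bytes, idx)
        cols[k] = c + 1
        cells += rows
        if record_columns:
            recorded[k].append(cur[k].copy())

    for j in range(reference_length):
        if _mget(maps[0], cols[0] - 1, big) == j:
            advance(0)
        if _mget(maps[1], cols[1] - 1, big) == j:
            advance(1)
        # switch possibilities at reference position j: minimise one matrix's
        # tip column into the other's.  Row 0 (empty haploid prefix) takes part:
        # its value must be the length of the *shortest* recombination ending at
        # the tip character, or deletion-heavy alignments through short mosaics
        # are over-counted (see docs/methods.md on boundary handling).
        if _mget(maps[0], cols[0] - 2, big) == j and (
            _mget(maps[1], cols[1] - 1, big) == j + 1
            or _mget(maps[1], cols[1] - 2, big) == j
        ):
            np.minimum(cur[1], cur[0], out=cur[1])
        if _mget(maps[1], cols[1] - 2, big) == j and (
            _mget(maps[0], cols[0] - 1, big) == j + 1
            or _mget(maps[0], cols[0] - 2, big) == j
        ):
            np.minimum(cur[0], cur[1], out=cur[0])
        # insertion columns still mapping to j
        while _mget(maps[0], cols[0] - 1, big) <= j:
            advance(0)
        while _mget(maps[1], cols[1] - 1, big) <= j:
            advance(1)

    finals = (int(cur[0][-1]), int(cur[1][-1]))
    result = AlignmentResult(min(finals), finals, cells, "full")
    if record_columns:
        object.__setattr__(result, "columns", recorded)
    return result


def nonoverlap_shortcut(a: str, b1: Allele, b2: Allele) -> AlignmentResult | None:
    """Concatenation shortcut for alleles covering disjoint reference ranges.

    When every reference position of B1 precedes every position of B2 (or vice
    versa), any valid recombination is exactly the appropriate concatenation,
    so the distance is a plain Levenshtein distance.  Returns ``None`` when the
    alleles overlap (caller should run the dynamic program).
    """
    if len(b1.mapping) == 0 or len(b2.mapping) == 0:
        return None
    if b1.mapping[-1] < b2.mapping[0]:
        d = levenshtein(a, b1.sequence + b2.sequence)
    elif b2.mapping[-1] < b1.mapping[0]:
        d = levenshtein(a, b2.sequence + b1.sequence)
    else:
        return None
    return AlignmentResult(d, (d, d), (len(b1) + len(b2)) * len(a), "shortcut")


def align_to_diploid(
    a: str,
    b1: Allele,
    b2: Allele,
    reference_length: int,
    *,
    engine: str = "doubling",
    cutoff: int | None = None,
) -> AlignmentResult:
    """Public entry point: non-overlap shortcut first, then the selected engine.

    ``engine`` is ``"full"`` (quadratic-time Algorithm) or ``"doubling"``
    (banded diagonal doubling, O(d n) time).  A fixed ``cutoff`` runs a single
    banded pass instead and raises :class:`diploidalign.banded.CutoffExceeded`
    if the distance exceeds it.
    """
    shortcut = nonoverlap_shortcut(a, b1, b2)
    if shortcut is not None:
        return shortcut
    if cutoff is not None:
        from .banded import diploid_align_banded

        return diploid_align_banded(a, b1, b2, reference_length, cutoff)
    if engine == "full":
        return diploid_align(a, b1, b2, reference_length)
    if engine == "doubling":
        from .banded import diploid_align_doubling

        return diploid_align_doubling(a, b1, b2, reference_length)
    raise ValueError(f"unknown engine {engine!r}")
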