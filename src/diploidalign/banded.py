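"""Banded (diagonal-doubling) variant of the haploid-to-diploid alignment.

For plain edit distance the classic cutoff argument restricts computation to
diagonals ``|i - j| <= k``: every diagonal change costs one edit.  With
recombination that zone is unsafe as stated, because a switch connects columns
of the two matrices whose *recombination prefix lengths* need not equal their
column indices (the alleles may carry different indel content up to the switch
point), so a cheap path can leave the naive per-matrix diagonal zone.  The band
used here generalises the argument soundly: for every column we bound the
lengths of recombination prefixes that can end at that column's character, and
of suffixes that can complete it, from per-reference-position character counts
of the two alleles.  A cell ``(col, i)`` can lie on a path of total cost at
most ``k`` only if

    dist(i, [Lmin, Lmax](col)) + dist(n_A - i, [Smin, Smax](col)) <= k

since an alignment of ``A[:i]`` against a prefix of length ``l`` costs at least
``|l - i|``, and likewise for the completion.  Cells outside are +infinity and
the tip exchange between the matrices is restricted to rows present in both
bands.  A banded pass that returns a value at most ``k`` is therefore exact;
otherwise the distance provably exceeds ``k``.

The doubling driver starts at ``k0 = max(1, |len(A)-len(B1)|, |len(A)-len(B2)|)``
(the smallest cutoff whose band can reach the bottom-right corner of both
matrices) and doubles until the result certifies, giving O(d n) total cells.
"""

from __future__ import annotations

import numpy as np

from .align import AlignmentResult, _seq_to_bytes
from .genome import Allele, validate_allele

__all__ = ["CutoffExceeded", "diploid_align_banded", "diploid_align_doubling"]


class CutoffExceeded(Exception):
    """The distance exceeds the requested cutoff; carries cells computed so far."""

    def __init__(self, cutoff: int, cells: int):
        super().__init__(f"distance exceeds cutoff {cutoff}")
        self.cutoff = cutoff
        self.cells = cells


class _BandBounds:
    """Per-column recombination prefix/suffix length intervals for one matrix.

    Per reference position ``j`` a valid recombination contributes between
    ``cmin(j)`` and ``cmax(j)`` characters, where ``cmin = min(n1, n2)`` when
    both alleles have characters at ``j`` (a mosaic cannot skip a position both
    alleles carry) and 0 otherwise, and ``cmax = max(n1, n2)``.  Prefix sums of
    these per-position bounds over each column's tip period give sound
    per-column intervals of achievable prefix and suffix lengths.
    """

    def __init__(self, mapping: np.ndarray, reference_length: int,
                 psmin: np.ndarray, psmax: np.ndarray):
        L = len(mapping)
        self.length = L
        total_min = int(psmin[-1])
        total_max = int(psmax[-1])
        # a column stays the exchange tip for every reference position from its
        # own character's (j_own) up to its successor's (j_next); the intervals
        # must span all prefixes/suffixes representable anywhere in that period,
        # since an exchange at any such position merges the other matrix's
        # prefixes into this column
        m = mapping.astype(np.int64)
        j_next = np.concatenate((m[1:], [reference_length])) if L else None
        # chars consumed within the column's own reference position (exact)
        q = np.arange(1, L + 1, dtype=np.int64) - np.searchsorted(m, m)
        lmin = np.empty(L + 1, dtype=np.int64)
        lmax = np.empty(L + 1, dtype=np.int64)
        smin = np.empty(L + 1, dtype=np.int64)
        smax = np.empty(L + 1, dtype=np.int64)
        lmin[0], smin[0] = 0, total_min
        lmax[0] = psmax[m[0]] if L else total_max  # merged-in prefixes before m[0]
        smax[0] = total_max
        if L:
            # own prefix: full coverage below j_own plus exactly q chars at it;
            # merged-in prefixes (exchanges during the tip period) reach up to
            # everything before j_next
            lmin[1:] = psmin[m] + 1
            lmax[1:] = np.maximum(psmax[m] + q, psmax[j_next])
            # a completion must still cover every position both alleles carry
            # beyond j_own; anything at or before it may already be consumed
            # (a terminal switch can even end the recombination at j_own)
            smin[1:] = total_min - psmin[m + 1]
            smax[1:] = total_max - psmax[m]
        self.lmin, self.lmax, self.smin, self.smax = lmin, lmax, smin, smax

    def rows(self, col: int, na: int, k: int) -> tuple[int, int]:
        """Admissible row interval [lo, hi] for this column at cutoff k (lo > hi: none)."""
        l1, r1 = int(self.lmin[col]), int(self.lmax[col])
        l2, r2 = na - int(self.smax[col]), na - int(self.smin[col])
        if l1 - r2 > k or l2 - r1 > k:
            return 0, -1
        lo = max(0, l1 - k, l2 - k, (l1 + l2 - k + 1) // 2)
        hi = min(na, r1 + k, r2 + k, (r1 + r2 + k) // 2)
        return lo, hi


def _band_bounds(b1: Allele, b2: Allele, reference_length: int
                 ) -> tuple[_BandBounds, _BandBounds]:
    c1 = np.bincount(b1.mapping, minlength=reference_length)
    c2 = np.bincount(b2.mapping, minlength=reference_length)
    both = (c1 > 0) & (c2 > 0)
    cmin = np.where(both, np.minimum(c1, c2), 0).astype(np.int64)
    cmax = np.maximum(c1, c2).astype(np.int64)
    psmin = np.concatenate(([0], np.cumsum(cmin)))  # psmin[j] = sum over j' < j
    psmax = np.concatenate(([0], np.cumsum(cmax)))
    return (
        _BandBounds(b1.mapping, reference_length, psmin, psmax),
        _BandBounds(b2.mapping, reference_length, psmin, psmax),
    )


class _BandedMatrix:
    """One allele's DP matrix, computed column-by-column inside the band.

    On top of the static band, columns only store the row window where values
    can still be at most the cutoff: rows outside a stored window provably hold
    values above it (stored values themselves are exact whenever they are at
    most the cutoff, and otherwise are upper bounds that are still above it).
    The window of a new column derives from the rows of the previous column at
    most the cutoff — evaluated lazily, after any tip exchanges have lowered
    them — extended downwards by the pure-deletion chain while it stays within
    budget.  An exchange may widen the receiving column's window (inside its
    static band) since merged-in values can revive rows the column had ruled
    out on its own.
    """

    def __init__(self, seq: np.ndarray, mapping: np.ndarray, a_bytes: np.ndarray,
                 bounds: _BandBounds, cutoff: int, inf: int):
        self.seq = seq
        self.mapping = mapping
        self.a = a_bytes
        self.na = len(a_bytes)
        self.bounds = bounds
        self.k = cutoff
        self.inf = inf
        self.col = 0  # last computed column
        lo, hi = bounds.rows(0, self.na, cutoff)
        hi = min(hi, cutoff)  # column 0 is the plain Levenshtein boundary
        self.lo = lo
        self.vals = np.arange(lo, hi + 1, dtype=np.int64)
        self.cells = 0

    @property
    def hi(self) -> int:
        return self.lo + len(self.vals) - 1

    def _window(self, a: int, b: int) -> np.ndarray:
        """Previous-column values for rows a..b, +inf outside its stored window."""
        out = np.full(b - a + 1, self.inf, dtype=np.int64)
        s = max(a, self.lo)
        e = min(b, self.hi)
        if s <= e:
            out[s - a: e - a + 1] = self.vals[s - self.lo: e - self.lo + 1]
        return out

    def advance(self) -> None:
        """Fill the next column for the next allele character."""
        col = self.col + 1
        b_char = self.seq[col - 1]
        k = self.k
        slo, shi = self.bounds.rows(col, self.na, k)
        live = np.flatnonzero(self.vals <= k) if len(self.vals) else np.empty(0, int)
        if slo > shi or not len(live):
            # nothing within budget can reach this column on its own; it may
            # still be revived later by an exchange
            self.col, self.lo, self.vals = col, 0, np.empty(0, dtype=np.int64)
            return
        lo = max(slo, self.lo + int(live[0]))
        hi = min(shi, self.lo + int(live[-1]) + 1)
        if lo > hi:
            self.col, self.lo, self.vals = col, 0, np.empty(0, dtype=np.int64)
            return
        cand = np.minimum(self._window(lo, hi) + 1, self.inf)
        if hi >= 1:
            first = max(lo, 1)
            diag = self._window(first - 1, hi - 1)
            delta = (self.a[first - 1: hi] != b_char).astype(np.int64)
            np.minimum(cand[first - lo:], diag + delta, out=cand[first - lo:])
        idx = np.arange(lo, hi + 1, dtype=np.int64)
        vals = np.minimum.accumulate(cand - idx) + idx
        # pure-deletion extension below the window while it stays within budget
        tail = int(vals[-1])
        ext = min(shi - hi, k - tail)
        if ext > 0:
            vals = np.concatenate(
                (vals, tail + 1 + np.arange(ext, dtype=np.int64))
            )
            hi += ext
        self.col, self.lo, self.vals = col, lo, vals
        self.cells += hi - lo + 1

    def receive(self, src: "_BandedMatrix") -> None:
        """Merge the source matrix's tip column into this one.

        Restricted to this matrix's static band for its current column; widens
        the stored window where the source brings rows within budget.
        """
        if not len(src.vals):
            return
        ds_lo, ds_hi = self.bounds.rows(self.col, self.na, self.k)
        s_lo = max(src.lo, ds_lo)
        s_hi = min(src.hi, ds_hi)
        if s_lo > s_hi:
            return
        if not len(self.vals):
            new_lo, new_hi = s_lo, s_hi
        else:
            new_lo, new_hi = min(self.lo, s_lo), max(self.hi, s_hi)
        merged = np.full(new_hi - new_lo + 1, self.inf, dtype=np.int64)
        if len(self.vals):
            merged[self.lo - new_lo: self.hi - new_lo + 1] = self.vals
        tgt = merged[s_lo - new_lo: s_hi - new_lo + 1]
        np.minimum(tgt, src.vals[s_lo - src.lo: s_hi - src.lo + 1], out=tgt)
        self.cells += max(0, (new_hi - new_lo + 1) - len(self.vals))
        self.lo, self.vals = new_lo, merged

    def final_value(self) -> int:
        if len(self.vals) and self.hi == self.na:
            return int(self.vals[-1])
        return self.inf


def _mget(m: np.ndarray, idx: int, big: int) -> int:
    if idx < 0:
        return -1
    if idx >= len(m):
        return big
    return int(m[idx])


def diploid_align_banded(
    a: str,
    b1: Allele,
    b2: Allele,
    reference_length: int,
    cutoff: int,
    _bounds: tuple[_BandBounds, _BandBounds] | None = None,
) -> AlignmentResult:
    """Single banded pass with a fixed cutoff.

    Returns the exact distance when it is at most ``cutoff``; raises
    :class:`CutoffExceeded` otherwise.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    for name, allele in (("B1", b1), ("B2", b2)):
        verdict = validate_allele(allele, reference_length)
        if not verdict.valid:
            raise ValueError(f"{name}: {verdict.reason}")

    a_bytes = _seq_to_bytes(a)
    na = len(a_bytes)
    inf = na + max(len(b1), len(b2)) + 10
    if _bounds is None:
        _bounds = _band_bounds(b1, b2, reference_length)

    m1 = _BandedMatrix(_seq_to_bytes(b1.sequence), b1.mapping, a_bytes,
                       _bounds[0], cutoff, inf)
    m2 = _BandedMatrix(_seq_to_bytes(b2.sequence), b2.mapping, a_bytes,
                       _bounds[1], cutoff, inf)
    big = reference_length + 5

    for j in range(reference_length):
        if _mget(m1.mapping, m1.col, big) == j:
            m1.advance()
        if _mget(m2.mapping, m2.col, big) == j:
            m2.advance()
        if _mget(m1.mapping, m1.col - 1, big) == j and (
            _mget(m2.mapping, m2.col, big) == j + 1
            or _mget(m2.mapping, m2.col - 1, big) == j
        ):
            m2.receive(m1)
        if _mget(m2.mapping, m2.col - 1, big) == j and (
            _mget(m1.mapping, m1.col, big) == j + 1
            or _mget(m1.mapping, m1.col - 1, big) == j
        ):
            m1.receive(m2)
        while _mget(m1.mapping, m1.col, big) <= j:
            m1.advance()
        while _mget(m2.mapping, m2.col, big) <= j:
            m2.advance()

    finals = (m1.final_value(), m2.final_value())
    cells = m1.cells + m2.cells
    distance = min(finals)
    if distance > cutoff:
        raise CutoffExceeded(cutoff, cells)
    return AlignmentResult(distance, finals, cells, cutoff)


def diploid_align_doubling(
    a: str, b1: Allele, b2: Allele, reference_length: int
) -> AlignmentResult:
    """Exact distance via banded passes with doubling cutoffs, O(d n) total work."""
    na = len(a)
    k = max(1, abs(na - len(b1)), abs(na - len(b2)))
    k_cap = 2 * (na + max(len(b1), len(b2)) + 1)  # full-width band is exact
    bounds = _band_bounds(b1, b2, reference_length)
    total_cells = 0
    while True:
        try:
            res = diploid_align_banded(a, b1, b2, reference_length, k, bounds)
        except CutoffExceeded as exc:
            total_cells += exc.cells
            if k > k_cap:  # cannot happen: full-width band is exact
                raise AssertionError("doubling failed to terminate") from exc
            k *= 2
            continue
        return AlignmentResult(
            res.distance, res.per_matrix_final, total_cells + res.cells_computed, k
        )
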