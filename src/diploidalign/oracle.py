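"""Brute-force reference implementation: enumerate every valid recombination.

Used only for verification.  Every valid reference-guided recombination of the
two alleles is spelled out as an explicit string by walking the switch graph,
each string is scored against the haploid with an independent Levenshtein
implementation (edlib), and the minimum is returned.  This shares no code with
the dynamic program it cross-checks.

Switch semantics (operational, mirroring the column sweep of the production
algorithm): a switch leaves an allele at a *reference-aligned* character — one
that is the first of its mapping value, never partway through an insertion
run — at reference position ``j``, and resumes in the other allele either just
after that allele's own reference-aligned character at ``j`` (picking up its
insertion run at ``j``), or at its first character mapping to ``j + 1`` when it
has no character at ``j``.  When the other allele ends exactly at ``j`` the
continuation is empty and the recombination terminates there.  Otherwise a
recombination terminates at the final character of the allele it is in.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from .genome import Allele

__all__ = ["RecombinationString", "enumerate_recombinations", "oracle_distance"]

#: combined allele length above which enumeration refuses to run
DEFAULT_CAP = 24


@dataclass(frozen=True)
class RecombinationString:
    """A recombined string plus one path of (allele index, allele position) pairs."""

    text: str
    path: tuple[tuple[int, int], ...]


def _first_index_with(mapping: np.ndarray, value: int) -> int | None:
    """Index of the first allele character mapping to ``value``, or None."""
    i = int(np.searchsorted(mapping, value, side="left"))
    if i < len(mapping) and mapping[i] == value:
        return i
    return None


def _switch_target(dst: Allele, j: int) -> int | None:
    """Continuation index in ``dst`` for a switch at reference position ``j``.

    Returns ``len(dst)`` for an empty continuation (the recombination may end),
    or ``None`` when no switch into ``dst`` is possible at ``j``.
    """
    r = _first_index_with(dst.mapping, j)
    if r is not None:
        # resume after dst's reference-aligned character at j; its insertion
        # run at j (if any) travels with the right-hand segment
        return r + 1
    f = _first_index_with(dst.mapping, j + 1)
    if f is not None:
        return f
    return None


def enumerate_recombinations(
    b1: Allele, b2: Allele, cap: int = DEFAULT_CAP
) -> list[RecombinationString]:
    """All valid reference-guided recombinations of ``b1`` and ``b2``.

    De-duplicated by text (one representative path kept per string).  Refuses
    combined allele lengths above ``cap`` — the dynamic program is the
    production path for anything non-toy.
    """
    if len(b1) + len(b2) > cap:
        raise ValueError(
            f"combined allele length {len(b1) + len(b2)} exceeds enumeration "
            f"cap {cap}; use the dynamic program instead"
        )
    alleles = (b1, b2)
    results: dict[str, tuple[tuple[int, int], ...]] = {}

    def is_ref_aligned(a: int, pos: int) -> bool:
        m = alleles[a].mapping
        return pos == 0 or m[pos] != m[pos - 1]

    def walk(a: int, p: int, text: list[str], path: list[tuple[int, int]],
             just_switched: bool) -> None:
        allele = alleles[a]
        if p == len(allele):
            # reached the allele's end: a complete recombination, but switching
            # onward into the other allele remains possible from the final tip
            results.setdefault("".join(text), tuple(path))
        else:
            # consume the next character of the current allele
            text.append(allele.sequence[p])
            path.append((a, p))
            walk(a, p + 1, text, path, False)
            text.pop()
            path.pop()
        # switch away from a reference-aligned consumed tip
        if not just_switched and p >= 1 and is_ref_aligned(a, p - 1):
            j = int(allele.mapping[p - 1])
            other = 1 - a
            s = _switch_target(alleles[other], j)
            if s is None:
                return
            if s == len(alleles[other]):
                # empty continuation: the other allele ends at j, so the
                # recombination may terminate here
                results.setdefault("".join(text), tuple(path))
            else:
                walk(other, s, text, path, True)

    for start in (0, 1):
        if len(alleles[start]) > 0:
            walk(start, 0, [], [], False)
        else:
            results.setdefault("", ())
    return [RecombinationString(t, p) for t, p in sorted(results.items())]


def _edit_distance(x: str, y: str) -> int:
    if not x or not y:
        return max(len(x), len(y)) if (not x or not y) else 0
    return edlib.align(x, y, task="distance")["editDistance"]


def oracle_distance(a: str, b1: Allele, b2: Allele, cap: int = DEFAULT_CAP) -> int:
    """Minimum edit distance from ``a`` to any valid recombination, by brute force."""
    recs = enumerate_recombinations(b1, b2, cap=cap)
    a = a.upper()
    return min(_edit_distance(a, r.text) for r in recs)


def random_instance(rng, max_ref_len: int = 8, cap: int = DEFAULT_CAP
                    ) -> tuple[str, Allele, Allele, int]:
    """A random mutation-dense instance small enough for the brute-force oracle.

    Alleles are built directly as (sequence, mapping) pairs with dense
    substitutions, deletions and multi-character insertion runs — deliberately
    harsher than the genome simulator — and the haploid is an unrelated random
    string, so that switch corner cases (insertion runs at switch points,
    skipped positions, terminal switches) are well exercised.  ``rng`` is a
    ``random.Random``.
    """

    def rand_allele(ref: str) -> Allele:
        chars: list[str] = []
        mapping: list[int] = []
        for j, c in enumerate(ref):
            r = rng.random()
            if r < 0.18:
                pass  # deletion
            elif r < 0.40:
                chars.append(rng.choice("ACGT"))
                mapping.append(j)
            else:
                chars.append(c)
                mapping.append(j)
            while mapping and rng.random() < 0.15:
                chars.append(rng.choice("ACGT"))
                mapping.append(mapping[-1])
        return Allele("".join(chars), np.array(mapping, dtype=np.int64))

    while True:
        n = rng.randint(1, max_ref_len)
        ref = "".join(rng.choice("ACGT") for _ in range(n))
        b1, b2 = rand_allele(ref), rand_allele(ref)
        if len(b1) + len(b2) <= cap:
            a = "".join(rng.choice("ACGT") for _ in range(rng.randint(0, n + 3)))
            return a, b1, b2, n
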