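"""Variant records and their application to a reference.

Two directions of use:

* building the *truth* diploid: zygosity-annotated variants are applied per
  allele (homozygous to both, heterozygous to one) producing sequences together
  with their reference mapping tables;
* building *predicted* haploids: all called variants are applied greedily left
  to right on one haploid; conflicting heterozygous calls spill over into
  additional haploids (each of which also receives every homozygous call that
  fits), so that every prediction is materialised somewhere.

Variants are stored in anchored (VCF-style) or plain form; before application
each is normalised by trimming the longest shared prefix of its ref and alt
strings, so that equivalent encodings occupy identical reference intervals.  A
pure insertion then occupies the zero-width boundary before its position and
conflicts only with another insertion at the same boundary or with a variant
whose interval strictly contains the boundary; replacements conflict when their
intervals intersect.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .genome import Allele, DiploidTruth, Reference


class Zygosity(str, enum.Enum):
    HETEROZYGOUS = "heterozygous"
    HOMOZYGOUS = "homozygous"


@dataclass(frozen=True)
class Variant:
    """An anchored substitution/insertion/deletion at a 0-based reference position.

    ``ref_allele`` is the replaced reference substring (may be empty for a pure
    insertion *before* ``position``); ``alt_allele`` replaces it.  ``allele``
    optionally phases a heterozygous variant onto truth allele 1 or 2.
    """

    position: int
    ref_allele: str
    alt_allele: str
    zygosity: Zygosity = Zygosity.HOMOZYGOUS
    allele: int | None = None

    def __post_init__(self) -> None:
        if self.position < 0:
            raise ValueError(f"negative position {self.position}")
        if not self.ref_allele and not self.alt_allele:
            raise ValueError("ref and alt cannot both be empty")
        object.__setattr__(self, "ref_allele", self.ref_allele.upper())
        object.__setattr__(self, "alt_allele", self.alt_allele.upper())
        if self.allele not in (None, 1, 2):
            raise ValueError("allele must be None, 1 or 2")

    @property
    def is_het(self) -> bool:
        return self.zygosity is Zygosity.HETEROZYGOUS


@dataclass(frozen=True)
class _Edit:
    """A normalised (prefix-trimmed) edit: replace reference [start, end) by alt."""

    start: int
    end: int
    alt: str
    source: Variant

    @property
    def is_insertion(self) -> bool:
        return self.start == self.end

    def conflicts(self, other: "_Edit") -> bool:
        if self.is_insertion and other.is_insertion:
            return self.start == other.start
        if self.is_insertion:
            return other.start < self.start < other.end
        if other.is_insertion:
            return self.start < other.start < self.end
        return self.start < other.end and other.start < self.end


def _normalise(v: Variant, reference: Reference) -> _Edit:
    ref, alt, pos = v.ref_allele, v.alt_allele, v.position
    end = pos + len(ref)
    if end > reference.length:
        raise ValueError(f"variant at position {v.position} runs past the reference end")
    actual = reference.sequence[pos:end]
    if actual != ref:
        raise ValueError(
            f"REF mismatch at position {v.position}: variant says {ref!r}, "
            f"reference has {actual!r}"
        )
    # trim the longest common prefix so equivalent encodings coincide
    while ref and alt and ref[0] == alt[0]:
        ref, alt, pos = ref[1:], alt[1:], pos + 1
    return _Edit(pos, pos + len(ref), alt, v)


def _sort_key(e: _Edit):
    return (e.start, not e.is_insertion, e.source.ref_allele, e.source.alt_allele)


def _materialise(reference: Reference, edits: list[_Edit]) -> tuple[str, np.ndarray]:
    """Apply non-conflicting edits, producing the sequence and its mapping table.

    Substituted characters keep their reference position; surplus (inserted)
    characters carry the nearest preceding reference-aligned position; deleted
    positions are skipped.  An insertion before position 0 has no preceding
    anchor and is rejected.
    """
    chunks: list[str] = []
    maps: list[np.ndarray] = []
    cursor = 0
    for e in sorted(edits, key=_sort_key):
        if e.start < cursor:
            raise ValueError("conflicting edits passed to materialise")
        chunks.append(reference.sequence[cursor:e.start])
        maps.append(np.arange(cursor, e.start, dtype=np.int64))
        if e.alt:
            n_keep = min(len(e.alt), max(e.end - e.start, 1))
            if e.is_insertion:
                if e.start == 0:
                    raise ValueError(
                        "insertion before the first reference position is unsupported"
                    )
                m = np.full(len(e.alt), e.start - 1, dtype=np.int64)
            else:
                m = np.empty(len(e.alt), dtype=np.int64)
                m[:n_keep] = np.arange(e.start, e.start + n_keep)
                m[n_keep:] = e.start + n_keep - 1
            chunks.append(e.alt)
            maps.append(m)
        cursor = max(cursor, e.end)
    chunks.append(reference.sequence[cursor:])
    maps.append(np.arange(cursor, reference.length, dtype=np.int64))
    mapping = (
        np.concatenate(maps) if maps else np.empty(0, dtype=np.int64)
    )
    return "".join(chunks), mapping


@dataclass
class PredictedHaploidSet:
    """Haploid sequences materialised from predicted variants.

    ``applied[i]`` lists the variants realised on haploid ``i``; ``skipped``
    holds (variant, reason) pairs for calls that fit nowhere.
    """

    haploids: list[str]
    applied: list[list[Variant]]
    skipped: list[tuple[Variant, str]] = field(default_factory=list)


def apply_variants(reference: Reference, variants: list[Variant]) -> PredictedHaploidSet:
    """Greedy left-to-right application of predicted variants.

    The first haploid receives every variant that does not conflict with one
    already placed on it.  A conflicting heterozygous call opens (or reuses)
    a further haploid, which also receives all homozygous calls that fit; a
    conflicting homozygous call that fits no existing haploid is reported as
    skipped rather than spawning haploids of its own.
    """
    edits = sorted((_normalise(v, reference) for v in variants), key=_sort_key)
    placed: list[list[_Edit]] = [[]]

    def fits(group: list[_Edit], e: _Edit) -> bool:
        return not any(e.conflicts(p) for p in group)

    skipped: list[tuple[Variant, str]] = []
    for e in edits:
        if e.source.is_het:
            for group in placed:
                if fits(group, e):
                    group.append(e)
                    break
            else:
                # open a new haploid seeded with the homozygous calls so far
                group = [e]
                for prev in edits:
                    if prev is e:
                        break
                    if not prev.source.is_het and fits(group, prev):
                        group.append(prev)
                placed.append(group)
        else:
            hit = False
            for group in placed:
                if fits(group, e):
                    group.append(e)
                    hit = True
            if not hit:
                skipped.append((e.source, "conflicts on every haploid"))

    haploids, applied = [], []
    for group in placed:
        seq, _ = _materialise(reference, group)
        haploids.append(seq)
        applied.append([e.source for e in sorted(group, key=_sort_key)])
    return PredictedHaploidSet(haploids, applied, skipped)


def build_truth_diploid(reference: Reference, variants: list[Variant]) -> DiploidTruth:
    """Construct the truth diploid from zygosity-annotated variants.

    Homozygous variants go to both alleles; heterozygous ones to their phased
    allele, or to allele 1 when unphased.  Conflicting variants on the same
    allele are an error — a single haplotype cannot realise both.
    """
    per_allele: tuple[list[_Edit], list[_Edit]] = ([], [])
    for v in variants:
        e = _normalise(v, reference)
        targets = (0, 1) if not v.is_het else ((v.allele or 1) - 1,)
        for t in targets:
            clash = next((p for p in per_allele[t] if e.conflicts(p)), None)
            if clash is not None:
                raise ValueError(
                    f"variants at positions {clash.source.position} and "
                    f"{v.position} overlap on allele {t + 1}"
                )
            per_allele[t].append(e)
    seq1, map1 = _materialise(reference, per_allele[0])
    seq2, map2 = _materialise(reference, per_allele[1])
    return DiploidTruth(
        reference.id, Allele(seq1, map1), Allele(seq2, map2), reference.length
    )
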