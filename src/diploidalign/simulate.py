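"""Diploid genome simulator for benchmarking the alignment.

Generates a uniform random DNA reference and mutates it into a diploid: at each
reference position an independent draw applies at most one single-base event —
substitution, deletion, or insertion after the position — each with its own
per-position probability (default 0.003, i.e. roughly n/100 variations over a
length-n reference with the three defaults combined).  Each event is homozygous
with probability ``p_hom`` (default 0.5), otherwise heterozygous and assigned
to a uniformly random allele.  Because events are anchored at distinct
positions they never conflict within an allele, and the expected
recombination-aware distance from the original reference to the simulated
diploid is about half the variation count: at a heterozygous site one allele
still agrees with the reference, and a valid recombination can follow it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import DiploidTruth, Reference
from .variants import Variant, Zygosity, build_truth_diploid

__all__ = ["SimulationParams", "random_reference", "mutate_to_diploid"]

_ALPHABET = "ACGT"


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the diploid simulator.

    ``p_sub``, ``p_del`` and ``p_ins`` are per-position per-type probabilities;
    when more than one type fires at a position (probability ~1e-5 at the
    defaults) the first of substitution, deletion, insertion wins, keeping at
    most one event per position.
    """

    n: int
    p_ins: float = 0.003
    p_del: float = 0.003
    p_sub: float = 0.003
    p_hom: float = 0.5
    seed: int = 0
    alphabet: str = _ALPHABET

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("reference length must be at least 1")
        for name in ("p_ins", "p_del", "p_sub", "p_hom"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.p_ins + self.p_del + self.p_sub > 1.0:
            raise ValueError("p_ins + p_del + p_sub must not exceed 1")


def random_reference(n: int, seed: int | np.random.Generator,
                     alphabet: str = _ALPHABET) -> Reference:
    """Uniform i.i.d. DNA string of length ``n``; deterministic given the seed."""
    if n < 1:
        raise ValueError("reference length must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    letters = np.frombuffer(alphabet.encode(), dtype=np.uint8)
    seq = rng.integers(0, len(letters), size=n)
    return Reference("sim", letters[seq].tobytes().decode())


def mutate_to_diploid(
    reference: Reference, params: SimulationParams
) -> tuple[DiploidTruth, list[Variant]]:
    """Mutate a reference into a diploid truth plus its variant list.

    The returned diploid's mapping tables are built by the same machinery as
    :func:`diploidalign.variants.build_truth_diploid` applied to the emitted
    variant list, so the two representations are consistent by construction.
    """
    rng = np.random.default_rng(params.seed)
    n = reference.length
    u = rng.random((n, 3))
    sub_hit = u[:, 0] < params.p_sub
    del_hit = (u[:, 1] < params.p_del) & ~sub_hit
    ins_hit = (u[:, 2] < params.p_ins) & ~sub_hit & ~del_hit

    letters = params.alphabet
    variants: list[Variant] = []
    positions = np.flatnonzero(sub_hit | del_hit | ins_hit)
    hom_draw = rng.random(len(positions)) < params.p_hom
    allele_draw = rng.integers(1, 3, size=len(positions))
    # substitution targets drawn among the three non-reference bases,
    # inserted bases among all four
    sub_choice = rng.integers(0, 3, size=len(positions))
    ins_choice = rng.integers(0, 4, size=len(positions))

    for idx, pos in enumerate(positions):
        pos = int(pos)
        base = reference.sequence[pos]
        zyg = Zygosity.HOMOZYGOUS if hom_draw[idx] else Zygosity.HETEROZYGOUS
        allele = None if hom_draw[idx] else int(allele_draw[idx])
        if sub_hit[pos]:
            others = [c for c in letters if c != base]
            alt = others[sub_choice[idx] % len(others)]
            variants.append(Variant(pos, base, alt, zyg, allele))
        elif del_hit[pos]:
            variants.append(Variant(pos, base, "", zyg, allele))
        else:
            inserted = letters[int(ins_choice[idx])]
            # single-base insertion after the position
            variants.append(Variant(pos + 1, "", inserted, zyg, allele))
    truth = build_truth_diploid(reference, variants)
    return truth, variants
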