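"""End-to-end evaluation: predictions -> haploids -> distances to the truth diploid."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

from .align import align_to_diploid
from .genome import DiploidTruth, Reference
from .variants import Variant, apply_variants, build_truth_diploid


@dataclass
class EvaluationReport:
    """Machine-readable outcome of an evaluation run.

    ``distances`` has one recombination-aware edit distance per predicted
    haploid; ``total_distance`` is their sum (the aggregation over multiple
    haploids is a reporting convention — the method itself defines only the
    per-haploid distance).
    """

    distances: list[int]
    haploid_lengths: list[int]
    allele_lengths: tuple[int, int]
    reference_length: int
    engine: str
    cutoffs_used: list[int | str]
    cells_computed: int
    skipped_variants: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    @property
    def total_distance(self) -> int:
        return sum(self.distances)

    def to_json(self) -> str:
        payload = asdict(self)
        payload["total_distance"] = self.total_distance
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        payload = json.loads(text)
        payload.pop("total_distance", None)
        payload["allele_lengths"] = tuple(payload["allele_lengths"])
        return cls(**payload)


def align_haploids(
    haploids: list[str],
    truth: DiploidTruth,
    *,
    engine: str = "doubling",
    cutoff: int | None = None,
    parameters: dict | None = None,
) -> EvaluationReport:
    """Align each predicted haploid to the truth diploid and collect a report."""
    distances: list[int] = []
    cutoffs: list[int | str] = []
    cells = 0
    for hap in haploids:
        res = align_to_diploid(
            hap, truth.allele1, truth.allele2, truth.reference_length,
            engine=engine, cutoff=cutoff,
        )
        distances.append(res.distance)
        cutoffs.append(res.cutoff_used)
        cells += res.cells_computed
    return EvaluationReport(
        distances=distances,
        haploid_lengths=[len(h) for h in haploids],
        allele_lengths=(len(truth.allele1), len(truth.allele2)),
        reference_length=truth.reference_length,
        engine=engine if cutoff is None else f"banded(k={cutoff})",
        cutoffs_used=cutoffs,
        cells_computed=cells,
        parameters=parameters or {},
    )


def evaluate_predictions(
    reference: Reference,
    truth_variants: list[Variant],
    predicted_variants: list[Variant],
    *,
    engine: str = "doubling",
    cutoff: int | None = None,
) -> EvaluationReport:
    """Full pipeline: truth diploid from truth variants, predicted haploid(s)
    from calls, recombination-aware distances between them."""
    truth = build_truth_diploid(reference, truth_variants)
    predicted = apply_variants(reference, predicted_variants)
    report = align_haploids(
        predicted.haploids, truth, engine=engine, cutoff=cutoff,
        parameters={
            "n_truth_variants": len(truth_variants),
            "n_predicted_variants": len(predicted_variants),
            "n_haploids": len(predicted.haploids),
        },
    )
    report.skipped_variants = [
        f"{v.position}:{v.ref_allele or '.'}>{v.alt_allele or '.'} ({reason})"
        for v, reason in predicted.skipped
    ]
    return report
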