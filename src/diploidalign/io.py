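"""File formats: FASTA, aligned-FASTA truth, mapping tables, variant TSV/VCF."""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Allele, DiploidTruth, Reference, derive_mappings
from .variants import Variant, Zygosity


def read_fasta(path: str | os.PathLike) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path: str | os.PathLike, records: list[tuple[str, str]]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        str(path),
        "fasta",
    )


def read_truth_aligned_fasta(path: str | os.PathLike) -> tuple[Reference, DiploidTruth]:
    """Read a truth diploid from a 3-record gapped FASTA (reference, allele 1, allele 2)."""
    records = read_fasta(path)
    if len(records) != 3:
        raise ValueError(
            f"aligned truth FASTA must hold exactly 3 records (reference, two "
            f"alleles); {path} has {len(records)}"
        )
    (p_id, p_row), (_, b1_row), (_, b2_row) = records
    a1, a2 = derive_mappings(p_row, b1_row, b2_row)
    reference = Reference(p_id, p_row.replace("-", "").replace(".", ""))
    truth = DiploidTruth(p_id, a1, a2, reference.length)
    truth.validate()
    return reference, truth


def write_mappings_tsv(path: str | os.PathLike, a1: Allele, a2: Allele) -> None:
    """Both alleles' mapping tables as columns (allele, index, reference position)."""
    with open(path, "w") as fh:
        fh.write("#allele\tindex\treference_position\n")
        for label, allele in ((1, a1), (2, a2)):
            for i, v in enumerate(allele.mapping):
                fh.write(f"{label}\t{i}\t{int(v)}\n")


def read_mappings_tsv(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    cols: dict[int, list[int]] = {1: [], 2: []}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                allele, idx, pos = line.split("\t")
                cols[int(allele)].append(int(pos))
            except (ValueError, KeyError) as exc:
                raise ValueError(f"{path}:{ln}: malformed mapping row") from exc
    return (
        np.array(cols[1], dtype=np.int64),
        np.array(cols[2], dtype=np.int64),
    )


_TSV_ZYGOSITY = {
    "het": (Zygosity.HETEROZYGOUS, None),
    "heterozygous": (Zygosity.HETEROZYGOUS, None),
    "het1": (Zygosity.HETEROZYGOUS, 1),
    "het2": (Zygosity.HETEROZYGOUS, 2),
    "hom": (Zygosity.HOMOZYGOUS, None),
    "homozygous": (Zygosity.HOMOZYGOUS, None),
}


def parse_variants_tsv(text: str) -> list[Variant]:
    """Parse the ``position<TAB>ref<TAB>alt<TAB>zygosity`` dialect (0-based, '.' = empty).

    Zygosity ``het1``/``het2`` phases a heterozygous variant onto a truth allele.
    """
    out: list[Variant] = []
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"line {ln}: expected 4 tab-separated fields")
        pos_s, ref, alt, zyg_s = fields
        try:
            pos = int(pos_s)
        except ValueError as exc:
            raise ValueError(f"line {ln}: bad position {pos_s!r}") from exc
        if zyg_s.lower() not in _TSV_ZYGOSITY:
            raise ValueError(f"line {ln}: unknown zygosity {zyg_s!r}")
        zyg, allele = _TSV_ZYGOSITY[zyg_s.lower()]
        ref = "" if ref == "." else ref
        alt = "" if alt == "." else alt
        try:
            out.append(Variant(pos, ref, alt, zyg, allele))
        except ValueError as exc:
            raise ValueError(f"line {ln}: {exc}") from exc
    return out


def write_variants_tsv(path: str | os.PathLike, variants: list[Variant]) -> None:
    with open(path, "w") as fh:
        fh.write("#position\tref\talt\tzygosity\n")
        for v in variants:
            if v.is_het:
                zyg = f"het{v.allele}" if v.allele else "het"
            else:
                zyg = "hom"
            fh.write(
                f"{v.position}\t{v.ref_allele or '.'}\t{v.alt_allele or '.'}\t{zyg}\n"
            )


def parse_variants_vcf(path: str | os.PathLike) -> list[Variant]:
    """Minimal VCF reader: CHROM/POS/REF/ALT and the first sample's GT.

    Multi-allelic rows are split into one variant per called ALT; phased
    genotypes (``1|0`` / ``0|1``) assign heterozygous variants to an allele.
    A row without genotype information is taken as homozygous.
    """
    import pysam

    out: list[Variant] = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf.fetch() if vf.index is not None else vf:
            if rec.alts is None:
                continue
            gt: tuple | None = None
            phased = False
            if len(rec.samples):
                sample = rec.samples[0]
                gt = sample.get("GT")
                phased = bool(sample.phased)
            for alt_index, alt in enumerate(rec.alts, start=1):
                if gt is not None and alt_index not in gt:
                    continue
                if gt is None or all(g == alt_index for g in gt if g is not None):
                    zyg, allele = Zygosity.HOMOZYGOUS, None
                else:
                    zyg = Zygosity.HETEROZYGOUS
                    allele = None
                    if phased and len(gt) == 2:
                        allele = 1 if gt[0] == alt_index else 2
                out.append(Variant(rec.start, rec.ref, alt, zyg, allele))
    return out


def write_variants_vcf(
    path: str | os.PathLike, variants: list[Variant], reference: Reference
) -> None:
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.contigs.add(reference.id, length=reference.length)
    header.add_sample("truth")
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for v in sorted(variants, key=lambda v: v.position):
            pos = v.position
            ref, alt = v.ref_allele, v.alt_allele
            if not ref or not alt:
                # anchor on the preceding base, VCF style
                if pos == 0:
                    raise ValueError("cannot anchor a variant at position 0 with empty REF")
                anchor = reference.sequence[pos - 1]
                ref, alt, pos = anchor + ref, anchor + alt, pos - 1
            rec = vf.new_record(
                contig=reference.id, start=pos, alleles=(ref, alt)
            )
            if not v.is_het:
                gt = (1, 1)
            elif v.allele == 2:
                gt = (0, 1)
            else:
                gt = (1, 0)
            rec.samples["truth"]["GT"] = gt
            rec.samples["truth"].phased = v.allele is not None
            vf.write(rec)


def parse_variants(source: str | os.PathLike, dialect: str = "tsv") -> list[Variant]:
    """Parse a variant file (or, for ``tsv``, raw text) in the given dialect."""
    if dialect == "vcf":
        return parse_variants_vcf(source)
    if dialect == "tsv":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        return parse_variants_tsv(text)
    raise ValueError(f"unknown dialect {dialect!r}")
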