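"""Multi-sample VCF input and parent-informative marker extraction.

A biparental doubled-haploid (DH) population descends from two fully
homozygous parents. Any biallelic site at which the parents carry different
homozygous alleles is *parent-informative*: a DH line's allele there reveals
which parent the surrounding chromosome segment came from. This module reads
a multi-sample VCF (two parents + DH lines), extracts the informative
markers, and translates each line's genotype into a parental-origin call.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from cyvcf2 import VCF

from ._util import HET, MISSING, P1, P2


@dataclass(frozen=True, order=True)
class ParentalMarker:
    """One biallelic site where the two parents are homozygous for different alleles.

    Coordinates are 1-based inclusive (VCF convention). ``p1_allele`` /
    ``p2_allele`` record which of ref/alt each parent carries.
    """

    chromosome: str
    position: int
    ref_allele: str
    alt_allele: str
    p1_allele: str
    p2_allele: str
    variant_class: str  # "SNP" or "InDel"


@dataclass(frozen=True)
class VariantRecord:
    """A VCF record reduced to what origin calling needs."""

    chromosome: str
    position: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None
    # sample -> (allele_index, allele_index); None entries are missing calls
    genotypes: dict[str, tuple[int | None, int | None]]


def read_vcf(path: str, sample_names: Sequence[str] | None = None) -> list[VariantRecord]:
    """Read a VCF (plain or bgzipped) into ordered :class:`VariantRecord` objects.

    Records are returned sorted by (chromosome, position). Multiallelic
    records pass through untouched; downstream extraction drops them.

    Parameters
    ----------
    sample_names
        If given, every name must appear in the VCF header; a missing sample
        raises ``ValueError`` naming it.
    """
    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    if sample_names is not None:
        absent = [s for s in sample_names if s not in header_samples]
        if absent:
            raise ValueError(f"sample(s) not in VCF header: {', '.join(absent)}")
    records: list[VariantRecord] = []
    for var in vcf:
        genotypes = {}
        for sample, gt in zip(header_samples, var.genotypes):
            a1, a2 = gt[0], gt[1]
            genotypes[sample] = (None if a1 < 0 else a1, None if a2 < 0 else a2)
        records.append(
            VariantRecord(
                chromosome=var.CHROM,
                position=var.POS,
                ref=var.REF,
                alts=tuple(var.ALT),
                qual=var.QUAL,
                genotypes=genotypes,
            )
        )
    vcf.close()
    records.sort(key=lambda r: (r.chromosome, r.position))
    return records


def _hom_allele(gt: tuple[int | None, int | None]) -> int | None:
    """Allele index if the genotype is homozygous non-missing, else None."""
    a1, a2 = gt
    if a1 is None or a2 is None or a1 != a2:
        return None
    return a1


def classify_variant(ref: str, alt: str) -> str:
    return "SNP" if len(ref) == 1 and len(alt) == 1 else "InDel"


def extract_informative_markers(
    records: Iterable[VariantRecord],
    p1_name: str,
    p2_name: str,
    min_qual: float = 20.0,
    snp_only: bool = False,
) -> list[ParentalMarker]:
    """Keep biallelic sites where both parents are homozygous for different alleles.

    Filters: records with QUAL below ``min_qual`` are dropped (records with no
    QUAL, e.g. simulator output, pass); ``snp_only`` additionally drops InDels.
    Output is sorted and deduplicated by (chromosome, position). Swapping the
    two parent names returns the same sites with p1/p2 alleles exchanged.
    """
    markers: dict[tuple[str, int], ParentalMarker] = {}
    for rec in records:
        if len(rec.alts) != 1:
            continue
        if rec.qual is not None and rec.qual < min_qual:
            continue
        alt = rec.alts[0]
        vclass = classify_variant(rec.ref, alt)
        if snp_only and vclass != "SNP":
            continue
        if p1_name not in rec.genotypes or p2_name not in rec.genotypes:
            continue
        a1 = _hom_allele(rec.genotypes[p1_name])
        a2 = _hom_allele(rec.genotypes[p2_name])
        if a1 is None or a2 is None or a1 == a2:
            continue
        alleles = (rec.ref, alt)
        markers[(rec.chromosome, rec.position)] = ParentalMarker(
            chromosome=rec.chromosome,
            position=rec.position,
            ref_allele=rec.ref,
            alt_allele=alt,
            p1_allele=alleles[a1],
            p2_allele=alleles[a2],
            variant_class=vclass,
        )
    return [markers[k] for k in sorted(markers)]


def call_origins(
    markers: Sequence[ParentalMarker],
    records: Iterable[VariantRecord],
    line_name: str,
) -> np.ndarray:
    """Parental-origin call per marker for one DH line.

    Homozygous for the P1 parent's allele -> P1; for the P2 allele -> P2;
    carrying one of each -> HET; anything else (missing, third allele) ->
    MISSING. Genotypes are read unphased: 0/1 and 1/0 are equivalent.
    """
    by_site = {(r.chromosome, r.position): r for r in records}
    calls = np.empty(len(markers), dtype="<U7")
    for i, m in enumerate(markers):
        rec = by_site.get((m.chromosome, m.position))
        if rec is None or line_name not in rec.genotypes:
            calls[i] = MISSING
            continue
        gt = rec.genotypes[line_name]
        if gt[0] is None or gt[1] is None:
            calls[i] = MISSING
            continue
        alleles = (rec.ref,) + rec.alts
        try:
            observed = frozenset(alleles[a] for a in gt)  # type: ignore[index]
        except IndexError:
            calls[i] = MISSING
            continue
        p1_set = frozenset((m.p1_allele,))
        p2_set = frozenset((m.p2_allele,))
        if observed == p1_set:
            calls[i] = P1
        elif observed == p2_set:
            calls[i] = P2
        elif observed == frozenset((m.p1_allele, m.p2_allele)):
            calls[i] = HET
        else:
            calls[i] = MISSING
    return calls


MARKER_TSV_COLUMNS = ["chrom", "pos", "ref", "alt", "p1_allele", "p2_allele", "class"]


def write_markers_tsv(path: str, markers: Sequence[ParentalMarker]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MARKER_TSV_COLUMNS)
        for m in markers:
            w.writerow(
                [m.chromosome, m.position, m.ref_allele, m.alt_allele,
                 m.p1_allele, m.p2_allele, m.variant_class]
            )


def read_markers_tsv(path: str) -> list[ParentalMarker]:
    out: list[ParentalMarker] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            out.append(
                ParentalMarker(
                    chromosome=row["chrom"],
                    position=int(row["pos"]),
                    ref_allele=row["ref"],
                    alt_allele=row["alt"],
                    p1_allele=row["p1_allele"],
                    p2_allele=row["p2_allele"],
                    variant_class=row["class"],
                )
            )
    return out
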