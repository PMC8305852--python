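"""Marker-phenotype co-segregation and gene x line origin matrices.

Given per-line recombinant blocks and two phenotype groups of DH lines (for
the motivating cross: high- vs low-glucosinolate), this module finds genes
and genomic regions whose parental origin *perfectly* separates the groups —
every group-A line carries one parental label across the feature, every
group-B line the other. Perfect (all-or-nothing) co-segregation is the
normative filter; a ``max_violations`` relaxation exists for exploration.

Genes are projected onto blocks by their midpoint, reproducing the
single-label-per-cell structure of a gene x line genotype table; genes whose
interval additionally overlaps a differently-labeled block are flagged as
boundary-spanning rather than split.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import HET, NA, P1, P2
from .hmm import Block, blocks_to_marker_labels
from .variants import ParentalMarker


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: 1-based inclusive coordinates plus pathway stage."""

    chromosome: str
    start: int
    stop: int
    name: str
    gene_id_v1_5: str
    gene_id_v3_0: str | None = None
    pathway_stage: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.stop:
            raise ValueError(f"gene {self.name}: start > stop")
        if not self.gene_id_v1_5 and not self.gene_id_v3_0:
            raise ValueError(f"gene {self.name}: no gene id")

    @property
    def midpoint(self) -> int:
        return (self.start + self.stop) // 2


@dataclass(frozen=True)
class GeneCall:
    label: str
    boundary: bool = False  # gene interval overlaps a block of a different label


@dataclass(frozen=True)
class CosegRegion:
    """Maximal marker run whose origin separates the two groups."""

    chromosome: str
    start: int  # bp of first marker in the run
    end: int  # bp of last marker in the run
    n_markers: int
    groupA_label: str
    groupB_label: str


def read_gene_table(path: str) -> list[GeneModel]:
    """Read genes from TSV with columns chrom, start, stop, name, gene_id_v1_5,
    gene_id_v3_0, stage (extra columns ignored)."""
    genes: list[GeneModel] = []
    with open(path, newline="") as fh:
        delim = "\t" if path.endswith((".tsv", ".txt")) else ","
        for row in csv.DictReader(fh, delimiter=delim):
            genes.append(
                GeneModel(
                    chromosome=row["chrom"],
                    start=int(row["start"]),
                    stop=int(row["stop"]),
                    name=row["name"],
                    gene_id_v1_5=row["gene_id_v1_5"],
                    gene_id_v3_0=row.get("gene_id_v3_0") or None,
                    pathway_stage=row.get("stage") or None,
                )
            )
    return genes


def assign_gene_origin(blocks: Sequence[Block], gene: GeneModel) -> GeneCall:
    """Label a gene from one line's blocks by its midpoint.

    The gene takes the label of the block containing ``(start + stop) // 2``;
    a midpoint falling in an unlabeled gap gives NA. If the gene interval
    overlaps any block of a different label the call is flagged
    boundary-spanning.
    """
    mid = gene.midpoint
    label = NA
    boundary = False
    overlapping_labels = set()
    for b in blocks:
        if b.chromosome != gene.chromosome:
            continue
        if b.start <= mid <= b.end:
            label = b.label
        if b.start <= gene.stop and b.end >= gene.start:
            overlapping_labels.add(b.label)
    if label != NA and any(l != label for l in overlapping_labels):
        boundary = True
    return GeneCall(label=label, boundary=boundary)


def build_gene_matrix(
    blocks_by_line: Mapping[str, Sequence[Block]],
    genes: Sequence[GeneModel],
    parents: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Gene x line origin matrix (rows indexed by v1.5 gene id, input order).

    ``parents`` maps parent sample name -> its own label (e.g. {"LP08": "P1"});
    parent columns are filled with that label for every gene. Genes on a
    chromosome absent from a line's block set get NA.
    """
    index = [g.gene_id_v1_5 for g in genes]
    data: dict[str, list[str]] = {}
    boundary: dict[str, list[bool]] = {}
    for line, blocks in blocks_by_line.items():
        calls = [assign_gene_origin(blocks, g) for g in genes]
        data[line] = [c.label for c in calls]
        boundary[line] = [c.boundary for c in calls]
    if parents:
        for pname, plabel in parents.items():
            data[pname] = [plabel] * len(genes)
            boundary[pname] = [False] * len(genes)
    matrix = pd.DataFrame(data, index=index)
    matrix.attrs["genes"] = list(genes)
    matrix.attrs["boundary"] = pd.DataFrame(boundary, index=index)
    return matrix


def _check_groups(columns: Iterable[str], group_a: Sequence[str], group_b: Sequence[str]) -> None:
    set_a, set_b = set(group_a), set(group_b)
    if not set_a or not set_b:
        raise ValueError("both groups must be non-empty")
    if set_a & set_b:
        raise ValueError(f"groups overlap: {sorted(set_a & set_b)}")
    missing = (set_a | set_b) - set(columns)
    if missing:
        raise ValueError(f"lines not in matrix: {sorted(missing)}")


def find_cosegregating_genes(
    matrix: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    parental_labels: tuple[str, str] | None = None,
    max_violations: int = 0,
) -> list[str]:
    """Genes whose origin perfectly separates the two groups.

    A gene qualifies when every group-A cell carries one parental label and
    every group-B cell the other, in either orientation, with no HET/NA cell.
    ``max_violations`` relaxes this to at most that many deviating cells
    (default 0: the all-or-nothing criterion). Returns row ids in input order.
    """
    _check_groups(matrix.columns, group_a, group_b)
    if parental_labels is None:
        observed = {
            v for v in matrix.values.ravel() if v not in (HET, NA) and not pd.isna(v)
        }
        if len(observed) != 2:
            if observed <= {P1, P2}:
                observed = {P1, P2}
            else:
                raise ValueError(
                    f"cannot infer the two parental labels from matrix values {sorted(observed)}"
                )
        parental_labels = tuple(sorted(observed))  # type: ignore[assignment]
    lab_x, lab_y = parental_labels
    hits: list[str] = []
    sub_a = matrix[list(group_a)]
    sub_b = matrix[list(group_b)]
    for gene_id in matrix.index:
        row_a = sub_a.loc[gene_id].to_numpy()
        row_b = sub_b.loc[gene_id].to_numpy()
        for a_label, b_label in ((lab_x, lab_y), (lab_y, lab_x)):
            violations = int(np.sum(row_a != a_label)) + int(np.sum(row_b != b_label))
            if violations <= max_violations:
                hits.append(gene_id)
                break
    return hits


def find_cosegregating_regions(
    markers: Sequence[ParentalMarker],
    blocks_by_line: Mapping[str, Sequence[Block]],
    group_a: Sequence[str],
    group_b: Sequence[str],
    min_markers: int = 10,
) -> list[CosegRegion]:
    """Maximal marker runs whose block labels separate the groups.

    Scans each chromosome's informative markers; a run of consecutive markers
    at which all group-A lines share parental label X and all group-B lines
    share Y != X becomes a region bounded by its first and last marker. Runs
    shorter than ``min_markers`` are suppressed. Swapping the groups returns
    the same regions with labels exchanged.
    """
    _check_groups(blocks_by_line.keys(), group_a, group_b)
    by_chrom: dict[str, list[ParentalMarker]] = {}
    for m in markers:
        by_chrom.setdefault(m.chromosome, []).append(m)
    regions: list[CosegRegion] = []
    for chrom, chrom_markers in by_chrom.items():
        positions = [m.position for m in chrom_markers]
        labels = {
            line: blocks_to_marker_labels(blocks_by_line[line], positions, chrom)
            for line in (*group_a, *group_b)
        }
        a_mat = np.vstack([labels[l] for l in group_a])
        b_mat = np.vstack([labels[l] for l in group_b])
        # per-marker separation state: (X, Y) if separating, else None
        run_start = None
        run_pair: tuple[str, str] | None = None
        for i in range(len(positions) + 1):
            pair = None
            if i < len(positions):
                a_vals = set(a_mat[:, i])
                b_vals = set(b_mat[:, i])
                if (
                    len(a_vals) == 1
                    and len(b_vals) == 1
                    and a_vals != b_vals
                    and not (a_vals | b_vals) & {HET, NA}
                ):
                    pair = (next(iter(a_vals)), next(iter(b_vals)))
            if pair != run_pair:
                if run_pair is not None and i - run_start >= min_markers:
                    regions.append(
                        CosegRegion(
                            chromosome=chrom,
                            start=positions[run_start],
                            end=positions[i - 1],
                            n_markers=i - run_start,
                            groupA_label=run_pair[0],
                            groupB_label=run_pair[1],
                        )
                    )
                run_start = i if pair is not None else None
                run_pair = pair
    return regions


def pathway_profile(matrix: pd.DataFrame, line: str) -> pd.DataFrame:
    """Per-pathway-stage label summary for one line.

    Returns a tidy frame with one row per (stage, label): the count of genes
    and their names, enabling stepwise pathway comparisons between lines.
    Requires the matrix to carry its gene list (as built by
    :func:`build_gene_matrix` or the fixture loader).
    """
    if line not in matrix.columns:
        raise ValueError(f"unknown line {line!r}")
    genes: list[GeneModel] = matrix.attrs.get("genes", [])
    if not genes:
        raise ValueError("matrix carries no gene annotations")
    rows: list[tuple[str, str, int, str]] = []
    by_stage: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_stage.setdefault(g.pathway_stage or "unassigned", []).append(g)
    for stage, stage_genes in by_stage.items():
        by_label: dict[str, list[str]] = {}
        for g in stage_genes:
            label = matrix.at[g.gene_id_v1_5, line]
            by_label.setdefault(label, []).append(f"{g.name}({g.gene_id_v1_5})")
        for label, names in by_label.items():
            rows.append((stage, label, len(names), ";".join(names)))
    return pd.DataFrame(rows, columns=["stage", "label", "n_genes", "genes"])


def write_matrix_csv(path: str, matrix: pd.DataFrame, coseg_ids: Sequence[str] | None = None) -> None:
    out = matrix.copy()
    if coseg_ids is not None:
        out["coseg"] = out.index.isin(set(coseg_ids))
    out.to_csv(path, index_label="gene_id_v1_5")


def write_regions_tsv(path: str, regions: Sequence[CosegRegion]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "start", "end", "n_markers", "groupA_label", "groupB_label"])
        for r in regions:
            w.writerow([r.chromosome, r.start, r.end, r.n_markers, r.groupA_label, r.groupB_label])
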