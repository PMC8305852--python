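"""Synthetic biparental doubled-haploid populations with known ground truth.

The generator emulates the data a resequenced DH population yields: two fully
homozygous parents differing at a configurable marker density, DH lines as
recombinant mosaics of the two parental genomes (Poisson crossovers, uniform
in physical coordinates), genotype observations corrupted by error and
missingness, and a block-linked quantitative phenotype ("total GSL") whose
regime is decided by the parental origin at a planted causal region.

Every output is a pure function of (config, seed); substreams are derived
deterministically per (stage, line, chromosome) so partial regeneration
reproduces identical values.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import HET, MISSING, P1, P2, ConfigError, ORIGIN_LABELS
from .variants import ParentalMarker

_BASES = "ACGT"

#: GNA-dominant compound split applied to simulated totals: gluconapin carries
#: ~85% of total glucosinolate, mirroring the 80-91% share seen in
#: high-GSL *B. rapa* leaves; the remainder spreads over minor compounds.
DEFAULT_COMPONENT_FRACTIONS: dict[str, float] = {
    "GRA": 0.010,
    "GAL": 0.040,
    "SNG": 0.005,
    "GNA": 0.850,
    "GBN": 0.050,
    "GNL": 0.002,
    "PRO": 0.008,
    "GBS": 0.005,
    "4-MOGBS": 0.005,
    "NGBS": 0.020,
    "GNT": 0.005,
}


@dataclass(frozen=True)
class CausalRegion:
    """Genomic interval whose parental origin switches the phenotype regime."""

    chromosome: str
    start: int
    end: int
    high_label: str = P1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class PhenotypeParams:
    """Two-regime total-GSL phenotype (units: umol/g dry weight).

    Defaults straddle the observed high (44.1-57.0) and low (3.3-10.8) ranges.
    """

    mean_high: float = 50.0
    sd_high: float = 5.0
    mean_low: float = 7.0
    sd_low: float = 2.0


@dataclass
class SimulationConfig:
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"A03": 10_000_000})
    marker_density: float = 1e-4  # expected markers per bp (1 per 10 kb)
    n_dh_lines: int = 50
    crossover_rate_lambda: float = 2.0  # expected crossovers per chromosome per line
    genotype_error_eps: float = 0.02
    missing_rate: float = 0.01
    residual_het_rate: float = 0.0  # ideal DH lines are fully homozygous
    indel_fraction: float = 0.1  # fraction of markers simulated as 1-3 bp indels
    causal_region: CausalRegion | None = field(
        default_factory=lambda: CausalRegion("A03", 3_000_000, 6_000_000, P1)
    )
    phenotype_params: PhenotypeParams = field(default_factory=PhenotypeParams)
    component_fractions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPONENT_FRACTIONS)
    )
    n_replicates: int = 3
    seed: int = 0

    def validate(self) -> None:
        if not self.chrom_lengths:
            raise ConfigError("chrom_lengths must name at least one chromosome")
        for chrom, length in self.chrom_lengths.items():
            if length <= 0:
                raise ConfigError(f"chromosome {chrom} has non-positive length {length}")
        if self.marker_density < 0:
            raise ConfigError("marker_density must be >= 0")
        if self.n_dh_lines < 0:
            raise ConfigError("n_dh_lines must be >= 0")
        if self.crossover_rate_lambda < 0:
            raise ConfigError("crossover_rate_lambda must be >= 0")
        for name in ("genotype_error_eps", "missing_rate", "residual_het_rate", "indel_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.genotype_error_eps + self.missing_rate > 1.0:
            raise ConfigError("genotype_error_eps + missing_rate must be <= 1")
        if self.causal_region is not None:
            cr = self.causal_region
            if cr.chromosome not in self.chrom_lengths:
                raise ConfigError(f"causal region chromosome {cr.chromosome} unknown")
            if not 1 <= cr.start <= cr.end <= self.chrom_lengths[cr.chromosome]:
                raise ConfigError("causal region outside its chromosome")
            if cr.high_label not in (P1, P2):
                raise ConfigError("causal high-origin label must be P1 or P2")
        if self.component_fractions:
            total = sum(self.component_fractions.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"component fractions sum to {total}, expected 1")


@dataclass(frozen=True)
class Segment:
    """True origin segment, 1-based inclusive bp bounds."""

    start: int
    end: int
    label: str


@dataclass
class TruthSet:
    """Ground truth of one simulated population."""

    # line -> chromosome -> contiguous segments tiling [1, length]
    segments: dict[str, dict[str, list[Segment]]]
    # line -> chromosome -> crossover positions (continuous bp)
    crossovers: dict[str, dict[str, list[float]]]
    # line -> "high" | "low" (empty when no causal region is configured)
    groups: dict[str, str]
    # lines whose causal-region origin was not a clean parental label
    flagged: set[str]

    @property
    def lines(self) -> list[str]:
        return list(self.segments)

    def label_at(self, line: str, chromosome: str, position: int) -> str:
        for seg in self.segments[line][chromosome]:
            if seg.start <= position <= seg.end:
                return seg.label
        raise ValueError(f"position {position} outside chromosome {chromosome}")

    def labels_at_markers(
        self, line: str, markers: Sequence[ParentalMarker], chromosome: str
    ) -> np.ndarray:
        segs = self.segments[line][chromosome]
        ends = np.array([s.end for s in segs])
        labels = np.array([s.label for s in segs], dtype="<U7")
        pos = np.array([m.position for m in markers if m.chromosome == chromosome])
        idx = np.searchsorted(ends, pos, side="left")
        return labels[idx]


def _stream(seed: int, *key: str | int) -> np.random.Generator:
    """Deterministic substream from one root seed and a structured key."""
    words = [seed & 0x7FFFFFFF]
    for k in key:
        words.append(zlib.crc32(str(k).encode()))
    return np.random.default_rng(words)


def _unique_positions(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    """n distinct sorted integer positions in [1, length]."""
    n = min(n, length)
    pos: set[int] = set()
    while len(pos) < n:
        draw = rng.integers(1, length + 1, size=n - len(pos))
        pos.update(int(p) for p in draw)
    return np.array(sorted(pos), dtype=np.int64)


def simulate_markers(config: SimulationConfig) -> list[ParentalMarker]:
    """Parent-informative markers at the configured density.

    Per chromosome the marker count is Poisson(length * density) and positions
    are uniform; every marker gets distinct homozygous parental alleles, a
    random parent carrying the reference.
    """
    config.validate()
    markers: list[ParentalMarker] = []
    for chrom, length in config.chrom_lengths.items():
        rng = _stream(config.seed, "markers", chrom)
        n = int(rng.poisson(length * config.marker_density))
        positions = _unique_positions(rng, n, length)
        for pos in positions:
            ref_base = _BASES[rng.integers(4)]
            if rng.random() < config.indel_fraction:
                extra = "".join(_BASES[i] for i in rng.integers(4, size=int(rng.integers(1, 4))))
                if rng.random() < 0.5:
                    ref, alt = ref_base, ref_base + extra  # insertion
                else:
                    ref, alt = ref_base + extra, ref_base  # deletion
                vclass = "InDel"
            else:
                alt = _BASES[(int(_BASES.index(ref_base)) + int(rng.integers(1, 4))) % 4]
                ref = ref_base
                vclass = "SNP"
            p1_is_ref = rng.random() < 0.5
            markers.append(
                ParentalMarker(
                    chromosome=chrom,
                    position=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    p1_allele=ref if p1_is_ref else alt,
                    p2_allele=alt if p1_is_ref else ref,
                    variant_class=vclass,
                )
            )
    return markers


def line_names(n: int) -> list[str]:
    return [f"DH{i + 1:03d}" for i in range(n)]


def _mosaic(
    rng: np.random.Generator, length: int, lam: float, het_rate: float
) -> tuple[list[Segment], list[float]]:
    n_xo = int(rng.poisson(lam))
    xo = sorted(float(x) for x in rng.uniform(1.0, float(length), size=n_xo))
    start_label = P1 if rng.random() < 0.5 else P2
    # integer segment bounds: a crossover at x separates floor(x) from floor(x)+1
    bounds = sorted({int(np.floor(x)) for x in xo if 1 <= int(np.floor(x)) < length})
    labels = [start_label]
    for _ in bounds:
        labels.append(P2 if labels[-1] == P1 else P1)
    segs: list[Segment] = []
    prev = 1
    for b, lab in zip(bounds, labels):
        segs.append(Segment(prev, b, lab))
        prev = b + 1
    segs.append(Segment(prev, length, labels[-1]))
    # regional residual heterozygosity: relabel whole segments
    if het_rate > 0:
        segs = [
            Segment(s.start, s.end, HET) if rng.random() < het_rate else s for s in segs
        ]
        # coalesce neighbours that became identical
        merged: list[Segment] = []
        for s in segs:
            if merged and merged[-1].label == s.label:
                merged[-1] = Segment(merged[-1].start, s.end, s.label)
            else:
                merged.append(s)
        segs = merged
    return segs, xo


def simulate_dh_mosaics(
    config: SimulationConfig, markers: Sequence[ParentalMarker] | None = None
) -> TruthSet:
    """Recombinant mosaics for every DH line, plus true phenotype groups.

    Crossover counts are Poisson(lambda) per chromosome, positions uniform in
    physical coordinates (no interference); the chromosome-start label is P1
    or P2 with probability 1/2 and labels alternate at crossovers. Whole
    segments are relabeled HET with probability ``residual_het_rate``.
    """
    config.validate()
    segments: dict[str, dict[str, list[Segment]]] = {}
    crossovers: dict[str, dict[str, list[float]]] = {}
    groups: dict[str, str] = {}
    flagged: set[str] = set()
    for line in line_names(config.n_dh_lines):
        segments[line] = {}
        crossovers[line] = {}
        for chrom, length in config.chrom_lengths.items():
            rng = _stream(config.seed, "mosaic", line, chrom)
            segs, xo = _mosaic(
                rng, length, config.crossover_rate_lambda, config.residual_het_rate
            )
            segments[line][chrom] = segs
            crossovers[line][chrom] = xo
        if config.causal_region is not None:
            cr = config.causal_region
            label = next(
                s.label
                for s in segments[line][cr.chromosome]
                if s.start <= cr.midpoint <= s.end
            )
            if label == cr.high_label:
                groups[line] = "high"
            else:
                groups[line] = "low"
                if label not in (P1, P2):
                    flagged.add(line)
    return TruthSet(segments=segments, crossovers=crossovers, groups=groups, flagged=flagged)


def observe_genotypes(
    truth: TruthSet,
    markers: Sequence[ParentalMarker],
    config: SimulationConfig,
) -> dict[str, dict[str, np.ndarray]]:
    """Noisy per-marker origin calls: line -> chromosome -> label array.

    Each call equals the truth with probability 1 - eps - missing_rate, is a
    uniformly chosen wrong label with probability eps, and MISSING with
    probability missing_rate.
    """
    config.validate()
    by_chrom: dict[str, list[ParentalMarker]] = {}
    for m in markers:
        by_chrom.setdefault(m.chromosome, []).append(m)
    eps, miss = config.genotype_error_eps, config.missing_rate
    calls: dict[str, dict[str, np.ndarray]] = {}
    for line in truth.lines:
        calls[line] = {}
        for chrom, chrom_markers in by_chrom.items():
            rng = _stream(config.seed, "observe", line, chrom)
            true_labels = truth.labels_at_markers(line, chrom_markers, chrom)
            n = len(true_labels)
            u = rng.random(n)
            wrong_pick = rng.integers(2, size=n)
            observed = true_labels.copy().astype("<U7")
            for i in range(n):
                if u[i] < eps:
                    others = [l for l in ORIGIN_LABELS if l != true_labels[i]]
                    observed[i] = others[wrong_pick[i]]
                elif u[i] < eps + miss:
                    observed[i] = MISSING
            calls[line][chrom] = observed
    return calls


def _gt_string(label: str, marker: ParentalMarker) -> str:
    p1_idx = 0 if marker.p1_allele == marker.ref_allele else 1
    p2_idx = 1 - p1_idx
    if label == P1:
        return f"{p1_idx}/{p1_idx}"
    if label == P2:
        return f"{p2_idx}/{p2_idx}"
    if label == HET:
        return "0/1"
    return "./."


def write_vcf(
    path: str,
    markers: Sequence[ParentalMarker],
    calls: dict[str, dict[str, np.ndarray]],
    chrom_lengths: dict[str, int],
    p1_name: str = "LP08",
    p2_name: str = "LP21",
) -> None:
    """Write markers + calls as a deterministic multi-sample VCF v4.2 (GT only)."""
    lines = list(calls)
    index_in_chrom: dict[str, int] = {}
    with open(path, "w", newline="") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=dhblocks-simulate\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join([p1_name, p2_name] + lines)
            + "\n"
        )
        for m in sorted(markers, key=lambda m: (m.chromosome, m.position)):
            i = index_in_chrom.get(m.chromosome, 0)
            index_in_chrom[m.chromosome] = i + 1
            fields = [
                m.chromosome, str(m.position), ".", m.ref_allele, m.alt_allele,
                ".", "PASS", ".", "GT",
                _gt_string(P1, m), _gt_string(P2, m),
            ]
            for line in lines:
                fields.append(_gt_string(str(calls[line][m.chromosome][i]), m))
            fh.write("\t".join(fields) + "\n")


def simulate_metabolites(truth: TruthSet, config: SimulationConfig) -> pd.DataFrame:
    """Replicate-level compound concentrations tied to the causal-region origin.

    A line whose origin at the causal midpoint equals the high-origin label
    draws each replicate's total from Normal(mean_high, sd_high), every other
    line from Normal(mean_low, sd_low); totals are clipped at zero and split
    into compounds by the configured fractions. Columns: line, replicate,
    compound, value.
    """
    config.validate()
    if config.causal_region is None:
        raise ConfigError("simulate_metabolites requires a causal region")
    pp = config.phenotype_params
    rows: list[tuple[str, int, str, float]] = []
    for line in truth.lines:
        rng = _stream(config.seed, "phenotype", line)
        high = truth.groups[line] == "high"
        mean, sd = (pp.mean_high, pp.sd_high) if high else (pp.mean_low, pp.sd_low)
        for rep in range(1, config.n_replicates + 1):
            total = max(0.0, float(rng.normal(mean, sd)))
            for compound, frac in config.component_fractions.items():
                rows.append((line, rep, compound, frac * total))
    return pd.DataFrame(rows, columns=["line", "replicate", "compound", "value"])


def truth_to_blocks(truth: TruthSet, markers: Sequence[ParentalMarker]):
    """Marker-bounded true blocks per line: the oracle the block caller chases.

    Each true segment containing at least one marker becomes a
    :class:`~dhblocks.hmm.Block` bounded by its first and last marker.
    """
    from .hmm import Block

    by_chrom: dict[str, np.ndarray] = {}
    for m in markers:
        by_chrom.setdefault(m.chromosome, [])
    for chrom in by_chrom:
        by_chrom[chrom] = np.array(
            [m.position for m in markers if m.chromosome == chrom], dtype=np.int64
        )
    out: dict[str, list] = {}
    for line in truth.lines:
        blocks = []
        for chrom, pos in by_chrom.items():
            for s in truth.segments[line][chrom]:
                inside = pos[(pos >= s.start) & (pos <= s.end)]
                if len(inside) == 0:
                    continue
                blocks.append(
                    Block(line, chrom, int(inside[0]), int(inside[-1]), s.label, len(inside), 0)
                )
        out[line] = blocks
    return out


def write_truth_bed(path: str, truth: TruthSet) -> None:
    """True segments as BED (0-based half-open): chrom, start, end, line, label."""
    with open(path, "w", newline="") as fh:
        for line in truth.lines:
            for chrom, segs in truth.segments[line].items():
                for s in segs:
                    fh.write(f"{chrom}\t{s.start - 1}\t{s.end}\t{line}\t{s.label}\n")


def write_phenotype_csv(path: str, phenotypes: pd.DataFrame) -> None:
    phenotypes.to_csv(path, index=False)


@dataclass
class SimulationResult:
    config: SimulationConfig
    markers: list[ParentalMarker]
    truth: TruthSet
    calls: dict[str, dict[str, np.ndarray]]
    phenotypes: pd.DataFrame | None


def simulate_population(config: SimulationConfig) -> SimulationResult:
    """Run the full generator: markers -> mosaics -> observed calls -> phenotypes."""
    markers = simulate_markers(config)
    truth = simulate_dh_mosaics(config, markers)
    calls = observe_genotypes(truth, markers, config)
    phenotypes = (
        simulate_metabolites(truth, config) if config.causal_region is not None else None
    )
    return SimulationResult(config, markers, truth, calls, phenotypes)
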