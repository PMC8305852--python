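"""End-to-end orchestration: simulate -> markers -> blocks -> coseg -> metabolites.

Stages communicate through files (VCF/TSV/CSV/BED) so each is independently
runnable; a run writes a machine-readable manifest (config hash, outputs) and
a human-readable summary. Identical config + seed give byte-identical outputs.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import coseg as coseg_mod
from . import hmm as hmm_mod
from . import metabolites as met_mod
from . import simulate as sim_mod
from . import variants as var_mod
from ._util import P1, P2, ConfigError

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    # either a simulation section or real input paths
    simulation: sim_mod.SimulationConfig | None = None
    vcf: str | None = None
    p1_name: str = "LP08"
    p2_name: str = "LP21"
    genes: str | None = None  # gene annotation TSV/CSV
    gene_matrix: str | None = None  # pre-computed gene x line origin matrix CSV
    metabolites: str | None = None  # concentration CSV (replicate or summary)
    groups: str | None = None  # two-column CSV: line, group
    min_qual: float = 20.0
    snp_only: bool = False
    hmm: hmm_mod.HmmParams = field(default_factory=hmm_mod.HmmParams)
    min_region_markers: int = 10
    max_violations: int = 0
    alpha: float = 0.05
    posthoc: str = "tukey"
    seed: int = 0


def _build_sim_config(section: dict, errors: list[str]) -> sim_mod.SimulationConfig | None:
    kwargs = dict(section)
    if "causal_region" in kwargs and kwargs["causal_region"] is not None:
        cr = kwargs["causal_region"]
        try:
            kwargs["causal_region"] = sim_mod.CausalRegion(
                chromosome=cr["chromosome"],
                start=int(cr["start"]),
                end=int(cr["end"]),
                high_label=cr.get("high_label", P1),
            )
        except (KeyError, TypeError, ValueError) as exc:
            errors.append(f"simulation.causal_region invalid: {exc}")
            return None
    if "phenotype_params" in kwargs and kwargs["phenotype_params"] is not None:
        try:
            kwargs["phenotype_params"] = sim_mod.PhenotypeParams(**kwargs["phenotype_params"])
        except TypeError as exc:
            errors.append(f"simulation.phenotype_params invalid: {exc}")
            return None
    try:
        cfg = sim_mod.SimulationConfig(**kwargs)
        cfg.validate()
        return cfg
    except (TypeError, ConfigError) as exc:
        errors.append(f"simulation section invalid: {exc}")
        return None


def validate_config(raw: dict) -> tuple[PipelineConfig | None, list[str]]:
    """Validate a raw (YAML-loaded) config dict; all errors are collected."""
    errors: list[str] = []
    sim_section = raw.get("simulation")
    vcf = raw.get("vcf")
    if sim_section is None and vcf is None and raw.get("gene_matrix") is None and raw.get("metabolites") is None:
        errors.append(
            "config needs a simulation section or input paths (vcf/gene_matrix/metabolites)"
        )
    sim_cfg = _build_sim_config(sim_section, errors) if sim_section is not None else None
    if vcf is not None and not Path(vcf).exists():
        errors.append(f"vcf path does not exist: {vcf}")
    for key in ("genes", "gene_matrix", "metabolites", "groups"):
        p = raw.get(key)
        if p is not None and not Path(p).exists():
            errors.append(f"{key} path does not exist: {p}")
    hmm_params = hmm_mod.HmmParams()
    hmm_section = raw.get("hmm", {})
    try:
        hmm_params = hmm_mod.HmmParams(**hmm_section)
    except (TypeError, ConfigError) as exc:
        errors.append(f"hmm section invalid: {exc}")
    alpha = raw.get("alpha", 0.05)
    if not 0 < alpha < 1:
        errors.append(f"alpha={alpha} outside (0, 1)")
    posthoc = raw.get("posthoc", "tukey")
    if posthoc not in ("tukey", "duncan"):
        errors.append(f"posthoc must be 'tukey' or 'duncan', got {posthoc!r}")
    if errors:
        return None, errors
    config = PipelineConfig(
        simulation=sim_cfg,
        vcf=vcf,
        p1_name=raw.get("p1_name", "LP08"),
        p2_name=raw.get("p2_name", "LP21"),
        genes=raw.get("genes"),
        gene_matrix=raw.get("gene_matrix"),
        metabolites=raw.get("metabolites"),
        groups=raw.get("groups"),
        min_qual=float(raw.get("min_qual", 20.0)),
        snp_only=bool(raw.get("snp_only", False)),
        hmm=hmm_params,
        min_region_markers=int(raw.get("min_region_markers", 10)),
        max_violations=int(raw.get("max_violations", 0)),
        alpha=alpha,
        posthoc=posthoc,
        seed=int(raw.get("seed", 0)),
    )
    return config, []


def load_config(path: str) -> tuple[PipelineConfig | None, list[str]]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _config_hash(config: PipelineConfig) -> str:
    def default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        return str(obj)

    blob = json.dumps(dataclasses.asdict(config), default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Run all configured stages, writing outputs under ``out_dir``.

    Returns the manifest dict (also written as ``manifest.json``). A stage
    failure raises :class:`PipelineError` naming the stage; outputs written
    so far are kept alongside a ``FAILED`` marker.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "outputs": {},
        "summary": {},
    }
    summary_lines: list[str] = []
    stage = "setup"
    t0 = time.time()
    try:
        groups_df: pd.DataFrame | None = None
        # ---- simulate ----------------------------------------------------
        if config.simulation is not None:
            stage = "simulate"
            sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
            result = sim_mod.simulate_population(sim_cfg)
            vcf_path = out / "simulated.vcf"
            sim_mod.write_vcf(
                str(vcf_path), result.markers, result.calls, sim_cfg.chrom_lengths,
                p1_name=config.p1_name, p2_name=config.p2_name,
            )
            sim_mod.write_truth_bed(str(out / "truth.bed"), result.truth)
            if result.phenotypes is not None:
                sim_mod.write_phenotype_csv(str(out / "phenotypes.csv"), result.phenotypes)
                manifest["outputs"]["phenotypes"] = "phenotypes.csv"
            groups_df = pd.DataFrame(
                {"line": list(result.truth.groups), "group": list(result.truth.groups.values())}
            )
            groups_df.to_csv(out / "groups.csv", index=False)
            config = dataclasses.replace(config, vcf=str(vcf_path))
            manifest["outputs"]["vcf"] = "simulated.vcf"
            manifest["outputs"]["truth_bed"] = "truth.bed"
            logger.info("stage simulate done (%.1fs)", time.time() - t0)

        blocks_by_line: dict[str, list[hmm_mod.Block]] = {}
        markers: list[var_mod.ParentalMarker] = []
        # ---- markers + blocks -------------------------------------------
        if config.vcf is not None:
            stage = "markers"
            records = var_mod.read_vcf(config.vcf, [config.p1_name, config.p2_name])
            markers = var_mod.extract_informative_markers(
                records, config.p1_name, config.p2_name,
                min_qual=config.min_qual, snp_only=config.snp_only,
            )
            var_mod.write_markers_tsv(str(out / "markers.tsv"), markers)
            manifest["outputs"]["markers"] = "markers.tsv"
            manifest["summary"]["n_markers"] = len(markers)
            summary_lines.append(f"informative markers: {len(markers)}")

            stage = "blocks"
            from cyvcf2 import VCF as _VCF

            all_samples = list(_VCF(config.vcf).samples)
            dh_lines = [s for s in all_samples if s not in (config.p1_name, config.p2_name)]
            by_chrom_positions: dict[str, list[int]] = {}
            for m in markers:
                by_chrom_positions.setdefault(m.chromosome, []).append(m.position)
            all_blocks: list[hmm_mod.Block] = []
            for line in dh_lines:
                calls = var_mod.call_origins(markers, records, line)
                calls_by_chrom = {}
                offset = 0
                for chrom, positions in by_chrom_positions.items():
                    n = len(positions)
                    calls_by_chrom[chrom] = (positions, calls[offset : offset + n])
                    offset += n
                line_blocks = hmm_mod.call_blocks(calls_by_chrom, config.hmm, line=line)
                blocks_by_line[line] = line_blocks
                all_blocks.extend(line_blocks)
            hmm_mod.write_blocks_tsv(str(out / "blocks.tsv"), all_blocks)
            hmm_mod.write_blocks_bed(str(out / "blocks.bed"), all_blocks)
            for chrom, positions in by_chrom_positions.items():
                hmm_mod.painting_matrix(blocks_by_line, positions, chrom).to_csv(
                    out / f"painting_{chrom}.csv", index_label="position"
                )
            manifest["outputs"]["blocks"] = "blocks.tsv"
            manifest["summary"]["n_blocks"] = len(all_blocks)
            manifest["summary"]["blocks_per_line"] = {
                line: len(b) for line, b in blocks_by_line.items()
            }
            summary_lines.append(f"blocks called: {len(all_blocks)} across {len(dh_lines)} lines")

        # ---- groups ------------------------------------------------------
        if config.groups is not None:
            groups_df = pd.read_csv(config.groups)
        group_a: list[str] = []
        group_b: list[str] = []
        if groups_df is not None:
            levels = list(dict.fromkeys(groups_df["group"]))
            if len(levels) == 2:
                group_a = [str(l) for l in groups_df.loc[groups_df["group"] == levels[0], "line"]]
                group_b = [str(l) for l in groups_df.loc[groups_df["group"] == levels[1], "line"]]

        # ---- cosegregation ----------------------------------------------
        if config.genes is not None and blocks_by_line:
            stage = "coseg"
            genes = coseg_mod.read_gene_table(config.genes)
            matrix = coseg_mod.build_gene_matrix(
                blocks_by_line, genes, parents={config.p1_name: P1, config.p2_name: P2}
            )
            coseg_ids: list[str] = []
            if group_a and group_b:
                coseg_ids = coseg_mod.find_cosegregating_genes(
                    matrix, group_a, group_b,
                    parental_labels=(P1, P2), max_violations=config.max_violations,
                )
                summary_lines.append(f"co-segregating genes: {len(coseg_ids)}")
                manifest["summary"]["coseg_genes"] = coseg_ids
            coseg_mod.write_matrix_csv(str(out / "gene_matrix.csv"), matrix, coseg_ids)
            manifest["outputs"]["gene_matrix"] = "gene_matrix.csv"
        if config.gene_matrix is not None and group_a and group_b:
            # matrix-filter mode: a pre-computed gene x line origin matrix
            # (e.g. a published table) is filtered without any block calling
            stage = "coseg-matrix"
            matrix = pd.read_csv(config.gene_matrix, index_col=0, keep_default_na=False)
            coseg_ids = coseg_mod.find_cosegregating_genes(
                matrix, group_a, group_b, max_violations=config.max_violations
            )
            coseg_mod.write_matrix_csv(str(out / "gene_matrix.csv"), matrix, coseg_ids)
            manifest["outputs"]["gene_matrix"] = "gene_matrix.csv"
            manifest["summary"]["coseg_genes"] = coseg_ids
            summary_lines.append(f"co-segregating genes: {len(coseg_ids)}")
        if markers and blocks_by_line and group_a and group_b:
            stage = "coseg-regions"
            regions = coseg_mod.find_cosegregating_regions(
                markers, blocks_by_line, group_a, group_b,
                min_markers=config.min_region_markers,
            )
            coseg_mod.write_regions_tsv(str(out / "coseg_regions.tsv"), regions)
            manifest["outputs"]["coseg_regions"] = "coseg_regions.tsv"
            manifest["summary"]["n_coseg_regions"] = len(regions)
            for r in regions:
                summary_lines.append(
                    f"co-segregating region {r.chromosome}:{r.start}-{r.end} "
                    f"({r.n_markers} markers, {r.groupA_label} vs {r.groupB_label})"
                )

        # ---- metabolites -------------------------------------------------
        met_path = config.metabolites
        if met_path is None and config.simulation is not None:
            met_path = str(out / "phenotypes.csv")
        if met_path is not None and Path(met_path).exists():
            stage = "metabolites"
            table = pd.read_csv(met_path)
            lines = [str(l) for l in table["line"].unique()]
            totals = {l: met_mod.total_concentration(table, l) for l in lines}
            report = pd.DataFrame({"line": lines, "total": [totals[l] for l in lines]})
            report.to_csv(out / "metabolite_report.csv", index=False)
            manifest["outputs"]["metabolite_report"] = "metabolite_report.csv"
            manifest["summary"]["totals"] = totals
            summary_lines.append(
                "metabolite totals: "
                + ", ".join(f"{l}={totals[l]:.2f}" for l in lines[:8])
                + ("..." if len(lines) > 8 else "")
            )

        stage = "report"
        (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
        manifest["outputs"]["summary"] = "summary.txt"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage} failed: {exc}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
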