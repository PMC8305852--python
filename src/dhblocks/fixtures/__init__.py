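"""Packaged reference tables for the motivating *Brassica rapa* cross.

Three small CSVs are shipped verbatim:

* ``table1_gsl.csv`` — leaf glucosinolate concentrations (umol/g dw,
  mean +/- sd of three biological replicates) for the reference accession,
  both parents, the F1, and eight DH lines.
* ``table3_matrix.csv`` — the published gene x line parental-origin matrix:
  76 glucosinolate-pathway genes against both parents, five high-GSL and
  three low-GSL DH lines (cells LP08/LP21).
* ``table4_hydrolysis.csv`` — glucosinolate hydrolysis products (ug/g dw) of
  the five high-GSL lines and a commercial pak choi control.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from ..coseg import GeneModel

#: DH line groups as defined by total leaf glucosinolate content.
HGSL_LINES = ["DH005", "DH014", "DH016", "DH017", "DH026"]
LGSL_LINES = ["DH009", "DH059", "DH061"]
PARENT_HIGH = "LP08"
PARENT_LOW = "LP21"


def _path(name: str):
    return resources.files(__package__).joinpath(name)


def load_table1() -> pd.DataFrame:
    """Glucosinolate summary table: line, group, compound, mean, sd.

    Not-detected entries have NaN mean/sd; totals treat them as zero.
    """
    with resources.as_file(_path("table1_gsl.csv")) as p:
        return pd.read_csv(p)


def load_table4() -> pd.DataFrame:
    """Hydrolysis-product summary table: line, group, compound, mean, sd."""
    with resources.as_file(_path("table4_hydrolysis.csv")) as p:
        return pd.read_csv(p)


def load_table3() -> pd.DataFrame:
    """Gene x line origin matrix with gene annotations in ``attrs['genes']``.

    Rows are indexed by v1.5 gene id in published order; sample columns hold
    LP08/LP21 labels. Line columns are LP08, the five HGSL lines, the three
    LGSL lines, and LP21.
    """
    with resources.as_file(_path("table3_matrix.csv")) as p:
        raw = pd.read_csv(p, keep_default_na=False)
    genes = [
        GeneModel(
            chromosome=row["chrom"],
            start=int(row["start"]),
            stop=int(row["stop"]),
            name=row["name"],
            gene_id_v1_5=row["gene_id_v1_5"],
            gene_id_v3_0=row["gene_id_v3_0"] or None,
            pathway_stage=row["stage"],
        )
        for _, row in raw.iterrows()
    ]
    sample_cols = [PARENT_HIGH] + HGSL_LINES + LGSL_LINES + [PARENT_LOW]
    matrix = raw[sample_cols].copy()
    matrix.index = raw["gene_id_v1_5"]
    matrix.index.name = "gene_id_v1_5"
    matrix.attrs["genes"] = genes
    return matrix
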