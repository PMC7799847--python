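"""Packaged reference tables.

Two small annotation tables ship with the package:

* :func:`gnomad_eas_plp_table` — the P/LP variants of BRCA1/2 reported for the
  gnomAD East-Asian subpopulation, with their 3.5KJPNv2 frequencies where the
  variant is also present in that panel.
* :func:`candidate_summary_table` — the summary of known and candidate
  pathogenic BRCA1/2 variants in the 3.5KJPNv2 panel (classes
  "InterVar P or LP", "Computational+MAF", "Benign"), with CADD_phred and
  Eigen_raw scores for the single-nucleotide variants.

Both are in the standard annotation-TSV dialect understood by
:func:`brcascreen.annotations.read_annotation_table`.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .annotations import VariantAnnotation, read_annotation_table

__all__ = [
    "gnomad_eas_plp_path",
    "candidate_summary_path",
    "gnomad_eas_plp_table",
    "candidate_summary_table",
    "candidate_summary_frame",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("brcascreen").joinpath("data", name))


def gnomad_eas_plp_path() -> Path:
    return _data_path("table1_gnomad_eas_plp.tsv")


def candidate_summary_path() -> Path:
    return _data_path("table2_candidate_summary.tsv")


def gnomad_eas_plp_table() -> list[VariantAnnotation]:
    return read_annotation_table(gnomad_eas_plp_path())


def candidate_summary_table() -> list[VariantAnnotation]:
    return read_annotation_table(candidate_summary_path())


def candidate_summary_frame() -> pd.DataFrame:
    """Raw candidate-summary table including its ``Class`` column."""
    return pd.read_csv(candidate_summary_path(), sep="\t", dtype=str, keep_default_na=False)
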