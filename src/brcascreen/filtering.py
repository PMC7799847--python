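"""Score/MAF threshold derivation and the candidate filtration cascade.

The screen derives its filter from the variants it already trusts: among the
annotated variants, those labelled P or LP by ClinVar that are single-nucleotide
(nonsynonymous or stopgain) and carry both computational scores form the
reference set.  The thresholds are then the least extreme values observed in
that set — minimum CADD_phred, minimum Eigen_raw, maximum panel allele
frequency — so every reference variant passes its own filter by construction.

The cascade proceeds in three ordered steps:

1. variants already classified P/LP by ClinVar *or* InterVar are set aside as
   known;
2. the rest are kept only if CADD_phred >= cadd_min, Eigen_raw >= eigen_min and
   MAF <= maf_max (all inclusive; a missing score or frequency fails —
   the score thresholds only speak to single-nucleotide variants);
3. keepers that ClinVar calls benign or likely benign are excluded.  The
   benign rule is applied on the MAF criterion alone when scores are absent,
   so a rare ClinVar-benign variant never surfaces as a novel candidate.

Survivors are the novel candidate pathogenic variants.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotations import PathogenicityLabel, VariantAnnotation

__all__ = [
    "FilterThresholds",
    "CascadePartition",
    "select_reference_set",
    "derive_thresholds",
    "apply_cascade",
    "protein_position_summary",
    "partition_frame",
]

_SCORED_FUNC_CLASSES = ("nonsynonymous SNV", "stopgain")


@dataclass(frozen=True)
class FilterThresholds:
    """The (CADD_min, Eigen_min, MAF_max) filter triple."""

    cadd_min: float
    eigen_min: float
    maf_max: float

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v != v or v in (float("inf"), float("-inf")):
                raise ValueError(f"{name} must be finite, got {v}")
        if not 0.0 < self.maf_max < 1.0:
            raise ValueError(f"maf_max must be in (0,1), got {self.maf_max}")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "FilterThresholds":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class CascadePartition:
    """Disjoint partition of the annotated input set (union = input)."""

    known_plp: list[VariantAnnotation]
    candidates: list[VariantAnnotation]
    benign_excluded: list[VariantAnnotation]
    remainder: list[VariantAnnotation]
    thresholds_used: FilterThresholds

    def __len__(self) -> int:
        return (
            len(self.known_plp)
            + len(self.candidates)
            + len(self.benign_excluded)
            + len(self.remainder)
        )


def select_reference_set(
    annotated: Iterable[VariantAnnotation], dataset_tag: str
) -> list[VariantAnnotation]:
    """ClinVar P/LP single-nucleotide variants with both scores and a MAF.

    These known pathogenic variants anchor the threshold derivation.  An empty
    result is an error: thresholds would be underivable.
    """
    ref = [
        a
        for a in annotated
        if a.clinvar.is_plp()
        and a.func_class in _SCORED_FUNC_CLASSES
        and a.is_single_nucleotide
        and a.cadd_phred is not None
        and a.eigen_raw is not None
        and a.maf(dataset_tag) is not None
    ]
    if not ref:
        raise ValueError(
            "reference set is empty: no ClinVar P/LP single-nucleotide variant "
            f"with CADD, Eigen and a {dataset_tag!r} frequency — thresholds underivable"
        )
    return ref


def derive_thresholds(
    reference: Sequence[VariantAnnotation], dataset_tag: str
) -> FilterThresholds:
    """Componentwise min/min/max over the reference set."""
    if not reference:
        raise ValueError("reference set is empty")
    for a in reference:
        if a.cadd_phred is None or a.eigen_raw is None or a.maf(dataset_tag) is None:
            raise ValueError(f"reference variant {a.key.key} is missing a score or MAF")
    return FilterThresholds(
        cadd_min=min(a.cadd_phred for a in reference),
        eigen_min=min(a.eigen_raw for a in reference),
        maf_max=max(a.maf(dataset_tag) for a in reference),
    )


def apply_cascade(
    annotated: Iterable[VariantAnnotation],
    thresholds: FilterThresholds,
    dataset_tag: str,
) -> CascadePartition:
    """Run the three-step filtration cascade."""
    known, candidates, benign, remainder = [], [], [], []
    for a in annotated:
        if a.clinvar.is_plp() or a.intervar.is_plp():
            known.append(a)
            continue
        maf = a.maf(dataset_tag)
        maf_ok = maf is not None and maf <= thresholds.maf_max
        scores_ok = (
            a.cadd_phred is not None
            and a.eigen_raw is not None
            and a.cadd_phred >= thresholds.cadd_min
            and a.eigen_raw >= thresholds.eigen_min
        )
        if a.clinvar.is_benign():
            # benign exclusion is keyed to the ClinVar label only and applies
            # whether or not scores are printed, provided the variant is rare
            # enough to have entered the filter at all
            if maf_ok:
                benign.append(a)
            else:
                remainder.append(a)
        elif scores_ok and maf_ok:
            candidates.append(a)
        else:
            remainder.append(a)
    return CascadePartition(known, candidates, benign, remainder, thresholds)


_AA_POS = re.compile(r"^p\.(?:[A-Z][a-z]{2}|[A-Z*])(\d+)", re.ASCII)

_FUNC_CODE = {
    "frameshift deletion": "F",
    "frameshift insertion": "F",
    "nonsynonymous SNV": "N",
    "splicing": "S",
    "stopgain": "X",
}


def protein_position_summary(
    annotated: Iterable[VariantAnnotation],
) -> pd.DataFrame:
    """Per-gene (protein position, consequence code, count) table.

    Consequence codes: F frameshift, N nonsynonymous, S splicing, X stopgain —
    the lollipop-plot vocabulary.  Records without a protein change string
    (splice-region variants) are skipped; an unparseable string is an error.
    """
    rows = []
    for a in annotated:
        if a.aa_change is None:
            continue
        m = _AA_POS.match(a.aa_change)
        if not m:
            raise ValueError(f"cannot parse protein change {a.aa_change!r}")
        code = _FUNC_CODE.get(a.func_class)
        if code is None:
            raise ValueError(f"no consequence code for functional class {a.func_class!r}")
        rows.append({"gene": a.gene, "position": int(m.group(1)), "consequence": code})
    df = pd.DataFrame(rows, columns=["gene", "position", "consequence"])
    return (
        df.groupby(["gene", "position", "consequence"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["gene", "position"], ignore_index=True)
    )


_CLASS_NAMES = {
    "known_plp": "InterVar P or LP",
    "candidates": "Computational+MAF",
    "benign_excluded": "Benign",
    "remainder": "Remainder",
}


def partition_frame(partition: CascadePartition, dataset_tag: str) -> pd.DataFrame:
    """Flatten a cascade partition into a table with a ``Class`` column."""
    rows = []
    for attr, label in _CLASS_NAMES.items():
        for a in getattr(partition, attr):
            rows.append(
                {
                    "Class": label,
                    "Chr": a.key.chrom,
                    "Start": a.key.start,
                    "End": a.key.end,
                    "Ref": a.key.ref,
                    "Alt": a.key.alt,
                    "Gene.refGene": a.gene,
                    "Func.refGene": a.func_class,
                    "AAChange": a.aa_change or ".",
                    "Clinvar": a.clinvar.value,
                    "InterVar": a.intervar.value,
                    dataset_tag: a.maf(dataset_tag),
                    "CADD": a.cadd_phred,
                    "Eigen": a.eigen_raw,
                }
            )
    return pd.DataFrame(rows)
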