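"""Annotation tables and clinical-classification harmonization.

ClinVar and InterVar emit classification strings in several dialects
("Pathogenic/Likely_pathogenic", "LP", "Conflicting interpretations of
pathogenicity", ...).  :func:`parse_class` maps them onto a controlled
vocabulary; anything outside the known dialects is an error rather than a
silent UNKNOWN, so novel upstream strings surface immediately.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .variants import TrimmedVariant

__all__ = [
    "PathogenicityLabel",
    "VariantAnnotation",
    "parse_class",
    "read_annotation_table",
    "join_annotations",
    "JoinResult",
]


class PathogenicityLabel(enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    PATHOGENIC_OR_LIKELY_PATHOGENIC = "PATHOGENIC_OR_LIKELY_PATHOGENIC"
    UNCERTAIN = "UNCERTAIN"
    CONFLICTING = "CONFLICTING"
    UNKNOWN = "UNKNOWN"
    LIKELY_BENIGN = "LIKELY_BENIGN"
    BENIGN = "BENIGN"

    def is_plp(self) -> bool:
        """True for pathogenic / likely-pathogenic (any tier)."""
        return self in (
            PathogenicityLabel.PATHOGENIC,
            PathogenicityLabel.LIKELY_PATHOGENIC,
            PathogenicityLabel.PATHOGENIC_OR_LIKELY_PATHOGENIC,
        )

    def is_benign(self) -> bool:
        return self in (PathogenicityLabel.BENIGN, PathogenicityLabel.LIKELY_BENIGN)


_CLASS_MAP = {
    "pathogenic": PathogenicityLabel.PATHOGENIC,
    "p": PathogenicityLabel.PATHOGENIC,
    "likely_pathogenic": PathogenicityLabel.LIKELY_PATHOGENIC,
    "likely pathogenic": PathogenicityLabel.LIKELY_PATHOGENIC,
    "lp": PathogenicityLabel.LIKELY_PATHOGENIC,
    "pathogenic/likely_pathogenic": PathogenicityLabel.PATHOGENIC_OR_LIKELY_PATHOGENIC,
    "pathogenic/likely pathogenic": PathogenicityLabel.PATHOGENIC_OR_LIKELY_PATHOGENIC,
    "p/lp": PathogenicityLabel.PATHOGENIC_OR_LIKELY_PATHOGENIC,
    "vus": PathogenicityLabel.UNCERTAIN,
    "uncertain significance": PathogenicityLabel.UNCERTAIN,
    "uncertain_significance": PathogenicityLabel.UNCERTAIN,
    "unk": PathogenicityLabel.UNKNOWN,
    ".": PathogenicityLabel.UNKNOWN,
    "": PathogenicityLabel.UNKNOWN,
    "likely_benign": PathogenicityLabel.LIKELY_BENIGN,
    "likely benign": PathogenicityLabel.LIKELY_BENIGN,
    "benign": PathogenicityLabel.BENIGN,
    "benign / little clinical significance": PathogenicityLabel.BENIGN,
}


def parse_class(raw: str | None) -> PathogenicityLabel:
    """Harmonize a ClinVar/InterVar classification string.

    Case-insensitive; any string starting with "Conflicting" maps to
    CONFLICTING; an unrecognized token raises ``ValueError`` naming it.
    """
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return PathogenicityLabel.UNKNOWN
    token = str(raw).strip().lower()
    if token.startswith("conflicting"):
        return PathogenicityLabel.CONFLICTING
    try:
        return _CLASS_MAP[token]
    except KeyError:
        raise ValueError(f"unrecognized pathogenicity class {raw!r}") from None


@dataclass
class VariantAnnotation:
    """Scores, functional class, and harmonized labels for one trimmed variant."""

    key: TrimmedVariant
    gene: str
    func_class: str
    aa_change: str | None
    clinvar: PathogenicityLabel
    intervar: PathogenicityLabel
    cadd_phred: float | None = None
    eigen_raw: float | None = None
    dann_rank: float | None = None
    freqs: dict[str, float] = field(default_factory=dict)

    def maf(self, dataset_tag: str) -> float | None:
        return self.freqs.get(dataset_tag)

    @property
    def is_single_nucleotide(self) -> bool:
        return (
            len(self.key.ref) == 1
            and len(self.key.alt) == 1
            and self.key.ref != "-"
            and self.key.alt != "-"
        )


_MANDATORY = [
    "Chr", "Start", "End", "Ref", "Alt",
    "Gene.refGene", "Func.refGene", "Clinvar", "InterVar",
]
_SCORE_COLUMNS = {"CADD": "cadd_phred", "Eigen": "eigen_raw", "DANN": "dann_rank"}
_NON_FREQ = set(_MANDATORY) | set(_SCORE_COLUMNS) | {"AAChange", "Class", "OncoKB", "BRCA_Exchange"}

# tolerate the "6.41.E-04" scientific-notation dialect seen in annotation exports
_DOT_E = re.compile(r"\.(?=[eE][+-]?\d)")


def _parse_float(cell, row_idx: int, column: str) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    s = str(cell).strip()
    if s in (".", "", "NA"):
        return None
    try:
        return float(s)
    except ValueError:
        pass
    try:
        return float(_DOT_E.sub("", s))
    except ValueError:
        raise ValueError(
            f"row {row_idx}: cannot parse {column}={cell!r} as a number"
        ) from None


def read_annotation_table(path: str | Path) -> list[VariantAnnotation]:
    """Parse an annotation TSV into :class:`VariantAnnotation` records.

    Dialect: tab-separated, ``.`` for missing, mandatory columns
    Chr/Start/End/Ref/Alt/Gene.refGene/Func.refGene/Clinvar/InterVar, optional
    AAChange/CADD/Eigen/DANN, and one frequency column per dataset tag
    (any remaining column, e.g. ``3.5KJPN`` or ``gnomAD_EAS``).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")
    freq_cols = [c for c in df.columns if c not in _NON_FREQ]
    out: list[VariantAnnotation] = []
    for i, row in enumerate(df.itertuples(index=False)):
        r = dict(zip(df.columns, row))
        key = TrimmedVariant(r["Chr"], int(r["Start"]), int(r["End"]), r["Ref"], r["Alt"])
        aa = r.get("AAChange", ".")
        aa = None if aa in (".", "", "NA") else aa
        scores = {
            attr: _parse_float(r.get(col, "."), i, col)
            for col, attr in _SCORE_COLUMNS.items()
        }
        freqs = {}
        for col in freq_cols:
            f = _parse_float(r.get(col, "."), i, col)
            if f is not None:
                freqs[col] = f
        out.append(
            VariantAnnotation(
                key=key,
                gene=r["Gene.refGene"].strip("*"),
                func_class=r["Func.refGene"],
                aa_change=aa,
                clinvar=parse_class(r["Clinvar"]),
                intervar=parse_class(r["InterVar"]),
                freqs=freqs,
                **scores,
            )
        )
    return out


@dataclass
class JoinResult:
    annotated: list[tuple[TrimmedVariant, VariantAnnotation]]
    unmatched_variants: list[TrimmedVariant]
    unused_annotations: int


def join_annotations(
    variants: Iterable[TrimmedVariant],
    table: Iterable[VariantAnnotation],
) -> JoinResult:
    """Exact-key join of annotations onto variants.

    Keys are ``(chrom, start, end, ref, alt)``.  Variants without a matching
    annotation go to the unmatched report; annotations without a variant are
    counted but otherwise ignored.  Duplicate annotation keys with conflicting
    content are an error.
    """
    index: dict[tuple, VariantAnnotation] = {}
    for ann in table:
        prev = index.get(ann.key.key)
        if prev is not None and prev != ann:
            raise ValueError(f"conflicting duplicate annotation for key {ann.key.key}")
        index[ann.key.key] = ann
    annotated, unmatched = [], []
    used = set()
    for v in variants:
        ann = index.get(v.key)
        if ann is None:
            unmatched.append(v)
        else:
            annotated.append((v, ann))
            used.add(v.key)
    return JoinResult(
        annotated=annotated,
        unmatched_variants=unmatched,
        unused_annotations=len(set(index) - used),
    )
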