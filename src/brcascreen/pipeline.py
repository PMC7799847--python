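"""End-to-end orchestration: normalize → extract → annotate → filter → report.

Also hosts ``verify_fixture_tables``, the regression mode that recomputes the
packaged-table summary numbers (P/LP count, accumulated frequency, per-person
rate, thresholds, candidate count, cross-panel overlap) from the shipped
fixtures.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import popstats
from .annotations import VariantAnnotation, join_annotations, read_annotation_table
from .datasets import candidate_summary_table, gnomad_eas_plp_table
from .famhist import family_history_screen, qc_records
from .filtering import (
    CascadePartition,
    FilterThresholds,
    apply_cascade,
    derive_thresholds,
    partition_frame,
    protein_position_summary,
    select_reference_set,
)
from .variants import (
    BRCA1_REGION,
    BRCA2_REGION,
    FastaReference,
    RegionSpec,
    extract_region,
    normalize,
    read_sites_vcf,
    to_trimmed,
)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "verify_fixture_tables"]

logger = logging.getLogger("brcascreen")

# panel and questionnaire-cohort sizes of the emulated study population
DEFAULT_PANEL_SIZE = 3552


@dataclass
class PipelineConfig:
    """Configuration for one full analysis run."""

    annotations: Path
    output_dir: Path
    sites_vcf: Path | None = None
    reference_fasta: Path | None = None
    questionnaire: Path | None = None
    dataset_tag: str = "3.5KJPN"
    n_individuals: int = DEFAULT_PANEL_SIZE
    regions: list[RegionSpec] = field(
        default_factory=lambda: [BRCA1_REGION, BRCA2_REGION]
    )
    thresholds: FilterThresholds | None = None  # None -> derive from data
    carrier_definition: str = "union"  # known_plp | candidates | union
    famhx_categories: Sequence[str] = (
        "self", "father", "mother", "brother", "sister", "offspring", "spouse",
        "any_family",
    )

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for p in (self.annotations, self.sites_vcf, self.reference_fasta, self.questionnaire):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.carrier_definition not in ("known_plp", "candidates", "union"):
            raise ValueError(f"unknown carrier definition {self.carrier_definition!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "regions" in raw:
            raw["regions"] = [RegionSpec(**r) for r in raw["regions"]]
        if "thresholds" in raw and raw["thresholds"] is not None:
            raw["thresholds"] = FilterThresholds(**raw["thresholds"])
        for key in ("annotations", "output_dir", "sites_vcf", "reference_fasta", "questionnaire"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(**raw)


@dataclass
class PipelineReport:
    thresholds: FilterThresholds
    partition_sizes: dict[str, int]
    summary: dict
    famhx: pd.DataFrame | None

    def to_json(self) -> str:
        payload = {
            "thresholds": asdict(self.thresholds),
            "partition_sizes": self.partition_sizes,
            "summary": self.summary,
        }
        if self.famhx is not None:
            payload["famhx"] = self.famhx.to_dict(orient="records")
        return json.dumps(payload, indent=2, default=float)


def _stage(name: str, n_in: int, n_out: int) -> None:
    logger.info("%s: %d in, %d out", name, n_in, n_out)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run the full screen and write the report bundle into ``output_dir``."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.dataset_tag

    table = read_annotation_table(config.annotations)
    _stage("read_annotation_table", 0, len(table))

    if config.sites_vcf is not None:
        if config.reference_fasta is None:
            raise ValueError("sites_vcf given without reference_fasta for normalization")
        ref_seq = FastaReference(config.reference_fasta)
        raw = read_sites_vcf(config.sites_vcf, dataset_tag=tag)
        normalized = [normalize(v, ref_seq) for v in raw]
        in_region = [
            v for region in config.regions for v in extract_region(normalized, region)
        ]
        _stage("normalize+extract", len(raw), len(in_region))
        trimmed = [to_trimmed(v) for v in in_region]
        join = join_annotations(trimmed, table)
        annotated = [ann for _, ann in join.annotated]
        _stage("join_annotations", len(trimmed), len(annotated))
        if join.unmatched_variants:
            logger.warning("%d variants had no annotation", len(join.unmatched_variants))
    else:
        annotated = list(table)

    if not annotated:
        empty = PipelineReport(
            thresholds=config.thresholds or FilterThresholds(0.0, 0.0, 0.5),
            partition_sizes={"known_plp": 0, "candidates": 0, "benign_excluded": 0, "remainder": 0},
            summary={"n_variants": 0, "plp_count": 0},
            famhx=None,
        )
        (out / "report.json").write_text(empty.to_json() + "\n")
        return empty

    if config.thresholds is None:
        reference = select_reference_set(annotated, tag)
        thresholds = derive_thresholds(reference, tag)
        _stage("derive_thresholds", len(annotated), len(reference))
    else:
        thresholds = config.thresholds
    thresholds.to_json(out / "thresholds.json")

    partition = apply_cascade(annotated, thresholds, tag)
    sizes = {
        "known_plp": len(partition.known_plp),
        "candidates": len(partition.candidates),
        "benign_excluded": len(partition.benign_excluded),
        "remainder": len(partition.remainder),
    }
    _stage("apply_cascade", len(annotated), sizes["candidates"])
    partition_frame(partition, tag).to_csv(out / "partition.tsv", sep="\t", index=False)

    clinvar_plp = [a for a in annotated if a.clinvar.is_plp()]
    plp_freqs = [a.maf(tag) for a in clinvar_plp if a.maf(tag) is not None]
    summary = {
        "n_variants": len(annotated),
        "dataset_tag": tag,
        "n_individuals": config.n_individuals,
        "plp_count": len(clinvar_plp),
        "plp_rate": popstats.plp_rate(len(clinvar_plp), config.n_individuals),
        "accumulated_frequency": popstats.accumulated_frequency(plp_freqs),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    lollipop = protein_position_summary(
        partition.known_plp + partition.candidates
    )
    lollipop.to_csv(out / "lollipop.tsv", sep="\t", index=False)

    famhx = None
    if config.questionnaire is not None:
        records = pd.read_csv(
            config.questionnaire, sep="\t", dtype={"participant_id": str}
        )
        if "carrier" not in records.columns:
            raise ValueError("questionnaire table lacks a 'carrier' column")
        kept, qc = qc_records(records)
        _stage("qc_records", len(records), len(kept))
        famhx = family_history_screen(kept, categories=config.famhx_categories)
        famhx.to_csv(out / "famhx.tsv", sep="\t", index=False)

    report = PipelineReport(thresholds, sizes, summary, famhx)
    (out / "report.json").write_text(report.to_json() + "\n")
    return report


def verify_fixture_tables() -> dict:
    """Recompute the packaged-table regression numbers.

    Returns the P/LP census of the candidate-summary fixture, the derived
    thresholds, the cascade partition sizes, the per-person rate and
    accumulated frequency at the panel size of 3,552, and the cross-panel
    overlap count from the gnomAD-EAS fixture.
    """
    tag = "3.5KJPN"
    table2 = candidate_summary_table()
    table1 = gnomad_eas_plp_table()

    clinvar_plp = [a for a in table2 if a.clinvar.is_plp()]
    freqs = [a.maf(tag) for a in clinvar_plp if a.maf(tag) is not None]
    reference = select_reference_set(table2, tag)
    thresholds = derive_thresholds(reference, tag)
    partition = apply_cascade(table2, thresholds, tag)
    overlap = [a.key for a in table1 if a.maf(tag) is not None]

    rate = popstats.plp_rate(len(clinvar_plp), DEFAULT_PANEL_SIZE)
    return {
        "clinvar_plp_count": len(clinvar_plp),
        "accumulated_frequency": popstats.accumulated_frequency(freqs),
        "plp_rate": rate,
        "plp_rate_3sf": popstats.sig_trunc(rate, 3),
        "thresholds": asdict(thresholds),
        "n_reference": len(reference),
        "candidates": len(partition.candidates),
        "benign_excluded": len(partition.benign_excluded),
        "known_plp": len(partition.known_plp),
        "gnomad_eas_overlap": len(overlap),
    }
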