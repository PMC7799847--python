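"""Synthetic cohort generator.

Real population panels and cohort questionnaires are access-restricted, so the
package ships a generator that emulates their statistical structure end to
end: a reference sequence, a site-only frequency VCF (with deliberately
injected multi-allelic and right-shifted indel representations to exercise
normalization), per-participant genotypes in Hardy–Weinberg proportions, an
annotation table whose score distributions separate pathogenic-like from
benign-like variants, and a self-reported cancer-history questionnaire in
which female first-degree relatives of carriers show elevated positive rates.

Every latent assignment (variant class, sampled scores, carrier ids, planted
over-limit questionnaire records) is recorded in a truth JSON so downstream
recovery can be checked exactly.  A fixed seed makes the whole bundle
byte-identical across runs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotations import read_annotation_table
from .famhist import (
    CATEGORIES,
    Contingency2x2,
    fisher_exact,
    yates_chi2,
)
from .variants import (
    GenomicVariant,
    RegionSpec,
    ReferenceWindow,
    TrimmedVariant,
    normalize,
    to_trimmed,
)

__all__ = [
    "ScoreModel",
    "PhenotypeModel",
    "VariantPlan",
    "SimulationConfig",
    "SimBundle",
    "default_config",
    "generate",
    "end_to_end_recovery",
    "carrier_probability",
    "sister_rejection_rate",
]

TrueClass = Literal["PLP", "CANDIDATE_LIKE", "BENIGN_LIKE", "NEUTRAL"]

CANCER_SITES = [
    "stomach", "colon", "rectum", "liver", "gallbladder", "pancreas", "lung",
    "breast", "ovary", "cervix", "uterus", "endometrium", "prostate", "testis",
    "penis", "vulva", "esophagus", "kidney", "bladder", "thyroid", "leukemia",
    "lymphoma", "myeloma", "brain", "skin", "melanoma", "oral", "pharynx",
    "larynx", "small_intestine", "bone", "soft_tissue", "adrenal",
    "mesothelioma", "eye", "salivary", "nasal", "anus", "other",
]
FEMALE_ONLY = {"ovary", "cervix", "uterus", "endometrium", "vulva"}
MALE_ONLY = {"prostate", "testis", "penis"}


def default_catalogue(size: int = 269) -> list[tuple[str, str]]:
    """(category, site) item catalogue of the malignant-neoplasm section."""
    items = list(product(CATEGORIES, CANCER_SITES))
    if size > len(items):
        raise ValueError(f"catalogue size {size} exceeds {len(items)} available items")
    return items[:size]


@dataclass(frozen=True)
class ScoreModel:
    """Truncated-normal score distributions for one variant class."""

    cadd_mean: float
    cadd_sd: float
    cadd_min: float
    eigen_mean: float
    eigen_sd: float

    def sample(self, rng: np.random.Generator) -> tuple[float, float]:
        a = (self.cadd_min - self.cadd_mean) / self.cadd_sd
        cadd = float(
            stats.truncnorm.rvs(
                a, np.inf, loc=self.cadd_mean, scale=self.cadd_sd, random_state=rng
            )
        )
        eigen = float(rng.normal(self.eigen_mean, self.eigen_sd))
        return round(cadd, 3), round(eigen, 3)


# deleterious vs neutral defaults: chosen so a min/min threshold regime over a
# handful of known-pathogenic variants lands in a realistic CADD ~25 / Eigen
# ~0.5 corner, well separated from the neutral bulk
DEFAULT_SCORE_MODELS: dict[str, ScoreModel] = {
    "PLP": ScoreModel(33.0, 5.0, 20.0, 0.75, 0.12),
    "CANDIDATE_LIKE": ScoreModel(33.0, 5.0, 20.0, 0.75, 0.12),
    "BENIGN_LIKE": ScoreModel(10.0, 6.0, 0.0, -0.2, 0.3),
    "NEUTRAL": ScoreModel(10.0, 6.0, 0.0, -0.2, 0.3),
}


@dataclass(frozen=True)
class PhenotypeModel:
    """Per-category baseline positive probabilities and carrier relative risks.

    Baselines approximate self-reported lifetime cancer-history rates in a
    middle-aged population cohort (fathers report most, offspring least).
    The relative risk applies to carriers for the listed categories only.
    """

    baseline: dict[str, float] = field(
        default_factory=lambda: {
            "self": 0.04,
            "father": 0.14,
            "mother": 0.10,
            "brother": 0.05,
            "sister": 0.05,
            "offspring": 0.01,
            "spouse": 0.06,
        }
    )
    relative_risk: dict[str, float] = field(
        default_factory=lambda: {"sister": 3.0, "offspring": 2.0}
    )

    def positive_prob(self, category: str, carrier: bool) -> float:
        p = self.baseline[category]
        if carrier:
            p *= self.relative_risk.get(category, 1.0)
        return min(p, 1.0)


@dataclass(frozen=True)
class VariantPlan:
    """One planted variant: location class, population AF, and truth class."""

    chrom: str
    af: float
    true_class: str
    kind: Literal["snv", "del", "ins"] = "snv"
    func_class: str = "nonsynonymous SNV"


def _default_variant_spec() -> list[VariantPlan]:
    # mirrors the screened panel's composition: ten known P/LP (half of them
    # frameshift indels without scores), seven rare candidate-like VUS, one
    # rare benign, and a neutral background including common variation
    plp_snv = [
        VariantPlan("13", 0.0001, "PLP", "snv", "stopgain"),
        VariantPlan("13", 0.0003, "PLP", "snv", "stopgain"),
        VariantPlan("13", 0.0001, "PLP", "snv", "nonsynonymous SNV"),
        VariantPlan("17", 0.0001, "PLP", "snv", "nonsynonymous SNV"),
        VariantPlan("17", 0.0003, "PLP", "snv", "stopgain"),
    ]
    plp_indel = [
        VariantPlan("13", 0.0001, "PLP", "del", "frameshift deletion"),
        VariantPlan("13", 0.0003, "PLP", "del", "frameshift deletion"),
        VariantPlan("13", 0.0001, "PLP", "ins", "frameshift insertion"),
        VariantPlan("17", 0.0001, "PLP", "del", "frameshift deletion"),
        VariantPlan("17", 0.0003, "PLP", "ins", "frameshift insertion"),
    ]
    candidates = [
        VariantPlan("13", 0.0001, "CANDIDATE_LIKE"),
        VariantPlan("13", 0.0001, "CANDIDATE_LIKE"),
        VariantPlan("13", 0.0003, "CANDIDATE_LIKE"),
        VariantPlan("13", 0.0001, "CANDIDATE_LIKE"),
        VariantPlan("17", 0.0001, "CANDIDATE_LIKE"),
        VariantPlan("17", 0.0003, "CANDIDATE_LIKE"),
        VariantPlan("17", 0.0001, "CANDIDATE_LIKE"),
    ]
    benign = [VariantPlan("13", 0.0001, "BENIGN_LIKE")]
    neutral_afs = [
        0.0001, 0.0002, 0.0003, 0.0005, 0.001, 0.002, 0.005, 0.01, 0.02, 0.05,
        0.0001, 0.0003, 0.001, 0.003, 0.008, 0.015, 0.0002, 0.0004, 0.006, 0.03,
    ]
    neutral = [
        VariantPlan("13" if i % 2 == 0 else "17", af, "NEUTRAL")
        for i, af in enumerate(neutral_afs)
    ]
    neutral += [  # two indels in the neutral background
        VariantPlan("13", 0.004, "NEUTRAL", "del", "frameshift deletion"),
        VariantPlan("17", 0.002, "NEUTRAL", "ins", "frameshift insertion"),
    ]
    return plp_snv + plp_indel + candidates + benign + neutral


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle.

    Defaults emulate the questionnaire cohort scale (35,199 participants, the
    >50-item QC rule removing ~63 records) with a variant panel mirroring the
    screened composition.  ``seed`` fixes all randomness.
    """

    seed: int = 0
    n_participants: int = 35_199
    variant_spec: list[VariantPlan] = field(default_factory=_default_variant_spec)
    score_model: dict[str, ScoreModel] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_MODELS)
    )
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel)
    qc_noise: float = 0.0018
    contradiction_rate: float = 0.0005
    item_catalogue_size: int = 269
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"13": 12_000, "17": 12_000}
    )
    regions: list[RegionSpec] = field(
        default_factory=lambda: [
            RegionSpec("13", 2_001, 11_000),
            RegionSpec("17", 2_001, 11_000),
        ]
    )
    multiallelic_pairs: int = 2
    unnormalized_rate: float = 0.3
    dataset_tag: str = "SIMPANEL"

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        for plan in self.variant_spec:
            if not 0.0 < plan.af < 1.0:
                raise ValueError(f"allele frequency must be in (0,1), got {plan.af}")
            if plan.true_class not in DEFAULT_SCORE_MODELS:
                raise ValueError(f"unknown true class {plan.true_class!r}")
        for p in (self.qc_noise, self.contradiction_rate, self.unnormalized_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        for rr in self.phenotype_model.relative_risk.values():
            if rr < 0:
                raise ValueError(f"relative risk must be >= 0, got {rr}")
        for p in self.phenotype_model.baseline.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"baseline probability out of [0,1]: {p}")


@dataclass
class SimBundle:
    """Paths of one generated bundle plus the loaded truth record."""

    reference_fasta: Path
    sites_vcf: Path
    genotypes_vcf: Path
    annotation_tsv: Path
    questionnaire_tsv: Path
    truth_json: Path
    truth: dict


def default_config(**overrides) -> SimulationConfig:
    cfg = SimulationConfig(**overrides)
    cfg.validate()
    return cfg


def carrier_probability(config: SimulationConfig) -> float:
    """P(participant carries >= 1 alternate allele of a PLP/CANDIDATE variant)."""
    p_none = 1.0
    for plan in config.variant_spec:
        if plan.true_class in ("PLP", "CANDIDATE_LIKE"):
            p_none *= (1.0 - plan.af) ** 2
    return 1.0 - p_none


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------

_AA = "ARNDCQEGHILKMFPSTWYV"


def _make_reference(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    bases = np.array(list("ACGT"))
    return {
        chrom: "".join(bases[rng.integers(0, 4, size=length)])
        for chrom, length in sorted(config.chrom_lengths.items())
    }


def _place_variants(
    config: SimulationConfig, rng: np.random.Generator, reference: dict[str, str]
) -> list[dict]:
    """Assign positions, alleles, scores and labels to each planned variant."""
    regions = {r.chrom: r for r in config.regions}
    by_chrom: dict[str, list[int]] = {}
    placed: list[dict] = []
    for idx, plan in enumerate(config.variant_spec):
        region = regions[plan.chrom]
        seq = reference[plan.chrom]
        taken = by_chrom.setdefault(plan.chrom, [])
        while True:  # keep loci >= 12 bp apart so indels never overlap
            pos = int(rng.integers(region.start + 1, region.end - 10))
            if all(abs(pos - t) >= 12 for t in taken):
                taken.append(pos)
                break
        ref_base = seq[pos - 1]
        if plan.kind == "snv":
            alt = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            ref = ref_base
        elif plan.kind == "del":
            del_len = int(rng.integers(1, 5))
            ref = seq[pos - 1 : pos + del_len]
            alt = ref_base
        else:  # insertion
            ins_len = int(rng.integers(1, 5))
            ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=ins_len)])
            ref = ref_base
            alt = ref_base + ins
        model = config.score_model[plan.true_class]
        if plan.kind == "snv":
            cadd, eigen = model.sample(rng)
        else:
            cadd = eigen = None  # computational scores cover SNVs only
        clinvar, intervar = {
            "PLP": ("Pathogenic", "Pathogenic"),
            "CANDIDATE_LIKE": ("VUS", "VUS"),
            "BENIGN_LIKE": ("Likely benign", "Benign"),
            "NEUTRAL": ("UNK", "UNK"),
        }[plan.true_class]
        prot_pos = 10 * (idx + 1)
        aa_ref = _AA[int(rng.integers(0, len(_AA)))]
        if plan.func_class == "stopgain":
            aa_change = f"p.{aa_ref}{prot_pos}X"
        elif plan.func_class.startswith("frameshift"):
            aa_change = f"p.{aa_ref}{prot_pos}fs"
        else:
            aa_alt = _AA[int(rng.integers(0, len(_AA)))]
            aa_change = f"p.{aa_ref}{prot_pos}{aa_alt}"
        window = ReferenceWindow(plan.chrom, seq)
        variant = normalize(
            GenomicVariant(plan.chrom, pos, ref, alt), window, window=pos
        )
        placed.append(
            {
                "plan": plan,
                "variant": variant,
                "trimmed": to_trimmed(variant),
                "cadd": cadd,
                "eigen": eigen,
                "clinvar": clinvar,
                "intervar": intervar,
                "aa_change": aa_change,
                "gene": "BRCA2" if plan.chrom == "13" else "BRCA1",
                "multiallelic": False,
            }
        )
    _inject_multiallelic(placed, config, rng)
    return placed


def _inject_multiallelic(
    placed: list[dict], config: SimulationConfig, rng: np.random.Generator
) -> None:
    """Re-anchor some SNV pairs onto shared loci so the sites VCF carries
    genuine multi-allelic lines; annotations and truth move with them."""
    by_chrom: dict[str, list[int]] = {}
    for i, p in enumerate(placed):
        if p["plan"].kind == "snv":
            by_chrom.setdefault(p["variant"].chrom, []).append(i)
    made = 0
    for chrom in sorted(by_chrom):
        pool = by_chrom[chrom]
        while made < config.multiallelic_pairs and len(pool) >= 2:
            i = pool.pop(int(rng.integers(0, len(pool))))
            j = pool.pop(int(rng.integers(0, len(pool))))
            anchor = placed[i]["variant"]
            alt_j = next(
                b for b in "ACGT" if b not in (anchor.ref, anchor.alt)
            )
            moved = GenomicVariant(anchor.chrom, anchor.pos, anchor.ref, alt_j)
            placed[j]["variant"] = moved
            placed[j]["trimmed"] = to_trimmed(moved)
            placed[i]["multiallelic"] = placed[j]["multiallelic"] = True
            made += 1


def _write_fasta(path: Path, reference: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sorted(reference.items()):
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _sites_records(
    placed: list[dict],
    config: SimulationConfig,
    rng: np.random.Generator,
    reference: dict[str, str],
) -> list[tuple[str, int, str, list[str], list[float]]]:
    """Site lines: same-locus alleles merged into multi-allelic records, and a
    fraction of indels emitted in a padded, non-minimal representation."""
    merged: dict[tuple[str, int, str], tuple[list[str], list[float]]] = {}
    for p in placed:
        v: GenomicVariant = p["variant"]
        ref, alt, pos = v.ref, v.alt, v.pos
        if len(ref) != len(alt) and rng.random() < config.unnormalized_rate:
            # pad with the following reference base: a right-extended,
            # non-minimal representation that normalization must undo
            nxt = reference[v.chrom][pos + len(ref) - 1]
            ref, alt = ref + nxt, alt + nxt
        alts, afs = merged.setdefault((v.chrom, pos, ref), ([], []))
        alts.append(alt)
        afs.append(p["plan"].af)
    return sorted(
        (chrom, pos, ref, alts, afs)
        for (chrom, pos, ref), (alts, afs) in merged.items()
    )


def _write_sites_vcf(path: Path, records, config: SimulationConfig) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">\n')
        for chrom, length in sorted(config.chrom_lengths.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alts, afs in records:
            af = ",".join(f"{f:.6g}" for f in afs)
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{','.join(alts)}\t.\t.\tAF={af}\n")


def _write_genotypes_vcf(
    path: Path, placed: list[dict], genotypes: np.ndarray, config: SimulationConfig
) -> None:
    n = genotypes.shape[1]
    samples = [f"S{i + 1:06d}" for i in range(n)]
    order = sorted(range(len(placed)), key=lambda i: (placed[i]["variant"].chrom, placed[i]["variant"].pos))
    gt_strings = np.array(["0/0", "0/1", "1/1"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in sorted(config.chrom_lengths.items()):
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for i in order:
            v = placed[i]["variant"]
            row = "\t".join(gt_strings[genotypes[i]])
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t.\tGT\t{row}\n")


def _fmt(x, nd=4) -> str:
    if x is None:
        return "."
    return f"{x:.6g}"


def _write_annotation_tsv(path: Path, placed: list[dict], tag: str) -> None:
    rows = []
    for p in placed:
        t: TrimmedVariant = p["trimmed"]
        rows.append(
            {
                "Chr": t.chrom,
                "Start": t.start,
                "End": t.end,
                "Ref": t.ref,
                "Alt": t.alt,
                "Gene.refGene": p["gene"],
                "Func.refGene": p["plan"].func_class,
                "AAChange": p["aa_change"],
                "Clinvar": p["clinvar"],
                "InterVar": p["intervar"],
                "CADD": _fmt(p["cadd"]),
                "Eigen": _fmt(p["eigen"]),
                tag: _fmt(p["plan"].af),
            }
        )
    df = pd.DataFrame(rows).sort_values(["Chr", "Start"], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)


def _simulate_questionnaire(
    config: SimulationConfig, rng: np.random.Generator, carrier: np.ndarray
) -> tuple[pd.DataFrame, dict]:
    n = config.n_participants
    catalogue = default_catalogue(config.item_catalogue_size)
    item_cols = [f"{cat}__{site}" for cat, site in catalogue]
    col_index = {c: k for k, c in enumerate(item_cols)}
    by_cat: dict[str, list[str]] = {}
    for cat, site in catalogue:
        by_cat.setdefault(cat, []).append(f"{cat}__{site}")

    sex = np.where(rng.random(n) < 0.5, "female", "male")
    items = np.zeros((n, len(item_cols)), dtype=np.uint8)
    model = config.phenotype_model
    for cat in CATEGORIES:
        p = np.array([model.positive_prob(cat, bool(c)) for c in carrier])
        positive = rng.random(n) < p
        cols = by_cat[cat]
        for i in np.flatnonzero(positive):
            allowed = cols
            if cat == "self":
                banned = FEMALE_ONLY if sex[i] == "male" else MALE_ONLY
                allowed = [c for c in cols if c.split("__", 1)[1] not in banned]
            elif cat in ("father", "brother"):
                allowed = [c for c in cols if c.split("__", 1)[1] not in FEMALE_ONLY]
            elif cat in ("mother", "sister"):
                allowed = [c for c in cols if c.split("__", 1)[1] not in MALE_ONLY]
            items[i, col_index[allowed[int(rng.integers(0, len(allowed)))]]] = 1

    # planted contradictions: males reporting a self female-specific cancer
    n_contr = int(round(config.contradiction_rate * n))
    male_idx = np.flatnonzero(sex == "male")
    contr_ids = []
    self_female = [
        c for c in by_cat["self"] if c.split("__", 1)[1] in FEMALE_ONLY
    ]
    if n_contr and len(male_idx) and self_female:
        chosen = rng.choice(male_idx, size=min(n_contr, len(male_idx)), replace=False)
        for i in chosen:
            items[i, col_index[self_female[int(rng.integers(0, len(self_female)))]]] = 1
            contr_ids.append(int(i))

    # planted over-limit records (the QC rule's target population)
    n_over = int(round(config.qc_noise * n))
    over_idx = rng.choice(n, size=n_over, replace=False) if n_over else np.array([], int)
    for i in over_idx:
        k = int(rng.integers(51, min(81, len(item_cols) + 1)))
        cols = rng.choice(len(item_cols), size=k, replace=False)
        items[i, :] = 0
        items[i, cols] = 1

    ids = [f"S{i + 1:06d}" for i in range(n)]
    df = pd.DataFrame(items, columns=item_cols)
    df.insert(0, "carrier", carrier.astype(int))
    df.insert(0, "sex", sex)
    df.insert(0, "participant_id", ids)
    truth = {
        "overlimit_ids": [ids[i] for i in sorted(over_idx.tolist())],
        "contradiction_ids": [ids[i] for i in sorted(contr_ids)],
    }
    return df, truth


def generate(config: SimulationConfig, outdir: str | Path) -> SimBundle:
    """Write a full synthetic bundle into ``outdir`` and return its paths."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    reference = _make_reference(config, rng)
    placed = _place_variants(config, rng, reference)
    sites = _sites_records(placed, config, rng, reference)

    n = config.n_participants
    genotypes = np.vstack(
        [rng.binomial(2, p["plan"].af, size=n).astype(np.uint8) for p in placed]
    )
    risk = np.array(
        [p["plan"].true_class in ("PLP", "CANDIDATE_LIKE") for p in placed]
    )
    carrier = (genotypes[risk] > 0).any(axis=0)

    questionnaire, q_truth = _simulate_questionnaire(config, rng, carrier)

    fasta = outdir / "reference.fa"
    sites_vcf = outdir / "sites.vcf"
    geno_vcf = outdir / "genotypes.vcf"
    ann_tsv = outdir / "annotations.tsv"
    quest_tsv = outdir / "questionnaire.tsv"
    truth_json = outdir / "truth.json"

    _write_fasta(fasta, reference)
    _write_sites_vcf(sites_vcf, sites, config)
    _write_genotypes_vcf(geno_vcf, placed, genotypes, config)
    _write_annotation_tsv(ann_tsv, placed, config.dataset_tag)
    questionnaire.to_csv(quest_tsv, sep="\t", index=False)

    ids = questionnaire["participant_id"].to_numpy()
    truth = {
        "seed": config.seed,
        "n_participants": n,
        "dataset_tag": config.dataset_tag,
        "carrier_probability": carrier_probability(config),
        "variants": [
            {
                "key": list(map(str, p["trimmed"].key)),
                "vcf": [p["variant"].chrom, p["variant"].pos, p["variant"].ref, p["variant"].alt],
                "true_class": p["plan"].true_class,
                "af": p["plan"].af,
                "observed_af": float(genotypes[i].sum() / (2 * n)),
                "cadd": p["cadd"],
                "eigen": p["eigen"],
                "func_class": p["plan"].func_class,
                "multiallelic": p["multiallelic"],
            }
            for i, p in enumerate(placed)
        ],
        "carrier_ids": [str(x) for x in ids[carrier]],
        **q_truth,
    }
    truth_json.write_text(json.dumps(truth, indent=1) + "\n")
    return SimBundle(fasta, sites_vcf, geno_vcf, ann_tsv, quest_tsv, truth_json, truth)


# ---------------------------------------------------------------------------
# recovery harness and fast replicate engine
# ---------------------------------------------------------------------------

def end_to_end_recovery(config: SimulationConfig, workdir: str | Path) -> dict:
    """Run the full pipeline on a generated bundle and score recovery.

    Checks: (i) fraction of candidate-like variants admitted and neutral
    variants rejected by the derived thresholds; (ii) exact agreement of the
    candidate set with the planted candidate-like set, allowing only the
    score-sampling misclassifications recorded in the truth JSON; (iii) QC
    drop recovery and the sister-category significance.  Failures are
    recorded in the report, not raised.
    """
    from .annotations import join_annotations
    from .famhist import family_history_screen, qc_records
    from .filtering import apply_cascade, derive_thresholds, select_reference_set
    from .variants import FastaReference, extract_region, normalize, read_sites_vcf

    bundle = generate(config, workdir)
    tag = config.dataset_tag
    ref_seq = FastaReference(bundle.reference_fasta)

    raw = read_sites_vcf(bundle.sites_vcf, dataset_tag=tag)
    normalized = [normalize(v, ref_seq) for v in raw]
    in_region = [
        v for region in config.regions for v in extract_region(normalized, region)
    ]
    trimmed = [to_trimmed(v) for v in in_region]

    table = read_annotation_table(bundle.annotation_tsv)
    join = join_annotations(trimmed, table)
    annotated = [ann for _, ann in join.annotated]

    reference_set = select_reference_set(annotated, tag)
    thresholds = derive_thresholds(reference_set, tag)
    partition = apply_cascade(annotated, thresholds, tag)

    truth_by_key = {tuple(v["key"]): v for v in bundle.truth["variants"]}

    def _passes(v: dict) -> bool:
        return (
            v["cadd"] is not None
            and v["eigen"] is not None
            and v["cadd"] >= thresholds.cadd_min
            and v["eigen"] >= thresholds.eigen_min
            and v["af"] <= thresholds.maf_max
        )

    cand_truth = [v for v in bundle.truth["variants"] if v["true_class"] == "CANDIDATE_LIKE"]
    neut_truth = [v for v in bundle.truth["variants"] if v["true_class"] == "NEUTRAL"]
    admit = sum(_passes(v) for v in cand_truth) / max(len(cand_truth), 1)
    reject = sum(not _passes(v) for v in neut_truth) / max(len(neut_truth), 1)

    expected_candidates = {
        tuple(v["key"]) for v in cand_truth if _passes(v)
    }
    found_candidates = {tuple(map(str, a.key.key)) for a in partition.candidates}

    questionnaire = pd.read_csv(bundle.questionnaire_tsv, sep="\t", dtype={"participant_id": str})
    kept, qc_report = qc_records(questionnaire)
    dropped_ids = set(qc_report.dropped["participant_id"])
    screen = family_history_screen(kept, categories=("self", "sister", "offspring", "any_family"))
    sister_p = float(screen.loc[screen.category == "sister", "p_value"].iloc[0])

    report = {
        "thresholds": asdict(thresholds),
        "n_reference": len(reference_set),
        "candidate_admit_rate": admit,
        "neutral_reject_rate": reject,
        "unmatched_variants": len(join.unmatched_variants),
        "candidates_found": sorted(found_candidates),
        "candidates_expected": sorted(expected_candidates),
        "candidates_match_truth": found_candidates == expected_candidates,
        "qc_dropped": sorted(dropped_ids),
        "qc_match_truth": dropped_ids == set(bundle.truth["overlimit_ids"]),
        "sister_p_value": sister_p,
        "sister_significant": sister_p < 0.05,
        "partition_sizes": {
            "known_plp": len(partition.known_plp),
            "candidates": len(partition.candidates),
            "benign_excluded": len(partition.benign_excluded),
            "remainder": len(partition.remainder),
        },
    }
    return report


def sister_rejection_rate(
    n_participants: int,
    p_carrier: float,
    baseline: float,
    relative_risk: float,
    n_replicates: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of replicates whose sister test rejects at ``alpha``.

    Vectorized replicate engine for power/type-I studies: each replicate draws
    the carrier count and the category-positive counts directly from their
    binomial laws (equivalent to, and much faster than, simulating the full
    questionnaire), then applies the expected-count rule to pick the test.
    """
    rng = np.random.default_rng(seed)
    p_pos = min(1.0, baseline * relative_risk)
    rejected = 0
    for _ in range(n_replicates):
        m = int(rng.binomial(n_participants, p_carrier))
        if m == 0:
            continue
        a = int(rng.binomial(m, p_pos))
        c = int(rng.binomial(n_participants - m, baseline))
        t = Contingency2x2(a, m - a, c, (n_participants - m) - c)
        if t.expected_min() < 5 or any(mg == 0 for mg in t.margins):
            res = fisher_exact(t)
        else:
            res = yates_chi2(t)
        if res.p_value is not None and res.p_value < alpha:
            rejected += 1
    return rejected / n_replicates
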