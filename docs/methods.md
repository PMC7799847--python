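# Methods notes

This note documents the models and procedures implemented in `brcascreen`,
the defaults and why they were chosen, and what the synthetic cohort does and
does not emulate.

## Variant representation and normalization

Variants live in two dialects. VCF-anchored records (`GenomicVariant`) use the
1-based position of the first REF base; indels carry a shared anchor base.
Trimmed records (`TrimmedVariant`) follow the annotation-table convention:
anchor dropped, `-` for the empty side, `start`/`end` spanning the affected
reference bases (for a pure insertion, `end = start` at the base the insertion
follows).

Normalization implements the standard vt/bcftools algorithm: repeatedly
right-trim shared trailing bases, extending left with the reference base when
an allele would empty, then left-trim shared leading bases. The result is the
unique minimal, left-most representation; the test suite checks this against
an independent oracle that enumerates every representation producing the same
edited haplotype. Left extension is bounded by a configurable window
(default 200 bp) and errors rather than stopping silently at the edge.

Numerical/positional choices:

* Coordinates are 1-based inclusive throughout. Region membership is decided
  by the POS of the normalized record only; an indel whose span crosses the
  region end but starts inside is retained. The rule is the simplest
  defensible one and matters only for variants within a few bases of a
  boundary.
* Chromosome names are accepted with or without a `chr` prefix and stored
  un-prefixed, since annotation tables and VCF sources mix both.
* A missing allele frequency is represented as absent, never as zero:
  "not observed in this panel" and "observed at frequency 0" are different
  statements, and the filtration cascade treats a missing MAF as a failure to
  demonstrate rarity rather than as maximal rarity.

## Classification harmonization

ClinVar and InterVar labels arrive in several string dialects; `parse_class`
maps them onto eight controlled values. Any string beginning with
"Conflicting" collapses to CONFLICTING; the composite
"Benign / Little Clinical Significance" collapses to BENIGN; unrecognized
strings raise an error rather than silently becoming UNKNOWN, so vocabulary
drift in upstream annotators surfaces immediately. CONFLICTING and UNCERTAIN
are deliberately both non-pathogenic and non-benign: such variants remain
eligible for the computational filter, which is exactly the population the
screen is for.

The packaged candidate-summary table reproduces its source table as printed.
The 22-row "InterVar P or LP" class is known to sit alongside a narrative
count of 23 (10 ClinVar + 13 InterVar-only); the additional InterVar-LP
variant (BRCA1 p.L52F, panel MAF 0.0037) is a benign-leaning outlier discussed
separately in the source and is not part of the printed table, so it is not
in the fixture either.

## Threshold derivation and the cascade

The reference set is restricted to **ClinVar** P/LP variants (not
InterVar-only calls): minima of 25.9 (CADD_phred) and 0.501 (Eigen_raw) are
attained inside the ClinVar-scored rows of the packaged table, and ClinVar
entries carry curated clinical provenance that InterVar's rule-based calls do
not. Only single-nucleotide variants with both scores present qualify —
CADD/Eigen calibration for indels is a different problem, and the packaged
table carries no indel scores. Thresholds are always recomputed from whatever
reference set is supplied; the triple (25.9, 0.501, 0.0003) is a regression
expectation, not a constant.

Cascade order: known P/LP first (ClinVar **or** InterVar — the screen's goal
is novelty), then the score/MAF filter with inclusive comparisons, then the
benign exclusion keyed to the **ClinVar** label only. The benign rule is
applied on the MAF criterion alone when scores are absent, so a rare
ClinVar-benign variant can never surface as a candidate merely because its
scores were unavailable. DANN_rankscore is parsed and stored but takes no
part in filtering: its distribution does not separate known pathogenic
variants from the rest the way CADD and Eigen do.

The cascade is monotone by construction: raising either score threshold or
lowering the MAF ceiling can only shrink the candidate set (property-tested).

## Burden statistics

The per-person P/LP rate is the number of distinct P/LP variants divided by
cohort size — a variant-count rate, not an allele-count rate; with 10 variants
over 3,552 genomes it reproduces the printed 2.81 × 10⁻³/person.
Reported rates are displayed to three significant figures **truncating toward
zero**, which is the convention the printed panel summaries follow
(2.8153 × 10⁻³ prints as 2.81 × 10⁻³); all returned values stay exact and
truncation is applied only at the reporting layer. The accumulated frequency
is a plain (compensated) sum of allele frequencies, an upper proxy for the
carrier frequency valid for rare, approximately independent variants.

Fold enrichment between panels is a frequency ratio with explicit flags for
zero-reference ("novel in target") and zero/zero ("undefined") cases, so the
distinction between "absent" and "unmeasured" is never collapsed into an
arbitrary finite number.

## Family-history screen

The questionnaire model is one row per participant, one 0/1 column per
(relative category, cancer site) item. QC drops participants with more than
50 checked malignant-neoplasm items (strict inequality; exactly 50 is kept) —
in the emulated instrument such records are dominated by contradictory
answers. Contradictions themselves (e.g. a male self-history of ovarian
cancer) are flagged but never drop a record on their own.

Counting is participant-level: a participant with two affected sisters counts
once, because the instrument records presence/absence per item and cannot
weight multiple affected relatives. "Family" positivity means any blood
relative (father, mother, brother, sister, offspring), excluding the
participant and spouse — spouse-only positives do not count.

Tests per category, carriers versus all non-carriers:

* default: chi-squared with Yates' continuity correction,
  χ² = N·(max(|ad−bc|−N/2, 0))² / ((a+b)(c+d)(a+c)(b+d)), switching to
  Fisher's exact (two-sided, sum of same-margin tables no more probable than
  observed) when any expected cell is below 5 or a margin is zero;
* secondary: one-sided binomial upper tail for the carrier-positive count
  against the non-carrier positive proportion — one-sided because the
  scientific question is a preponderance, not any difference; the direction
  is stated in the output.

Significance stars at p < 0.05 and p < 10⁻⁴. No multiple-testing correction
is applied by default (the categories are few and the analysis is
confirmatory per category); a Bonferroni flag is available. The carrier set
defaults to the union of known P/LP and candidate carriers, configurable to
either subset. Whether carriers should be compared against all non-carriers
or some other stratum is genuinely open; carriers-versus-all-non-carriers is
implemented as the simplest population contrast.

The implementation delegates the three tests to scipy
(`chi2_contingency`, `fisher_exact`, `binom.sf`); the test suite validates
them against independent oracles — the closed 2×2 formula with
erfc(√(x/2)) for the χ²₁ tail, exhaustive rational-arithmetic enumeration of
all same-margin tables for every 2×2 table with N ≤ 30, and log-space
term-by-term summation for the binomial tail.

## Synthetic cohort

The generator emulates the statistical structure the analysis relies on, at
configurable scale:

* **Genome**: two random chromosomes ("13", "17") of 12 kb with 9 kb gene
  regions. Real gene coordinates are not used — the pipeline takes regions
  from configuration, and small synthetic coordinates keep runtime bundles
  light.
* **Variants** (defaults mirror the screened panel's composition): 10
  pathogenic-like (half frameshift indels without scores), 7 candidate-like
  VUS, 1 rare benign-like, and ~22 neutral background variants including
  common ones; allele frequencies 1 × 10⁻⁴ – 3 × 10⁻⁴ for the
  pathogenic/candidate classes and up to 0.05 for neutrals. The sites VCF
  reports the configured panel frequency (the panel is an input to the
  screen, not an estimate made by it); genotypes are drawn per variant as
  Binomial(2, AF) — Hardy–Weinberg proportions, appropriate for a panel of
  unrelated individuals. Multi-allelic lines and right-extended, non-minimal
  indel representations are deliberately injected to exercise normalization;
  annotations and truth keys always refer to the normalized representation.
* **Scores**: per-class truncated normals; pathogenic-like and candidate-like
  CADD ~ TN(33, 5, min 20), Eigen ~ N(0.75, 0.12); neutral/benign-like
  CADD ~ TN(10, 6, min 0), Eigen ~ N(−0.2, 0.3). With a five-variant scored
  reference this puts the derived thresholds in a realistic CADD ≈ 26–28 /
  Eigen ≈ 0.5–0.6 corner. Because candidate-like scores are drawn from the
  same distribution as the reference, a candidate occasionally samples below
  the realized reference minimum; the truth JSON records every draw, so
  recovery is asserted *exactly given the recorded scores* rather than
  approximately. The recovery report also measures the admit/reject rates
  (neutral rejection is ≥ 95% under the defaults; candidate admission
  fluctuates around the order-statistic expectation of roughly 70–100% for a
  five-variant reference).
* **Questionnaire**: 269 (category, site) items over 7 relative categories;
  sexes Bernoulli(0.5) with female-/male-specific sites kept consistent
  except for deliberately planted contradictions (rate 5 × 10⁻⁴). Baseline
  per-category positive rates (self 0.04, father 0.14, mother 0.10,
  brother/sister 0.05, offspring 0.01, spouse 0.06) approximate self-reported
  lifetime histories in a middle-aged cohort, with fathers reporting most.
  Carriers' sister and offspring categories are elevated by relative risks 3
  and 2. The default cohort size is 35,199 with an over-limit planting rate
  of 0.0018, i.e. 63 QC-dropped records leaving 35,136.
* **Determinism**: a single seed drives every draw; a fixed seed reproduces
  the bundle byte for byte.
* **Truth JSON schema**: top-level keys `seed`, `n_participants`,
  `dataset_tag`, `carrier_probability`, `variants`, `carrier_ids`,
  `overlimit_ids`, `contradiction_ids`. Each entry of `variants` holds
  `key` (trimmed [chrom, start, end, ref, alt], all strings), `vcf`
  ([chrom, pos, ref, alt] of the normalized VCF representation),
  `true_class`, `af` (configured panel frequency), `observed_af` (realized
  genotype frequency), `cadd`/`eigen` (sampled scores, null for indels),
  `func_class`, and `multiallelic` (whether the variant shares its locus
  with another allele in the sites VCF).

What the generator does **not** emulate: linkage disequilibrium and kinship,
age structure, recall bias and item-level correlation in questionnaires,
sequencing error, and indel-calling uncertainty. Passing tests therefore show
that the pipeline's logic and statistics behave correctly under the assumed
sampling laws — not that the screen's clinical yield on real cohorts matches
the synthetic recovery rates.

## Problem sizes used in the test and acceptance runs

Unit tests use bundles of 300–4,000 participants; the planted-truth recovery
and QC-census checks run one bundle at the full default size (35,199). The
type-I calibration and power checks use the vectorized replicate engine
(carrier and positive counts drawn directly from their binomial laws) with
1,000 and 200 replicates respectively — the engine is statistically
equivalent to simulating full questionnaires and lets the calibration band be
estimated with Monte Carlo error well below its width. The exhaustive Fisher
check covers all 46,375 tables with N ≤ 30.

## Known limitations

* The screen consumes precomputed CADD/Eigen/DANN scores and ClinVar/InterVar
  labels; it never computes them.
* Score thresholds speak only to single-nucleotide variants; indels pass or
  fail on their clinical labels alone and candidate indels are out of reach.
* The family-history analysis is unadjusted for age and sex and uses
  self-reported histories; a significant category signals preponderance, not
  an effect size estimate.
* The benign exclusion trusts the ClinVar label; a mislabelled benign variant
  would be silently excluded.
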