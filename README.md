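# brcascreen

Screening a population whole-genome frequency panel for novel candidate
pathogenic variants in the hereditary breast and ovarian cancer (HBOC) genes
*BRCA1* and *BRCA2*, and testing whether carriers of the flagged variants show
a preponderance of cancer in their family histories.

## Who this is for

Groups running prospective genome-cohort studies face a practical question:
among the rare *BRCA1/2* variants segregating in their population, which
variants of uncertain significance (VUS) deserve close longitudinal follow-up?
Clinical databases (ClinVar) and ACMG rule engines (InterVar) only recognise
what has already been reported in disease families. `brcascreen` implements a
complementary, data-driven screen: it calibrates computational deleteriousness
thresholds on the panel's own known pathogenic variants and uses them, together
with an allele-frequency ceiling, to flag unreported candidates — then checks
the flag against self-reported cancer histories of carriers' relatives.

## The method

Let the annotated variant set carry, per variant *v*: a ClinVar label, an
InterVar label, CADD_phred and Eigen_raw deleteriousness scores (defined for
single-nucleotide variants), and a panel minor allele frequency MAF(*v*).

1. **Normalization.** Panel VCFs are decomposed into bi-allelic records and
   normalized to the minimal left-aligned representation (the standard
   vt/bcftools algorithm), then converted into the trimmed coordinate dialect
   used by annotation tables (anchor base dropped, `-` for the empty allele).
2. **Threshold derivation.** The reference set R = ClinVar P/LP
   single-nucleotide variants with both scores and a panel frequency. The
   filter triple is

       CADD_min  = min_{v∈R} CADD_phred(v)
       Eigen_min = min_{v∈R} Eigen_raw(v)
       MAF_max   = max_{v∈R} MAF(v)

   so every trusted pathogenic variant passes its own filter by construction.
   On the packaged reference table this gives (25.9, 0.501, 0.0003).
3. **Filtration cascade.** (a) set aside variants already P/LP in ClinVar or
   InterVar; (b) keep the rest iff CADD ≥ CADD_min ∧ Eigen ≥ Eigen_min ∧
   MAF ≤ MAF_max (inclusive; missing score ⇒ fail); (c) remove keepers that
   ClinVar calls benign/likely benign. Survivors are the novel candidates.
4. **Burden statistics.** Per-person P/LP rate (count / cohort size),
   accumulated pathogenic allele frequency, cross-panel overlap, fold
   enrichment, and score–frequency correlations.
5. **Family-history screen.** Carriers (known P/LP ∪ candidates) versus the
   rest of the questionnaire cohort, per relative category, on participant-level
   2×2 tables: chi-squared with Yates' continuity correction by default,
   Fisher's exact test when any expected cell < 5, and a one-sided binomial
   tail against the non-carrier positive proportion as a secondary check.
   Questionnaire QC drops records with more than 50 checked cancer items.

A synthetic-cohort generator (`brcascreen.simulate`) produces a reference
FASTA, frequency and genotype VCFs, an annotation table with class-separated
score distributions, and a questionnaire with elevated positive rates among
carriers' sisters/offspring — with every latent assignment recorded in a truth
JSON — so the whole pipeline is testable without restricted data.

## Worked example

The package ships two small reference tables: the summary of known and
candidate pathogenic *BRCA* variants in the 3.5KJPNv2 panel
(`candidate_summary_table`, 30 variants in classes "InterVar P or LP" /
"Computational+MAF" / "Benign") and the gnomAD-EAS P/LP table
(`gnomad_eas_plp_table`, 41 variants). The regression subcommand recomputes
every headline number from them:

```text
$ brcascreen verify-paper
clinvar_plp_count: 10 (expected 10) ok
accumulated_frequency: 0.0018 (expected 0.0018) ok
plp_rate_3sf: 0.00281 (expected 0.00281) ok
thresholds: {'cadd_min': 25.9, 'eigen_min': 0.501, 'maf_max': 0.0003} (expected {'cadd_min': 25.9, 'eigen_min': 0.501, 'maf_max': 0.0003}) ok
candidates: 7 (expected 7) ok
benign_excluded: 1 (expected 1) ok
known_plp: 22 (expected 22) ok
gnomad_eas_overlap: 4 (expected 4) ok
all fixture regression checks passed
```

Reading the numbers: the panel holds **10** ClinVar P/LP *BRCA* variants whose
frequencies sum to an accumulated pathogenic frequency of **0.0018**
(≈ 1 carrier per ~280 people as an upper proxy), i.e. **2.81 × 10⁻³**
P/LP variants per sequenced person. The five scored ClinVar P/LP
single-nucleotide variants calibrate the thresholds **CADD ≥ 25.9,
Eigen ≥ 0.501, MAF ≤ 0.0003**; eight unreported variants pass all three, one
of which is ClinVar-benign and is excluded, leaving **7 novel candidates**.
Only **4** of the gnomAD-EAS P/LP variants appear in the panel at all —
pathogenic *BRCA* variation is strongly population-specific.

The same stages are callable from Python:

```python
from brcascreen import select_reference_set, derive_thresholds, apply_cascade
from brcascreen.datasets import candidate_summary_table

table = candidate_summary_table()
thresholds = derive_thresholds(select_reference_set(table, "3.5KJPN"), "3.5KJPN")
partition = apply_cascade(table, thresholds, "3.5KJPN")
print(thresholds)           # FilterThresholds(cadd_min=25.9, eigen_min=0.501, maf_max=0.0003)
print(len(partition.candidates))  # 7
```

Other subcommands: `normalize`, `derive-thresholds`, `filter`, `popstats`,
`famhx`, `simulate`, `report` (full pipeline from a YAML config). See
`brcascreen --help`.

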