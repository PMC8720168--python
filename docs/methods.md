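# Methods

## The candidate-variant filter

The filter implements a panel-restricted rare-variant screen for inborn
errors of immunity. A genotype call survives when, in order:

1. its variant is annotated to a panel gene;
2. read depth > `min_depth` (default 10×) **and** genotype quality >
   `min_qual` (default PHRED 20) — both strict inequalities, so a call at
   exactly 10× fails;
3. its consequence is nonsynonymous (missense, nonsense, frameshift,
   ±1–2 splice site, start loss);
4. it is rare: every population database MAF *present* in the annotation
   table (ExAC, 1000 Genomes, ESP6500, gnomAD) is < `maf_threshold`
   (default 0.05, strict). A variant absent from all four databases counts
   as rare by default (`maf_missing_is_rare`), because novel null alleles
   by definition have no database frequency. The conjunctive reading — all
   present databases must be below threshold — is deliberate and
   configurable;
5. it has a pathogenicity basis: curated class DM or DM?, or, for
   unclassified variants, a null consequence (the PVS1-style novel-null
   rule). Unclassified missense variants are dropped;
6. it is not a recurrent novel null: unclassified null variants carried by
   more than `recurrent_null_carrier_fraction` (default 5%) of the cohort
   are removed as probable sequencing artifacts. The threshold mirrors the
   rarity bound; curated DM/DM? variants are exempt because their
   recurrence is not evidence of error.

Surviving calls are grouped per subject × gene and tested for a
disease-consistent inheritance pattern:

* **AD present** (alone or with AR): every call qualifies, het or hom.
* **AR only** (autosomal): homozygotes qualify; two or more *distinct*
  heterozygous variants in the gene qualify together as a **putative**
  compound heterozygote. Phase cannot be resolved without parental
  genotypes, so cis configurations are knowingly over-called; a lone het
  emits nothing. A hom plus a single distinct het emits only the hom —
  the het is not promoted without a second het partner.
* **XLR**: any male call (hemizygous or diploid-coded) qualifies; females
  require homozygosity. **XLD**: any call qualifies regardless of sex.
  The female XLR/XLD treatment is the conservative Mendelian reading; the
  clinical convention is genuinely ambiguous here, so both branches are
  explicit in `evaluate_inheritance` rather than buried in a default.
* With several modes on one disorder, each variant is labeled once, by
  the first branch that accepts it (AD → XLD → XLR → AR).

Candidates are sorted by (chromosome, position, alt) for deterministic
output. A subject's profile is IEI-positive iff it has ≥ 1 candidate; its
IUIS groups are the union of its candidate genes' categories, and
"multiple" means ≥ 2 distinct categories.

## Phenotype derivation

Microbiology is restricted to collection times within ±48 h of enrollment
(inclusive at exactly ±48 h — "48 h before or after" read inclusively,
configurable). Likely contaminants are excluded by (site, organism) pair,
matched case-insensitively against a data file, not code:
coagulase-negative staphylococci and viridans streptococci in blood,
*Candida albicans* and viridans streptococci in respiratory specimens,
mixed flora in urine. Culture-negative status means no positive result at
any site after windowing and exclusion, so it is mutually exclusive with
every site flag by construction.

Inflammatory flags use the most abnormal value per subject: minimum for
lymphocytes and platelets, maximum for ferritin and CRP, with strict
comparators (< 1000/µL, > 500 ng/mL, < 150,000/µL, > 10 mg/dL). The
ferritin comparator is configurable between > and ≥ because published
definitions disagree at the boundary; the default is strict >. An analyte
never measured for a subject yields a *missing* flag, not false, and the
subject is dropped from that phenotype's 2×2 table — denominators
therefore vary by marker availability, as they do in real cohorts.

Pediatric SIRS counts four criteria (age-percentile tachycardia and
tachypnea, temperature < 36 °C or > 38.5 °C, WBC > 12,000/µL or
< 4000/µL or > 10% immature neutrophils). The 90th-percentile HR/RR
table is pluggable; the shipped default follows consensus-style age
brackets (0–1, 1–2, 2–6, 6–13, 13–18 years) and should be replaced with
institutional norms where available. Sepsis = suspected infection + ≥ 2
criteria; severe sepsis additionally requires ≥ 1 of six literal
organ-failure definitions (cardiovascular infusion support; mechanical
ventilation with PaO₂/FiO₂ < 300; bilirubin > 1.0 mg/dL with ALT > 100
IU/L; creatinine > 1.0 mg/dL with urine output < 0.5 mL/kg/h; platelets
< 100,000/µL with INR > 1.5; GCS < 12 off sedation).

## Association statistics

Odds ratios are ad/bc with Haldane–Anscombe +0.5 on **all** cells applied
only when some cell is zero, flagged in the output. Confidence intervals
are Woolf (logit): exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). χ² is Pearson with
1 df and **no** continuity correction — with Yates the test no longer
reproduces standard uncorrected two-proportion results, and the
uncorrected form is what this analysis design calls for; a zero margin
returns p = 1 with a warning. Fisher's exact test uses the
probability-mass two-sided convention (sum of all tables with the
observed margins whose probability ≤ the observed table's, with 1e-7
relative tolerance on the comparison), matching mainstream statistical
software; it is verified in the tests against both exact-integer
enumeration and an independent library implementation. Wilcoxon rank-sum
uses the exact null distribution for combined n ≤ 20 without ties and the
tie-corrected normal approximation otherwise.

Benjamini–Hochberg adjustment is the standard step-up with one extension:
the family size *m* may be declared externally and exceed the number of
p-values supplied, as when a family of per-variant tests is reported
piecemeal (e.g. m = the number of unique identified variants).

The suite tests "any IEI" versus variant-negative subjects by χ², and
each of the nine IUIS categories plus the "multiple" group versus the same
variant-negative reference by Fisher exact. A subject contributes to
every category it carries *and* to "multiple" — the groups deliberately
overlap. BH families are formed per outcome over the group tests, with
the any-IEI test included in the family by default (configurable, since
family membership is an analysis choice).

## MAF enrichment

Cohort allele counts use AN = 2·subjects on autosomes and
AN = 2·females + 1·males on X, male alt calls contributing one allele
however coded. Comparisons are χ² on the 2×2 allele-count table (allele,
not carrier, counts — the reference publishes AC/AN); a Fisher fallback
for small expected cells exists behind a flag but is off by default. The
MAF ratio is cohort/reference, encoded `inf` when the reference frequency
is zero (the "x/0" situation of very rare alleles). Strata are
user-declared (subject-table column + value) with an explicit mapping to
a reference ancestry label: matching self-reported race to a genetic
ancestry panel is an analysis decision the user must own, never an
algorithmic inference.

## The synthetic-cohort generator

The generator emulates the *structure* of a severe-sepsis exome cohort:
330 subjects, ~54% male, three self-reported-race strata (68/21/11%),
a 22-gene panel spanning all nine IUIS categories with AD, AR-only, dual
and X-linked disorders, and a 28-variant pool with stratum-specific
Hardy–Weinberg frequencies tuned so ~60% of subjects carry a qualifying
variant (and ~3/4 of the Black stratum, whose complement-variant
frequencies are enriched several-fold). The pool deliberately includes
variants the filter must reject — a synonymous allele, a common DM?
allele (database MAF 0.20), and a recurrent novel null (~15% carriers) —
plus two novel nulls absent from every database. Reference AC/AN values
are scaled to a 141,456-individual database (AN = 282,912) with an
African-ancestry stratum of AN = 24,000.

Binary phenotypes are linked to carrier status by a logistic model,
logit(p) = logit(baseline) + ln(OR)·exposed, with default planted odds
ratios in the range observed for such cohorts (1.66–2.16 for
inflammatory flags, 2.82 and 8.23 for blood and urine positivity, 4.19
for ECMO) and null effects (OR 1) for respiratory and viral positivity.
Outcomes are then *realized* as records: positive cultures with pathogen
organisms drawn inside the ±48 h window (plus contaminants at 8% of
subjects and out-of-window positives at 5%, which downstream derivation
must ignore), and 2–4-point lab series whose extreme value crosses the
phenotype threshold exactly when the drawn flag is true. Lab series are
minimal by design because only the per-subject extreme matters
downstream. Exposure truth (`planted_exposures`) is computed directly
from the drawn genotypes and the design rules, independently of the
filter pipeline, so end-to-end recovery tests are not circular.

All randomness flows from one master seed through named
`numpy.random.SeedSequence` substreams (subjects, genotypes, qc,
outcomes, labs, cultures), so each output file is reproducible even when
other streams are consumed differently.

What the generator does **not** emulate: sequencing reads and coverage
profiles, annotation error, linkage between variants, population
admixture beyond discrete strata, within-subject correlation of
phenotypes beyond their shared exposure, and time dynamics of labs.
Passing tests therefore demonstrate the pipeline's correctness under the
stated generative model, not the clinical validity of any threshold on
real data.

## Problem sizes and numerical choices

* Calibration checks run the exposure→outcome kernel directly in memory:
  type-I error over 1000 replicates at n = 300 (expected rejection rate
  0.05 ± 0.014), CI coverage over 500 replicates at n = 1000, Woolf
  coverage over 2000 binomial tables at n = 1000 per arm. File-based
  round trips are exercised separately on 80–330-subject bundles.
* Fisher's exact test is validated exhaustively against exact-integer
  enumeration over all 46,375 tables with total ≤ 30.
* The candidate filter is validated against a brute-force textual-rule
  checker on 200 random micro-cohorts (≤ 5 subjects × ≤ 6 variants)
  covering every gate boundary (depth 10/11, PHRED 20/21, MAF
  0.049/0.05) and all five inheritance-mode shapes.
* Variant identity is (chromosome, 1-based position, ref, alt), alleles
  uppercased, no left-alignment: inputs are single-source and must be
  pre-normalized, and multi-allelic VCF records are rejected with advice
  to pre-split.
* Zero-cell 2×2 tables: Haldane–Anscombe before OR/CI; χ² on a zero
  margin returns p = 1 with a warning rather than NaN.

## Known limitations

* Compound heterozygotes are putative: without trio data the filter
  cannot distinguish cis from trans, and biallelic AR calls additionally
  require both alleles to carry a pathogenicity basis — an assumption,
  not an established convention.
* HGMD-style DM/DM? classes overestimate pathogenicity by design; the
  pipeline reports variant *burden*, not immunodeficiency diagnoses.
* The recurrent-null threshold (5% carriers) is a declared default, not
  an estimated error rate.
* Cohort-level prevalence figures from any particular study are not
  reproducible without the underlying genotypes; the synthetic generator
  reproduces the statistical structure, and the funnel counters make the
  filter auditable on real inputs.
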