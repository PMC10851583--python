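# Methods

## Scope and data flow

`varprio` models a two-arm exome-annotation study: coding variants of
candidate triglyceride genes, annotated with six in-silico predictors and
population frequencies, are classified pathogenic/benign; pathogenic calls
are aggregated into per-gene carrier burden, a three-way grouping of the case
arm, clinical group comparisons and a patient×gene mutation matrix. Raw reads,
variant calling, and the predictors themselves are out of scope: predictor
outputs, allele frequencies and conservation scores are *inputs*, consumed
from annotation tables. The reference genome and the real *APOA5* transcript
are likewise not required — consequence calling is validated against a
synthetic coding sequence constrained to the documented wild-type residues.

## The consensus classification rule

A variant with a resolved protein consequence is pathogenic iff

* its consequence is frameshift, stopgain or stoploss (automatic rule), or
* SIFT calls it damaging **and** the total number of damaging programs among
  the six is at least two (so SIFT plus any single corroborating program
  suffices).

Damaging categories: SIFT D; PolyPhen2-HDIV D or P; LRT D; MutationTaster D
(and A, the automatic variant of the same verdict, accepted as a conservative
superset); MutationAssessor H or M; CADD strictly greater than 15 on the
scaled score. The CADD ≥ 20 "top 1 % genome-wide" remark is carried into the
rationale text but never changes a vote. Missing annotations never count as
damaging, and in-frame indels are reported as `inframe` without triggering
the automatic rule — only true frame shifts and stop changes do. Allele
frequency, conservation and dbSNP status are deliberately outside the rule;
a property test asserts verdict invariance to them. Duplicate annotation rows
for one variant are rejected as input errors rather than merged, since the
rule has no defined semantics for conflicting duplicates.

## Consequence calling

Coding coordinates are 1-based from the A of the initiator ATG, so codon
*k* = ⌈position/3⌉. Substitutions are classified by mutating the affected
codon and comparing translations (standard genetic code via Biopython);
a substitution in the terminal stop codon yielding a sense codon is a
stoploss, a stop-retaining one is synonymous. Indels whose length is not a
multiple of three are frameshifts anchored at the codon containing the first
shifted nucleotide — for an insertion between positions *i* and *i*+1 this is
codon(*i*+1) — which reproduces the conventional `p.X…fs` naming (the 5-nt
insertion between 544 and 545 anchors at His182). No 3′-most normalization of
indels is attempted; printed variant names are taken at face value. The caller
is checked against a brute-force mutate-translate-diff oracle on ≥ 1000 random
small coding sequences.

## Domain map and residue properties

apoA-V coordinates use full-length numbering (Met1 = 1, 366 residues):
signal peptide 1–23; helices 112–153, 173–213, 221–262, 275–314;
lipid-binding 24–169, 194–268, 316–366; receptor-binding domains 21–26,
36–43, 48–54, 90–98, 146–152, 182–190, 232–237, 251–257, 281–292;
heparin-binding 209–250; LPL-activation 215–261. Intervals are 1-based and
inclusive on both ends and overlap freely across classes. Where published
boundary statements conflict by a single residue (lipid-binding 1 ending
Val169 vs Ala169; lipid-binding 2 ending Gly268 vs Glu268), the consolidated
schematic values (169, 268) are used.

Residue chemistry is a fixed documented table: charge at physiological pH
(D, E = −1; K, R, H = +1, histidine grouped with the basic residues; all else
0), polarity (polar set R N D C E Q H K S T Y), and hydropathy binarized from
the Kyte–Doolittle scale at 0 (> 0 hydrophobic). Qualitative labels for
borderline residues (notably Gly and Cys) differ between published
conventions; the table is a single constant in `annotation.py`, so an
alternative convention is a one-line change. What the classifier consumes is
never affected — property deltas inform interpretation text only.

Alignment-column conservation maps a reference residue through the gapped
reference row to its alignment column and reports the fraction of
non-reference sequences matching the reference symbol (gaps count as
mismatches); "strict" means fraction 1.0.

## Cohort statistics

Burden counts are distinct carriers per gene per arm — a patient with several
mutations in one gene counts once — reported for all variants and for
pathogenic mutations only, with percentages rounded half away from zero
(a one-decimal rendering is also provided, matching the severity rows of the
published table style). The case arm is partitioned as: group I = carries a
pathogenic *APOA5* mutation (precedence); group II = otherwise carries a
pathogenic mutation in the 25 other enriched candidate genes (PLA2G6 …
TIMD4); group III = the rest. The partition is exhaustive and disjoint by
construction.

Two-group comparisons follow a deterministic test menu: continuous variables
use Welch's t-test, falling back to the Mann-Whitney U test when either
group's sample skewness exceeds 2 in magnitude; categorical variables use
Pearson's χ² without continuity correction, falling back to Fisher's exact
test when any expected cell is below 5. All tests are two-tailed at α = 0.05;
no multiple-testing correction is applied, but the report records the number
of tests performed. A degenerate margin (a flag uniformly absent or present)
returns p = 1. p-values are printed to three decimals with `<0.001` and
significance stars below 0.05/0.01/0.001.

## The synthetic-data generator

The generator's defaults *are* the study conditions; it exists so the
pipeline is testable end-to-end without deposited data.

* **Arms:** 163 HLAP / 30 BAP patients.
* **Counts are assigned, not sampled.** Variant carriers (per variant, per
  zygosity), comorbidity flags, sex, severity classes and CT-score flags are
  placed by drawing patient identities without replacement so the configured
  counts are reproduced exactly; this makes the count-based outputs (burden
  table, group sizes, severity percentages) deterministic surfaces, while
  patient identities and continuous covariates remain seed-dependent.
  Infeasible configurations (counts exceeding arm sizes) raise immediately.
* **APOA5 carrier structure.** The common c.553G>T contributes 42
  heterozygous and 7 homozygous HLAP carriers and one BAP heterozygote; the
  five rare pathogenic variants have named single carriers, two of whom (the
  p.S35N and p.R223C carriers) also carry c.553G>T. This collapses the 54
  pathogenic carrier-events onto exactly 52 distinct carriers, the only
  configuration consistent with the documented double carriers. Benign-variant
  carriers are then placed with the overlap implied by the 97/13 any-variant
  totals.
* **Other genes.** Each of the 52 other candidate genes gets one synthetic
  pathogenic and one synthetic benign variant (their identities are
  placeholders; only carrier counts are data). Pathogenic carriers of the 25
  group-II genes are distributed round-robin over a designated pool of 50
  non-group-I patients, so the I/II/III sizes come out 52/50/61; carriers of
  the remaining genes are placed anywhere in the arm. One printed carrier
  count (KLHL8, comparison arm) exceeds its own any-variant count and is
  raised by one to restore feasibility.
* **Continuous covariates** are drawn per arm. Right-skewed laboratory values
  whose SD approaches or exceeds the mean (TG, TC, CRP, BUN) use a log-normal
  with σ² = ln(1 + (sd/mean)²), μ = ln(mean) − σ²/2, which matches the
  configured mean and SD exactly in expectation; the remaining covariates use
  a normal truncated at zero (negligible truncation at these means). Defaults
  are the published per-arm moments, e.g. HLAP TG 18.00 ± 19.30 mmol/L — an
  SD above the mean that rules out an untruncated normal on positive support.
  Covariate–covariate and covariate–genotype correlations are not modelled;
  an optional additive TG shift for pathogenic *APOA5* carriers is available
  and off by default.
* **Synthetic CDS.** 366 codons plus stop (1101 nt); explicitly chosen codons
  pin the wild-type residues referenced by the variant table (e.g. AGC at
  codon 35 so that c.104G>A yields p.S35N, AAA at 188 so c.563A>T yields
  p.K188I); all other codons are random sense codons under the seed.
* **Synthetic alignment.** Six sequences (human reference plus five species
  stand-ins) with independent per-residue substitutions at rate 0.08 —
  roughly the cross-mammal divergence the comparison needs to be informative —
  never at the strictly conserved residues 35, 167 and 223, plus a shared
  three-residue insertion in the two seal lineages so the reference row
  contains gap columns and gapped coordinate mapping is exercised.

What passing tests on these data do **not** show: recovery of real
linkage/population structure, predictor behaviour on real sequence context,
or the study's raw per-patient p-values — the generator reproduces printed
moments and counts, not individual-level data.

## Problem sizes and numerical conventions

The default test run generates cohorts of the study size (193 patients);
the type-I-error check uses 1000 replicates of two 50-patient groups under an
equal-mean null, and generator moment checks use up to 2×10⁵ draws and one
10⁴-patient arm. Seeds are explicit everywhere (`numpy.random.default_rng`);
identical seeds give byte-identical pipeline outputs. Ties in the
Mann-Whitney test use SciPy's default treatment; χ² is computed without
Yates correction to match the large-sample convention of the summary tables.

## Known limitations

* The HGVS subset is deliberately minimal (substitutions, simple insertions
  and deletions in `c.`; one-letter missense, `fs`, `*` forms in `p.`) — no
  delins, intronic offsets or genomic coordinates.
* The consequence caller handles a single coding sequence; splice effects and
  multi-exon genomic mapping are out of scope.
* Domain coordinates and the residue-property table are constants, not
  predictions; alternative hydropathy/polarity conventions change descriptive
  text but never verdicts.
* The classifier implements one specific consensus rule; it is not an ACMG
  criteria engine and performs no recalibration of predictor thresholds.
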