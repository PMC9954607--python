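# Methods

`pepscreen` implements a complete urinary peptidomics biomarker workflow
of the kind used with capillary-electrophoresis mass-spectrometry (CE-MS)
urine profiles for prostate-cancer (PCa) detection.  This note documents
the statistical model at each stage, the tunable parameters and their
defaults, what the synthetic-cohort generator does and does not emulate,
and the numerical choices that were genuinely open.

## Data model

A cohort is a features × samples intensity matrix plus a clinical table.
Each feature is a CE-MS-defined peptide: molecular mass (kDa), normalized
migration time (min, instrument window 10–55 min by default), and an
optional amino-acid sequence with lowercase modification marks
('p'/'m' for oxidized proline/methionine, 'q' for deamidation) mapped to
1-based coordinates in a parent protein.  Intensities are arbitrary units;
an *absent* value means "not detected" and is kept distinct from a
detected intensity of zero throughout — absences never enter arithmetic
as zeros unless a stage's contract says so explicitly (the log transform
below is the one place that happens).

## Internal-standard normalization

Urine concentration varies by an order of magnitude between voids, so
each sample is rescaled against a panel of reference peptides — in the
urinary literature, 29 collagen fragments whose excretion is stable
regardless of disease status.  The per-sample factor is

    f_s = median over detected panel peptides of (reference_i / observed_is)

a median-of-ratios estimator that tolerates individual reference
outliers.  After scaling, the median panel ratio is exactly 1, which
makes the step idempotent and removes any per-sample multiplicative
distortion end-to-end: every downstream statistic is invariant to
per-sample rescaling of the raw matrix (verified to 1e-9 in the tests).
A sample must detect at least `minimum_detected = 15` of the 29 panel
peptides (a majority; configurable) or it is excluded and flagged.

Statistics operate on `log10(1 + x)`; non-detection maps to the
transform's floor 0 and is tracked in a separate detection mask.  The
base and the +1 offset are conventions of this package — only "a log
transformation" is standard in the field — chosen so that non-detection,
detection at zero, and the transform's zero coincide.

## Case-control discovery

Per feature: detection frequency in each group; a two-sided Wilcoxon
rank-sum test on the log intensities with absences included at the
imputed 0 (lowest tied rank), so a peptide that disappears in one group
is detected by the same test that sees abundance shifts; and a fold
change defined as the ratio of group arithmetic means of the normalized
pre-log intensities with absences counted as 0.  The exact rank-sum null
is used when both groups have ≤ 8 observations and no ties; otherwise
the tie-corrected normal approximation.  P-values are adjusted by
Benjamini–Hochberg step-up.  The panel keeps features with q < α (0.05)
*and* detection frequency ≥ 90% in at least one group, ordered by
(q, feature_id) for reproducibility.

## SVM panel classifier

An RBF-kernel support vector machine with cost C = 16 and kernel width
γ = 0.01 — the conventional operating point for this platform — on
z-scored panel features (standardization constants fitted on the
training split only; an RBF kernel needs commensurate scales).  The
classification score is the signed distance to the decision boundary.
Cross-validation is leave-one-out by default (small-cohort convention;
stratified k-fold offered for speed), with the standardization and the
SVM refitted inside every fold.  The decision cutoff maximizes the
Youden index J = Se + Sp − 1 over midpoints between adjacent distinct
out-of-fold scores, ties broken toward the smaller cutoff (favoring
sensitivity, the clinically conservative side for a rule-out test).
Samples missing more than half of the panel features are scored (with
absences at the imputed 0) but flagged.

## Evaluation

AUC is the Mann–Whitney concordance probability with ties counting ½.
Its default confidence interval is DeLong's structural-components
variance; a Clopper–Pearson interval on concordant pairs is available.
Correlated AUCs on the same samples are compared with the paired DeLong
test (identical score vectors return Δ = 0, p = 1 by convention).
Operating points report Se/Sp with exact binomial CIs and NPV/PPV at an
externally stated prevalence (40% by default) via Bayes' rule, not the
sample prevalence.  A score of exactly the cutoff classifies positive.
Group-wise score comparisons use the tie-corrected Kruskal–Wallis test.
Replicate-score reproducibility is the percent coefficient of variation
(sample SD / |mean| × 100).

## Decision-curve analysis and nomogram

Net benefit at decision threshold t is NB(t) = TP/n − (FP/n)·t/(1−t),
with treat-all (π − (1−π)t/(1−t)) and treat-none (0) baselines on a
grid of 0.01–0.60 in steps of 0.01 (clinical interest concentrates
below 50%; margin added).  Raw SVM scores are mapped to probabilities by
logistic (Platt) calibration fitted on discovery out-of-fold scores; the
calibrator uses mild L2 regularization (C = 100) so the mapping stays
finite when the discovery scores are separable.  The integrative
nomogram is a maximum-likelihood logistic regression of biopsy outcome
on the panel score, age, PSA density and an externally supplied
ERSPC-style risk column, with Wald p-values per coefficient;
(quasi-)separation is reported as an error rather than returned as
divergent coefficients, and the pipeline omits the nomogram in that
case.

## Gleason-progression correlation

Tumor grade is encoded as an ordinal severity scale including the
controls: non-PCa = 0, GS6 = 1, 3+4 = 2, 4+3 = 3, GS8 = 4, GS≥9 = 5.
Each feature's log abundance is correlated with the ordinal by
tie-corrected Spearman rank correlation (two-sided p from the t
approximation).  Significant features (p < 0.05) with overall detection
frequency ≥ 30% are shortlisted; a parent protein counts as consistently
regulated when ≥ 75% of its peptides share the majority rho sign (an
exact 50/50 split fails).

## Protease-activity inference

Every endogenous peptide implies up to two proteolytic events: the
eight residues P4–P1|P1'–P4' around each terminus's scissile bond,
read from the parent protein (no event where the peptide is flush with
a protein end; windows clipped at an end are emitted truncated and
flagged, and never match exact-site records).  Specificity records are
either exact literature sites (string equality on the 8-mer) or
position-specific scoring matrices with a log10-probability threshold;
ambiguous residues (B/Z/X) never match exact sites and score as uniform
background in matrices.  Each protease with at least `min_sites = 5`
matched events receives the signed activity score

    xcorr = 100 × Σ over matched events (rho × detection frequency)

so proteases whose products rise with disease score positive.  The
formula is this package's concrete definition of a
frequency-and-abundance-weighted activity score; published scores from
proprietary tools are not numerically reproducible from it.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the study
conditions under which every downstream stage is validated.

Structure per cohort (defaults in parentheses):

* three splits — discovery (200 cases + 200 controls), validation
  (150 + 150), and a cases-only second validation (60) — sharing one
  feature universe (2000 features);
* latent log10 intensities per feature: mean ~ N(2.0, 0.6), SD ~
  U(0.15, 0.35); stored intensity = latent × per-sample scale factor
  10^N(0, 0.15) (urine dilution);
* detection is Bernoulli with a logistic link on the latent log
  intensity (slope 1 per latent SD) around a per-feature baseline rate ~
  U(0.05, 0.99), so missingness is intensity-dependent — the realistic
  hard case for frequency thresholds;
* 29 reference peptides, always detected, with 5% relative intensity
  noise around fixed targets;
* 181 planted markers with fold changes U(1.2, 3.0), 80% up-regulated,
  and baseline detection U(0.90, 0.99) — a discovered biomarker must by
  construction be able to pass the 90% frequency threshold;
* within cases, each marker adds a monotone log10 effect of
  direction × U(0.02, 0.08) per Gleason ordinal step, centered on the
  mean case ordinal so the marginal case-control shift stays exactly
  log10(fold);
* Gleason grades drawn with the mix 46.8 / 35.3 / 10.0 / 4.3 / 3.6 %
  (GS6 / 3+4 / 4+3 / 8 / ≥9), and clinical covariates with
  case-control shifts typical of biopsy cohorts (age +3 y, PSA ×1.12,
  volume ×0.79, DRE suspicious 30% vs 11%); the ERSPC-style risk column
  is simulated directly as expit(logit(0.3) ± 0.55 + N(0,1)), which
  yields an AUC near 0.65, the level reported for that comparator;
* all randomness flows from one seed through named (CRC-keyed)
  substreams, so editing one component leaves the others' draws intact.

For the protease stage, a planting helper embeds a subset of
up-regulated marker peptides into synthetic parent proteins so that all
their N-terminal windows equal one planted 8-mer, and builds decoy
proteases from the real C-terminal windows of signal-free peptides
(plus one 4-site decoy that must be excluded by the ≥5-site rule).

What the generator does **not** emulate: correlation between peptides
(features are independent given the sample scale), migration-time drift
or mass error, batch effects between centers, and the dependence
structure of real clinical covariates beyond simple location shifts.
Because 181 independent markers carry far more joint signal than 181
correlated collagen fragments, the SVM separates the synthetic cohorts
almost perfectly; passing tests therefore demonstrate correctness of the
machinery and recovery of planted structure, not the AUC level
achievable on patient data.  For the same reason the SVM scores saturate
near the decision margin, and mean-score monotonicity across disease
severity is checked at the three-way stratification
{non-PCa, GS6, GS≥7} rather than per Gleason category.

## Numerical choices

* SVC tolerance 1e-6 (tighter than sklearn's default) for score
  reproducibility across equivalent runs.
* Youden search and all panel orderings break ties deterministically
  (smaller cutoff; lexicographic feature id).
* Degenerate inputs have defined behavior: identical pooled values give
  rank-sum p = 1; constant scores make the Youden cutoff an error;
  ±∞ cutoffs give the (Se, Sp) limits with NaN for the undefined
  predictive value; empty panels are an error in the pipeline but legal
  in `select_panel`.
* Problem sizes in the test-suite and the acceptance script are the
  defaults above; the global-null false-discovery check uses 200
  replicates of a 30+30 × 200-feature null cohort.

## Known limitations

* The deposited patient data is not bundled; the pipeline's file-mode
  ingestion accepts its format (wide TSV / long CSV + clinical CSV), but
  all bundled validation is against synthetic ground truth.
* The ERSPC risk is always an input column; the calculator itself is out
  of scope.
* The nomogram requires a non-separated validation split; under the
  default synthetic conditions the panel separates perfectly and the
  pipeline reports the panel alone.
* Exact-site protease matching treats the two termini of one peptide as
  independent events and counts events, not unique genomic sites.
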