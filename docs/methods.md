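# Methods

This note documents the models, the synthetic-data generator, the
numerical choices and the limitations of `methfield`. Everything stated
here is computed by the test suite or `scripts/acceptance.py`; nothing is
quoted from external results.

## Study design the package assumes

A cohort of patients treated by radical prostatectomy, each contributing
3–5 tissue samples across three classes (cancer, normal adjacent to the
tumour, normal distant from it), profiled on a methylation array
(beta values in [0, 1]). Outcomes are patient-level: biochemical
recurrence (PSA > 0.2 ng/ml after surgery) and metastasis during
follow-up; metastasis implies recurrence in this design. The default
cohort shape is 16 patients (11 recurrence, 5 metastasis), ~64 samples,
with clinical follow-up spanning 8–16 years.

## Patient-aware group test

### Model

Per CpG, on the beta scale (an M-value switch exists but is off by
default, matching the scale on which effects are reported):

    y_ps = alpha + beta * g_p + b_p + e_ps,   b_p ~ (0, tau^2),  e_ps ~ (0, sigma^2)

Rather than fitting an unstable per-CpG maximum-likelihood mixed model
with 5–11 patients per group, the package uses the array-standard
consensus-correlation approximation:

1. per CpG, OLS residuals from `y ~ group` are decomposed by one-way
   ANOVA over patients; the method-of-moments intraclass correlation is
   computed (patients with ≥ 2 samples only);
2. those per-CpG estimates are pooled by mean atanh (variance-stabilized),
   clipped to (−0.95, 0.95), giving one consensus ρ;
3. per CpG, GLS with block compound-symmetry correlation ρ (analytic
   whitening per patient block), Wald t on the group coefficient with
   df = N − 2, then BH across CpGs.

If ρ is correct, the whitened residuals are i.i.d. and the t reference
distribution is exact; the calibration experiment (null cohort, 2,000
CpGs) verifies the q < 0.05 rate stays at the nominal level. Spiked CpGs
have a much higher true ICC than the consensus (by design: patient-level
effects dominate), which makes their tests mildly anti-conservative —
acceptable, as they are true positives.

Degenerate inputs: features with zero residual variance get NaN p and are
excluded from the BH family (q stays NaN). Masked beta values are imputed
by the probe mean for the vectorized GLS; the heterogeneity and
correlation statistics handle missing values pairwise-complete instead.

### Differential expression

Counts are transformed to log2 CPM with prior count 0.5 and tested with
the same GLS machinery; `grouping="tissue"` contrasts cancer vs pooled
normal samples as a within-patient contrast with the patient random
effect retained. CPM is compositional: when many genes shift in one
direction, unshifted genes move in relative terms, so recovery is
asserted on ranking, not on raw FDR against generator truth. No
TMM/voom-style normalization is implemented.

## Heterogeneity framework

* **Interpatient CV** — one uniformly drawn sample per patient (all
  tissue classes eligible), CV per CpG across patients, mean of 10
  iterations. Sample CV uses the n−1 denominator (small per-patient n;
  the conventional unbiased scale).
* **Intrapatient CV** — all samples per patient, one CV per
  (patient, CpG); single-sample patients are skipped and listed.
* **Matched nulls** — per iteration a sorted uniform draw of a
  size-matched CpG set from the filtered universe, scored identically and
  averaged per position (10 iterations for CV, 100 for correlation).
* **Similarity** — Spearman ρ (mid-ranks) between two samples per tissue
  type per patient ("normal" pools adjacent + distant by default; a flag
  splits three ways); with more than two samples, two are drawn once per
  run (seeded) and held fixed, including across null iterations. The
  cancer-vs-normal comparison correlates the patient's mean profiles.
* Distributions are compared by the two-sided Wilcoxon rank-sum test; the
  pooled patient × CpG intrapatient values enter the comparison.

## Enrichment

* The 17 ChromHMM labels collapse to six groups
  (5 promoter + 6 enhancer + 2 PRC + 2 transcribed + 1 heterochromatin +
  1 quiescent = 17; checked as a partition).
* Manifest positions are 1-based, BED segments 0-based half-open; the one
  conversion lives in `assign_cpgs_to_segments`: position p is inside
  [start, end) iff start ≤ p − 1 < end. Strand is ignored.
* TFBS padding is ±150 bp with starts clamped at 0; touching intervals
  merge (half-open adjacency has no gap). A CpG inside several TFs'
  regions counts for each TF.
* p-values are one-sided hypergeometric upper tails against the full
  probe background; BH within the natural family (six groups of one
  track; the TF set of one run). Cell-line tracks are analyzed
  separately, never unioned. TFs with no background CpG are dropped and
  listed.

## Risk model

Elastic-net Cox with Breslow ties, fit by Newton iterations with inner
coordinate descent on the Gram form of the weighted least-squares
surrogate (the glmnet scheme), features standardized internally,
monotone-objective step-halving, and a convergence criterion requiring
both a small step and a small objective gain. The implementation agrees
with an independent Newton–Raphson oracle at λ = 0 (to 1e-6) and with
scikit-survival's coxnet at matched penalties (test suite).

The stability selection leaves one **sample** out per iteration by
default; a `group_by_patient` option leaves out
whole patients instead, because same-patient samples in train and test
leak outcome information — users validating biomarkers should prefer it.
Penalty strength is chosen per iteration by inner 5-fold cross-validated
partial-likelihood deviance (Verweij–van Houwelingen), with each fold's
deviance normalized by its held-out event count and the **1-SE rule**
applied. The 1-SE rule (over the deviance-minimizing λ) is what keeps
pure-noise candidates from stabilizing: with mostly-ridge mixing, any
λ below the selection point makes *every* coefficient nonzero, so an
aggressive λ choice would inflate selection frequencies on noise. The
mixing parameter 0.1 is read as the elastic-net mixing constant (mostly
ridge), consistent with the intent of keeping most candidate CpGs in the
model; a config option allows treating it as the penalty strength
instead.

Final model: candidates nonzero in strictly more than 50% of iterations;
coefficient = mean of nonzero per-iteration values; cutoff = median
training risk score; ties at the cutoff go to high-risk (deterministic,
documented, arbitrary). Non-convergent iterations are skipped and
counted; more than 20% skips is an error.

## Synthetic cohort generator

Beta values are generated on the logit scale and back-transformed, which
guarantees (0, 1) for any effect size and gives an explicit
within-/between-patient variance decomposition:

    logit(beta_jps) = mu_j + shift_j * outcome_p + b_jp + e_jps

* Baselines `mu_j`: array-like bimodal mixture (40% hypomethylated around
  logit beta ≈ 0.12, 40% hypermethylated ≈ 0.88, 20% intermediate).
  Spiked (prognostic) CpGs sit near beta 0.30 so a group shift of 0.2 on
  the beta scale stays well inside (0, 1); the shift is computed on the
  logit scale to land exactly at the target mean beta.
* Noise scales (logit SD): spiked CpGs σ_inter = 0.30 between patients,
  σ_intra = 0.03 within (the 1:10 ratio realizes "high between-patient,
  low within-patient variation"); background CpGs σ_inter = 0.20,
  σ_intra = 0.15 (random array CpGs show comparable intra- and
  interpatient CV). These defaults yield median interpatient CV ≈ 0.34
  for the spiked panel vs ≈ 0.12 for random CpGs, and intrapatient CV an
  order of magnitude below — the qualitative structure the analysis is
  meant to detect. They were fixed analytically from the variance
  decomposition before any recovery experiment was run.
* Spiked sets: 37 recurrence DMCs (random shift direction) and 20
  metastasis DMCs (80% loss of methylation in the metastasis group, the
  direction expected late in progression), overlapping ~10%.
* QC failures: 100 designated probes (bead count < 3, detection
  p > 0.05, or SNP within 5 bp), never on spiked probes.
* Chromatin tracks: each of two synthetic cell lines partitions every
  chromosome at midpoints between consecutive CpGs, so each CpG is
  covered exactly once and its state is drawn per CpG. Background state
  weights reflect an array probe universe (promoter group ≈ 20% — array
  probes are deliberately promoter/island-biased — with quiescent
  chromatin dominating the rest); recurrence-spiked CpGs draw promoter
  states at a rate elevated by the configured factor. TFBS tracks place
  ~300 random sites per factor, plus sites within 150 bp of every spiked
  CpG for the planted factors.
* Survival: exponential event times with patient hazard
  λ_0 · exp(link), λ_0 = log 2 / 120 months, censored at a uniform
  96–192-month follow-up. `prognostic_risk_link` gives log(HR) per SD of
  patient-mean beta per prognostic CpG (default HR 2).
* Expression: gene counts via Poisson sampling of relative abundances
  with tissue (cancer vs normal) log2 fold changes on genes annotated to
  spiked CpGs plus a random 10%, patient effects, and no outcome effect.

What the generator does **not** emulate: probe cross-hybridization, batch
and array position effects, cell-composition differences, raw
intensities, genuine genomic correlation among neighbouring CpGs, and
negative-binomial overdispersion in counts. Passing recovery tests
therefore demonstrates the pipeline's correctness under its stated
assumptions, not performance on real tissue data.

## Problem sizes used in the checks

The bundled experiments run at the generator's default conditions:
10,000 probes and ~64 samples for DMC recovery (five cohorts pooled),
2,000 probes for null calibration, 50 TFs with 5 planted for enrichment,
and ten cohorts for the risk-model recovery. The end-to-end determinism
check uses a 1,500-probe cohort, rerun twice and compared byte for byte
(the wall-clock log excepted).

## Known limitations

* The consensus correlation is a single cohort-wide constant; CpGs whose
  true ICC differs strongly from it get approximate (not exact) p-values.
* Probe-level QC fields are per-probe scalars (worst case across
  samples); per-sample detection-p masking is not implemented.
* The log-rank p uses the χ²₁ approximation; no exact or permutation
  version.
* Percentages in the cohort summary use non-missing denominators and one
  decimal; IQR is the 25th/75th percentile with linear interpolation.
* Genome build is treated as opaque: coordinates are never lifted over,
  and all tracks must share the cohort's build.
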