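# Methods

## Scope

`melanoprs` implements a case-control risk-prediction analysis for
melanoma: construction of a polygenic risk score (PRS) from external
per-SNP weights, combination with a traditional risk-factor model, and
evaluation of the genomic score's incremental value. The package also
contains a synthetic data generator that emulates the two study designs the
machinery targets, so all statistical components can be validated by
parameter recovery and oracle equivalence rather than against unavailable
individual-level data.

## Risk scores

The PRS is the log-OR-weighted dosage sum
S_i = Σ_j (d_ij − c_j) ln OR_ij with c_j = 2·eaf_j when centering is on
(default). Centering shifts every participant by the same per-SNP constant,
so ranks, tertiles and all discrimination metrics are invariant to it; it
is on by default because a centered score is approximately mean-zero in the
source population and spans negative and positive values, which is how such
scores are conventionally reported. The log-OR-weighted sum is implemented
as the single scoring rule.

*MC1R* stratification: the melanoma association of *MC1R* variants is
modified by pigmentation phenotype, so each *MC1R* row of the weights
manifest may carry a sun-sensitive and a not-sensitive OR in addition to
the overall one. A participant is sun-sensitive if they have any of
freckles (few/some/many), red hair, or skin that usually or always burns.
*MC1R* membership is an explicit manifest boolean (`is_mc1r`) rather than
gene-symbol matching, keeping stratification auditable. With both
stratified ORs equal to the overall OR, stratified scoring reproduces
unstratified scoring exactly (tested).

The traditional score is the analogous linear predictor over categorical
risk-factor levels (log OR relative to each factor's reference level),
returned on the log-odds scale; any monotone rescaling would leave tertile
assignment and rank-based metrics unchanged.

### The packaged weight manifest is a skeleton

The canonical external weight set (45 SNPs in 21 genes; pathway SNP counts
pigmentation 31, nevus 13, telomere/senescence/other 9, with genes allowed
in multiple pathways) is shipped as
`data/synthetic_default_weights.tsv`. Thirty-one variant identifiers are
well-known melanoma GWAS hits (including eight *MC1R* protein variants);
the remaining 14 SNP ids (prefixed `syn_`) and three genes are synthetic
placeholders inserted to complete the pathway bookkeeping, and **every
allele frequency and odds ratio in the file is synthetic** — plausible in
magnitude (*MC1R* R alleles strongest, stratified ORs larger in the
non-sun-sensitive stratum) but not estimates from any source. Validation
enforces the 45/21/31/13/9 counts for this skeleton. Real analyses must
supply their own weights TSV; the example traditional weights in
`scoring.py` are synthetic in the same sense.

## Model combination

Externally weighted scores enter logistic models as offsets with
coefficient pinned to 1, while the forced demographic/design covariates
(age, sex, center, ancestry) and the intercept are estimated freely. This
keeps the external weights fixed (no overfitting to the analysis sample)
while still adjusting the predicted probabilities for design factors. A
free-covariate route (score as an ordinary term) is available by adding the
score column to a `ModelSpec` for internally derived analyses.

Logistic fits use statsmodels' GLM/Binomial IRLS (convergence tolerance
1e-10, max 200 iterations). Perfect or quasi-perfect separation is
diagnosed explicitly (any fitted probability outside (1e-10, 1 − 1e-10)
raises), and singular designs raise an error naming the collinear columns.
Categorical terms expand to indicators against a reference level (the first
level in the factor's canonical ordering); a single-level factor
contributes no columns, so a constant design covariate (e.g. one
recruitment center) is harmless rather than singular.

Backward selection refits the model repeatedly, testing every candidate
term by likelihood-ratio test (multi-level factors jointly — LR chosen over
Wald because it handles joint multi-df tests naturally) and removing the
candidate with the largest P ≥ 0.20 (ties broken toward the later list
position) until all remaining candidates have P < 0.20. Forced terms are
never droppable.

Tertile/decile OR tables cut the score at quantiles of a reference sample
(per-study by default; pooled available, reflecting that published category
boundaries can come from a pooled sample while per-study totals are exact
thirds). Intervals are half-open with boundary values going to the upper
category. The trend P is the Wald P of the ordinal category index (1..k)
entered as a single term — the conventional "P trend" construction; the
continuous-score alternative can be obtained by entering the raw score.

Cross-validation stratifies folds by case status (shuffled by the supplied
seed); `k = n` is deterministic leave-one-out. The CV AUC is computed on
the pooled out-of-fold probabilities.

## Evaluation statistics

* **AUC**: Mann–Whitney estimator (ties count ½), computed via midranks;
  variance from per-subject placement values (case and control components),
  95% CI normal-approximate and clipped to [0, 1]. The paired ΔAUC test
  uses the variance of the placement-value differences on the same sample;
  (ΔAUC)²/var is referred to chi-square with 1 df. The placement-value
  route was chosen so the single-model CI and the paired comparison share
  machinery; it is validated against exhaustive pair enumeration (exact)
  and a bootstrap variance (within 15%).
* **Continuous NRI**: event component P(up | case) − P(down | case),
  non-event component P(down | control) − P(up | control); ties count to
  neither direction. Component variances use the binomial-difference
  asymptotic form [p_up + p_down − (p_up − p_down)²]/n_group; the total's
  variance is the sum of the two independent components. These conventions
  (and the CI formula) follow the standard category-free NRI construction
  and are labelled asymptotic in the output.
* **OPERA**: the score is regressed on the adjustment covariates (default
  age and sex) among controls only; the adjusted SD is the sample SD of the
  control residuals (controls represent the reference population; a
  whole-sample option exists via the covariate argument and caller-side
  residualisation); the score divided by that SD enters an adjusted
  logistic model and the OR per adjusted SD is the exponentiated
  coefficient with Wald CI. The result is invariant to affine rescaling of
  the score (tested).
* **Hosmer–Lemeshow**: equal-size groups (default g = 10) of predicted risk
  (stable sort keeps tied predictions in input order), statistic
  Σ (O−E)²/(E(1−E/n_g)), chi-square with g − 2 df. Equal-size deciles and
  g − 2 df are the conventional choices; both are configurable. g = 2 has
  0 df and returns P = NaN (degenerate, statistic still reported).

Tertile cross-tabulation: cutpoints at the 1/3 and 2/3 sample quantiles,
boundary values to the upper category; with distinct values this yields
equal thirds (345/345/345 at n = 1,035), which can differ by one from
published tables produced under another quantile convention — comparisons
against printed tables are therefore made on the printed counts themselves,
which ship as package data (`data/reference_crosstabs.json`). Display
percentages round half-up; full precision is kept internally.

## Synthetic data generator

The generator defines the conditions under which the pipeline is validated:

* **Genotypes**: independent SNPs in Hardy–Weinberg proportions
  (Binomial(2, eaf) per SNP). No linkage disequilibrium, imputation
  uncertainty or population structure — the score treats SNPs additively,
  so independence suffices for exercising the machinery.
* **Phenotypes**: categorical traits drawn from configurable marginal
  frequencies (defaults are placeholders plausible for a fair-skinned
  European-ancestry population, not estimates of any study). Red hair,
  heavy freckling and burn propensity are coupled to *MC1R* dosage through
  per-SNP log-odds increments (default 0.9 per effect allele in the
  study-like configuration), so *MC1R* effects are partially mediated by
  observable phenotype and the effect-modification machinery is
  exercisable. Age is uniform within the profile's window; vacation sun
  exposure is a latent standard normal cut at its theoretical quartiles.
* **Outcome**: disease probability is logistic in an additive linear
  predictor (per-SNP log ORs plus per-level phenotype log ORs), with the
  intercept solved numerically (root-finding to 1e-8) so the
  source-population prevalence equals the profile's baseline prevalence
  (default 0.01). Cases and controls are then sampled without replacement
  to the profile's exact quotas within the design age windows — the
  early-onset profile takes cases only below age 40 and controls below 45
  (578/457); the unrestricted profile spans 18–82 (964/496); both are 60%
  female. Case-control ascertainment leaves per-allele ORs unbiased
  (tested by refit coverage).
* **Missingness** is off by default (the analysis is complete-case); an
  optional rate exists to exercise the `complete_cases` filter.

What passing tests show — and don't: parameter recovery and oracle
equivalence on this generator validate the estimators and bookkeeping, not
the epidemiology; real data have LD, correlated phenotypes, measurement
error and selection structure the generator deliberately omits.

## Problem sizes and seeds

Simulation-based checks use a 150,000-person source population for the
full-quota study profiles, 4,000–20,000 for single-SNP recovery, 50
replicates for CI-coverage checks, 1,000 replicates (n = 500) for the
Hosmer–Lemeshow size check, and three replicates of the full study-like
configuration for the directional incremental-value check — sizes chosen so
Monte-Carlo error is small relative to the tolerances being asserted. All
randomness flows through explicit integer seeds (NumPy `SeedSequence`
children; no global state), so every pipeline run and the acceptance script
are exactly reproducible.

## Known limitations

* No allele harmonisation / strand flipping: dosages are assumed to be on
  the manifest's effect allele; imputed (non-integer) dosages are accepted
  in [0, 2] but not modelled further.
* No penalised regression or Firth correction; separation is diagnosed,
  not repaired.
* Categorical NRI, integrated discrimination improvement and
  decision-curve analysis are out of scope, as are between-study
  interaction tests and per-tertile stratified discrimination analyses.
* The packaged weight manifest and traditional weights are synthetic
  skeletons (above); results computed from them characterise the software,
  not melanoma epidemiology.
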