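# Methods

This note documents the statistical models, the defaults and why they
were chosen, the numerical decisions, and what the synthetic-data tests
do and do not establish about real data.

## Phenotype calling and count extrapolation

A marker panel is seven thresholded booleans. The calling rule is a
total function: cells positive for CD45 (hematopoietic), CD31
(endothelial) or DAPI (nuclear stain accessible → membrane-compromised,
dead cell) are never CTCs; remaining cells need at least one positive
cancer-marker axis (epithelial = EpCAM ∨ E-cadherin; mesenchymal =
csVIM ∨ MCAM), and the label is eCTC / mCTC / emCTC for
epithelial-only / mesenchymal-only / both. Two asymmetries are
deliberately *not* encoded: EpCAM⁺/ECAD⁻ and ECAD⁺/EpCAM⁻ both count as
epithelial (no evidence supports distinguishing them), and DAPI is a
hard exclusion rather than a soft flag.

When only a fraction f ∈ (0, 1] of an enriched sample is screened, the
observed count is extrapolated as `observed / f`, producing legitimate
fractional per-5 mL counts (e.g. 1.1 mCTCs). f is supplied per sample by
the user; no formula derives it from volumes. Descriptive statistics keep
the fractions; only Poisson fitting rounds (half-up), because the
likelihood needs integers.

qPCR relative quantities use RQ = 2^(CqMAX − Cq) with CqMAX = 35 as the
last quantifiable cycle; undetected reactions and Cq > CqMAX map to
RQ = 0 rather than an error, since values past the last considered cycle
carry no quantitative information.

## Multi-response Poisson model and selection

"Multi-response" is realized as three independent Poisson log-linear
regressions sharing one predictor subset; the joint log-likelihood is the
sum. No cross-response covariance is modeled: effects are reported
separately per response, and one overall pseudo-R² is computed from the
joint likelihood.

**Fitting.** IRLS maximum likelihood on dense design matrices
(intercept + 0/1 predictor columns), convergence at max|Δβ| < 1e−10
within 100 iterations. A separation guard marks any fit with |β| > 15
non-converged (rate ratios beyond e¹⁵ are numerically meaningless for
cohort-scale counts). The hand-written fitter exists because exhaustive
selection with repeated cross-validation needs on the order of 10⁵ small
fits; it is verified in the test suite against the closed-form two-group
MLE and against an independent GLM implementation (statsmodels) to 1e−6.

**Inference.** Wald construction throughout: IRR = exp(β), 95% CI
exp(β ± 1.959964·se), two-sided normal p-values. No multiplicity
correction is applied to the IRR table.

**Cross-validation.** Per repetition, a fresh uniform random partition
into k = 10 folds (sizes differ by ≤ 1). Per fold: fit on the training
folds; record the held-out log-likelihood, the training fit's AIC
(2k − 2ℓ), and the RMSE of predicted means against observed counts on
the count scale, pooled over the three responses within the fold.
Metrics average over folds within a repetition, then over repetitions
(default 500; scaled-down runs use 50). The RMSE definition (count
scale, per-fold, response-pooled) is one defensible reading among
several; it makes separation-induced blow-ups visible in avg.RMSE.

Any fold in which a response fit fails to converge is dropped and
counted; by default a single failed fold excludes the model from
competition, mirroring the manual exclusion of predictor combinations
with convergence trouble. Subsets containing a declared excluded pair
(e.g. grade with cN) are enumerated but flagged non-competing.

**Paired partitions.** All candidate models are cross-validated on the
*same* sequence of fold partitions (one shared seed). Between-model
differences in avg.RMSE then reflect the models rather than partition
luck. This matters: with independent partitions per model, selection
noise is dominated by which models drew easy test folds.

**Ranking.** Lexicographic (min avg.RMSE, max avg.logLik, min avg.AIC);
with continuous metrics avg.RMSE effectively decides, and the remaining
criteria are documented tie-breaks.

**Known limitation — CV overselection.** Cross-validated selection among
nested models is not consistent: a truly null predictor whose sampled
association with the counts is spuriously strong in a given cohort draw
helps held-out prediction too (the held-out folds come from the same
draw), so the selector admits a superset of the true predictors in
roughly 20% of simulated cohorts at n = 300, essentially independent of
effect size and repetition count. The selection-consistency check in the
acceptance suite therefore uses a balanced simulation design (all
candidate prevalences 0.5, strong log-IRR = log 3 effects on the two true
predictors): rare binary covariates have higher coefficient variance and
inflate overselection, which would measure the design asymmetry rather
than the selector. Expect the 80%-recovery bar to sit at, not comfortably
above, the procedure's inherent accuracy.

**Pseudo-R².** Nagelkerke's rescaled likelihood-ratio R² with n = number
of patients; the joint value uses the summed log-likelihoods, and
per-response values use the per-response likelihoods against each
response's intercept-only model. A predictor's partial R² for a response
is the drop in that response's R² when the predictor is removed from the
full model (single-predictor models therefore have partial = overall for
each response). Partial values can be slightly negative in finite
samples; they are reported unclipped.

## Single-cell stages

**QC.** Cells with ≥ 800 detected genes (count > 0) are retained —
inclusive boundary. The multiplex-PCR quality rule (≥ 2 of EEF1A1, ACTB,
GAPDH) is a separate, earlier gate for the low-throughput workflow.

**Origin classification.** The protein rule dominates: cells whose
picking-time panel shows neither cancer-marker axis are true normal
cells (tNC) regardless of transcriptome. Protein-CTC-positive cells are
true CTCs (tCTC) when every configured immune/endothelial transcript is
strictly below the expression threshold, and potential normal cells
(pNC) at or above it. The default marker list is PTPRC and PECAM1 (the
transcripts encoding the CD45/CD31 exclusion proteins) and the threshold
is 4 on size-factor-normalized counts; both are configuration, echoed
into the run report, because the full lineage marker list and the
normalization behind the published threshold are not enumerable from the
source material. A panel that is cancer-marker-positive *and*
CD45/CD31/DAPI-positive is contradictory and raises rather than guesses.

**EMT score.** (Σ_mes − Σ_epi) log10(RPM + 1) divided by the total panel
size (10). RPM is per-cell count/total × 10⁶; zero-total cells are an
error naming the cell. Panel genes absent from the matrix score as RPM 0
with a logged warning (panels may reference genes filtered upstream).
Quartile classes use strict inequalities (score < Q1 → eCTC, > Q3 →
mCTC) over the population being classified, with numpy's linear
order-statistic interpolation (plotting position (k−1)/(n−1)) as the
default convention; the convention is a parameter and is recorded in the
report because alternative conventions can shift tail membership by one
cell on small populations.

**Normalization.** Median-of-ratios: size factor per cell = median over
reference genes of count / per-gene geometric mean; reference genes are
those non-zero in every cell, falling back (logged) to genes non-zero in
≥ 50% of cells with geometric means over their non-zero entries — sparse
single-cell matrices frequently have no all-non-zero gene. Size factors
are relative, as in the median-of-ratios literature: per-cell depth
distortions are removed exactly, while a uniform global rescale is
indistinguishable from deeper sequencing and propagates to the
normalized values.

**DEG rule.** Per gene: two-sided Student t-test (equal variance;
Welch behind a flag) on log2(normalized + 1); log2 fold change of group
medians with pseudocount 1 (per-cell ratios are undefined across
unpaired cells; the pseudocount prevents division by zero);
Benjamini–Hochberg across all tested genes when FDR mode is on
(validation-style analysis) and raw p-values otherwise
(discovery-style). Calls: significant and log2FC ≤ −1 → down, ≥ +1 → up,
else unchanged. Genes in the erythroid/platelet exclusion panels are
removed before testing and reported as `excluded`; the shipped default
panels are small canonical seed lists (haemoglobins; platelet granule
genes) — production analyses should supply the full curated lists as
plain-text panels. Genes with zero variance in both groups get NaN
p-values, an `unchanged` call and a flag. The test's input scale
(log2 of normalized counts) is a documented choice; nothing in the rule
depends on it beyond monotonicity.

## Synthetic-data generators

The cohort generator draws independent Bernoulli covariates at
configured prevalences (an optional Gaussian-copula correlation hook
exists because real clinical covariates are correlated; it defaults to
independence) and Poisson counts with log-mean = baseline + Σ x·log-IRR.
`study_cohort_config()` encodes the study-scale conditions: n = 96
patients, the selected model's IRRs for cT₂₋₄, cN⁺ and lobular histology
on each phenotype, plausible prevalences (0.55 / 0.35 / 0.15), and
baseline rates (0.15 / 0.4 / 1.0 per 5 mL) chosen to reproduce
median-zero eCTC/emCTC counts with an mCTC median near 1. The reported
eCTC IRR for lobular histology was 0 (perfect separation in the real
cohort); a log-linear model cannot encode a zero rate ratio, so 0.05
stands in.

The expression generator draws negative-binomial counts (gamma–Poisson
mixture, stable for any dispersion; variance m + m²/r, Poisson limit
r → ∞) with per-(class, panel) log2 mean shifts — epithelial cells
up-shift the epithelial panel, mesenchymal cells up-shift the
mesenchymal panel and *down*-shift ribosomal genes (−2, i.e. 4-fold),
leukocytes up-shift immune genes, and erythroid/platelet markers are a
uniform +2 background in all classes — thinned by i.i.d. Bernoulli
dropout (default 0.3). Defaults (60 cells in three classes, 1000 genes,
base mean 5, dispersion 2) keep test matrices small while preserving the
structure the downstream stages assume.

What the generators deliberately do **not** emulate: read-level data,
batch effects, doublets, gene–gene correlation beyond panel structure,
mean–dispersion trends, or cohort-matched covariate correlation. Passing
tests therefore establish correctness of the algorithms under their own
assumptions and calibration under the generative model — not performance
on any real cohort, whose headline quantities (specific IRR values,
explained-variability percentages, DEG counts) depend on patient-level
data that are not reproducible from summary statistics.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; fixed seed ⇒
bit-identical tables, matrices and cross-validation metrics. The
acceptance script and test suite use scaled simulation sizes chosen as
the package's own defaults for desk-scale verification: 200 cohorts of
n = 1000 for Wald coverage, 20 runs × 50 CV repetitions at n = 300 for
selection consistency, 3000 genes for DEG type-I calibration, n = 5000
for IRR parameter recovery.
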