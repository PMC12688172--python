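# ctc-emt

Analysis pipeline for studies of circulating tumor cells (CTCs) across the
epithelial–mesenchymal transition (EMT) spectrum in early breast cancer.
It is written for groups that enumerate CTCs by multi-marker
immunofluorescence (EpCAM, E-cadherin, cell-surface vimentin, MCAM, with
CD45/CD31/DAPI exclusion), relate per-patient phenotype counts to clinical
covariates, and profile micromanipulated single cells by full-length
scRNA-seq.

## What it computes

**Phenotype calling.** A cell is a CTC when CD45, CD31 and DAPI are absent
and at least one cancer-marker axis is positive; epithelial-only → eCTC,
mesenchymal-only → mCTC, both → emCTC. Counts observed in a screened
sample fraction are extrapolated to 5 mL blood (`observed / fraction`).
Helpers cover enrichment/depletion and spike-in recovery metrics and the
qPCR transform RQ = 2^(CqMAX − Cq) with CqMAX = 35.

**Count modeling.** The three phenotype counts are modeled jointly as
three Poisson log-linear regressions sharing one predictor subset
("multi-response"); effects are incidence-rate ratios IRR = exp(β) with
95% Wald intervals. Model selection enumerates all 2^p predictor subsets
(16 for the 4 clinical candidates cT, cN, grade, histological type),
scores each by repeated 10-fold cross-validation — held-out log-likelihood
(avg.logLik), training AIC (avg.AIC) and held-out count-scale RMSE pooled
over the three responses (avg.RMSE), averaged over folds then
repetitions — and ranks by (min avg.RMSE, max avg.logLik, min avg.AIC).
Subsets containing a user-declared excluded predictor pair, or whose fold
fits fail to converge (quasi-separation), do not compete. Explained
variability is Nagelkerke's pseudo-R²,

    R² = [1 − exp((2/n)(ℓ₀ − ℓ₁))] / [1 − exp((2/n) ℓ₀)],

with a predictor's partial R² per response defined as the drop in that
response's R² when the predictor is removed from the selected model.

**Single-cell stages.** QC keeps cells with ≥ 800 detected genes (and a
2-of-3 housekeeping rule for the PCR workflow); origin classification
combines the picking-time protein panel with immune/endothelial
transcripts (PTPRC, PECAM1; normalized expression < 4 → tCTC, ≥ 4 → pNC,
protein-negative → tNC). The EMT score per cell is
(Σ_mes log10(RPM+1) − Σ_epi log10(RPM+1)) / 10 over fixed mesenchymal
(FN1, CDH2, SERPINE1) and epithelial (KRT5/7/8/18/19, EPCAM, CDH1) panels,
with quartile classes (score < Q1 → eCTC, > Q3 → mCTC). Differential
expression uses median-of-ratios size factors, erythroid/platelet marker
exclusion, per-gene Student t-tests on log2(normalized + 1), a
median-based log2 fold change, optional Benjamini–Hochberg correction,
and the rule |log2FC| ≥ 1 and significant → up/down.

**Synthetic data.** `ctc_emt.synthetic_data` generates cohorts from the
same log-linear Poisson law the model assumes (configurable IRRs) and
overdispersed (negative-binomial, dropout-thinned) count matrices with
epithelial/mesenchymal/immune/ribosomal marker structure, so every stage
is testable with known ground truth.

## Worked example

```python
import math
from ctc_emt import (CohortConfig, DesignSpec, fit_multiresponse,
                     generate_cohort, irr_table, run_selection)
from ctc_emt.phenotyping import PHENOTYPES

cfg = CohortConfig(
    n_patients=300,
    predictor_prevalences={"cN": 0.4, "cT": 0.5, "grade": 0.3},
    true_log_irr={(ph, "cN"): math.log(2.85) for ph in PHENOTYPES},
    baseline_log_rate={ph: 0.0 for ph in PHENOTYPES},
    seed=1,
)
table, truth = generate_cohort(cfg)
result, scored = run_selection(table, ["cN", "cT", "grade"], reps=50, seed=1)
print("best model:", result.best.label())
best = fit_multiresponse(table, result.best)
for est in irr_table(best):
    if est.predictor == "cN":
        print(f"{est.response}: IRR {est.irr:.2f} "
              f"[{est.ci_low:.2f}-{est.ci_high:.2f}] p={est.p_value:.2g}")
```

prints (seed 1):

```
best model: cN
eCTC: IRR 2.72 [2.27-3.25] p=2e-27
emCTC: IRR 2.87 [2.39-3.45] p=2.2e-29
mCTC: IRR 2.37 [1.98-2.85] p=1.1e-20
```

The selector recovers the single true predictor, and each per-phenotype
IRR estimate brackets the generative value 2.85 in its 95% interval.

A command-line entry point wraps the same functions:

```bash
ctc-emt simulate --n-patients 96 --seed 1 --outdir run/
ctc-emt model-select --cohort-csv run/cohort.csv \
    --candidates cT234,cN_pos,lobular --reps 50 --seed 1
ctc-emt emt-score --matrix run/matrix.tsv
```

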