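# omicsig

Sparse-learning biomarker screening for cancer prognosis from multi-omics
expression data.

Bulk tumor cohorts typically carry several molecular layers per patient —
lncRNA, miRNA and mRNA expression, DNA methylation, protein abundance —
together with survival follow-up.  `omicsig` implements a complete,
testable version of the sparse-learning analysis used to screen such
cohorts for prognostic signatures: it filters low-purity samples, screens
each layer for features that separate good- from poor-survival patients,
infers group-specific regulatory networks by per-feature penalized
regression, assembles a fixed-size multi-omics signature with an
L1-penalized logistic model, and evaluates everything with stratified
cross-validation and Kaplan–Meier/log-rank survival comparisons.  A
synthetic-cohort generator with fully known ground truth (network, DE
features, hazard drivers) makes every stage quantitatively checkable
without any data download.

## The model

**Regulatory networks.** For each feature *i* of a layer, expression is
modeled linearly in all other features,

    g_i = G_{−i} b_i + ε_i ,   subject to ‖b_i‖₁ ≤ C_i ,

whose Lagrangian form is the LASSO objective

    ‖g_i − G_{−i} b_i‖² + λ‖b_i‖₁ .

The coefficient vectors stack into an adjacency matrix B = {b_1, …, b_p}ᵀ;
fitting separately on poor-survival and good-survival samples yields the
group-specific networks Bᵀ and Bᶜ.  The package solves each regression
with cyclic coordinate descent (soft-thresholding), stabilized by the
two-step **Random LASSO**: bootstrap fits on random candidate subsets
produce per-feature importances, then a second bootstrap round draws
candidates proportionally to importance and averages the coefficients.

**Differential expression.** An empirical-Bayes moderated t shrinks each
feature's pooled variance toward a prior fitted by method of moments on
log s², exactly as in the limma methodology (verified against
Bioconductor limma to 1e−8); Benjamini–Hochberg controls the FDR at 0.05.

**Prognostic signature.** Per layer, DE features are ranked by bootstrap
logistic-LASSO importance against the survival-group label and truncated
to fixed sizes — 5 lncRNAs, 11 miRNAs, 30 mRNAs, 4 methylations, 3
proteins by default — then a single penalized logistic model is refit on
the kept features.  Evaluation is stratified fivefold cross-validation
with balanced bootstrap resampling of training folds, reporting accuracy,
error rate and the Matthews correlation coefficient.

## Worked example

```bash
python examples/signature_cv.py
```

prints (seed 7):

```
244 samples retained after the purity cut
DE features per layer: {'lncRNA': 137, 'miRNA': 146, 'mRNA': 123, 'methylation': 146, 'protein': 105}
signature sizes: {'lncRNA': 5, 'miRNA': 11, 'mRNA': 30, 'methylation': 4, 'protein': 3}
CV accuracy 1.000, error 0.000, MCC 1.000 (best fold 1.000)
```

A 300-sample synthetic cohort loses 56 samples to the 60% tumor-purity
cut; the moderated-t screen keeps 105–146 features per layer at FDR 0.05;
the signature truncates these to the fixed per-layer sizes; and on this
strong-signal cohort (two-SD group shifts) the cross-validated classifier
separates the survival groups perfectly.  `examples/` contains analogous
walkthroughs for the generator, the DE screen, Random LASSO, network
inference, survival analysis and the end-to-end pipeline
(`full_pipeline.py` writes the complete report bundle: `signature.tsv`,
`cv_report.txt`, per-layer adjacency/edge TSVs, KM curves and log-rank
tests).

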