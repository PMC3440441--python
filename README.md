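# coldheat

Subtype discovery for two-class patient cohorts, built around the study
design that characterized **Cold** and **Heat** subtypes of rheumatoid
arthritis (RA) patients from symptom questionnaires, clinical chemistry and
LC-MS metabolomics. The package is aimed at biostatisticians and
metabolomics analysts who need the two core machines of that design as
tested, reusable code:

1. **Forced-classification nonlinear PCA (optimal scaling / CATPCA).**
   Categorical variables (1–7 symptom scores, clinical values uniformly
   binned into 19 categories) receive category quantifications `y_j` chosen
   by alternating least squares so that the variance of the transformed
   variables accounted for (VAF) by the principal component is maximal,
   subject to each variable's analysis level (nominal, ordinal,
   spline-nominal, spline-ordinal, numeric). With object scores `x`
   (mean 0, `x'x = n`), quantified variables `q_j` and loadings
   `a_j = q_j'x/n`, the per-variable VAF is `a_j²`. The binary class label
   enters as a variable with weight 1000, which forces the component onto
   the class contrast and separates the two classes' object scores
   completely. Variables with VAF > 0.20 are selected, the model is
   validated by leave-two-out cross-validation (stratified pairs; at n = 39
   that is 19 pairs plus a singleton, 37 training subjects per fold) and by
   permutation testing.

2. **PLS-DA with double cross-validation and jack-knife selection.**
   Feature tables are presence-filtered (nonzero in ≥80% of one class),
   zeros replaced by half the feature's smallest measured value, urine
   mean-centered and plasma autoscaled, and QC-screened by PCA. A
   deterministic NIPALS PLS1 regresses the −1/+1 class coding on the
   features; an inner leave-two-out loop picks the number of latent
   variables, an outer loop estimates the classification error without
   leakage, unstable features (coefficient small relative to its
   cross-fold standard error) are eliminated stepwise, and significance is
   assessed against 250 label-permuted models: the model passes when its
   error beats the 5th percentile of the null errors.

A seeded synthetic-cohort generator reproduces the study's design
(20 Cold / 19 Heat subjects; 57 items of which 15 lose all variation after
category merging; monotone and "high as well as low" quadratic clinical
relationships; log-normal LC-MS intensities with planted 2log Cold/Heat
effects, detection-limit zeros, pooled-QC replicates with injection-order
drift, and an acylcarnitine-like family with the diagnostic 59.0747 Da
neutral loss) together with ground truth for recovery tests. See
`docs/methods.md` for the model details and the generator's assumptions.

## Worked example

Questionnaire + clinical protocol on a synthetic cohort:

```python
from coldheat import (CategoricalDataset, CohortConfig, ScalingSpec,
                      generate_cohort)
from coldheat.preprocess import (bin_clinical, drop_single_category_variables,
                                 merge_sparse_categories)
from coldheat.workflows import nlpca_protocol

cfg = CohortConfig(seed=7)                      # 20 Cold / 19 Heat, 57 items
q, clin, urine, plasma, truth = generate_cohort(cfg)

data, specs = q.data.copy(), dict(q.specs)
for col in clin.columns:                        # 19 uniform bins, spline level
    data[col] = bin_clinical(clin[col], n_bins=19)
    specs[col] = ScalingSpec(analysis_level="spline-nominal", degree=2,
                             interior_knots=2, measurement_level="numeric-binned")
data["class"] = truth.class_labels.map({"Cold": 1, "Heat": 2})

ds = CategoricalDataset(data, specs)
ds, _ = merge_sparse_categories(ds, min_count=7)
ds, removed = drop_single_category_variables(ds)
print(f"{len(removed)} constant variables removed; {len(ds.variables)-1} analysed")

result = nlpca_protocol(ds, "class", vaf_threshold=0.20,
                        n_permutations=99, seed=7)
print(result.summary())
```

prints

```
15 constant variables removed; 82 analysed
Optimal-scaling nonlinear PCA
==============================================
subjects: 39   variables: 16
components: 1   iterations: 3   converged: True
total VAF: 0.9922
forced classification on 'class' (weight 1000); classes separated: True
total VAF excluding class variable: 0.4720

variable                       loading       VAF
------------------------------------------------
b29                              1.000     1.000
class                            1.000     1.000
v56                              0.801     0.641
...
selected variables (VAF > threshold): 15
leave-two-out CV error: 0.0%
permutation p-value: 0.0100 (99 permutations)
```

Reading the output: the 15 generated constant items mirror the published
57 → 42 variable reduction; the classes separate completely on the forced
component; 15 variables exceed the VAF > 0.20 selection rule (positive
loadings characterize Heat, negative ones Cold); the cross-validated error
of 0% on this strongly-informative synthetic cohort beats the 50% random
baseline, and no label permutation did better (p = 1/100 at 99
permutations).

The metabolomics side follows the same pattern:

```python
from coldheat import PLSDA
from coldheat.preprocess import filter_presence, replace_zeros, scale_features

table, _ = filter_presence(urine, 0.8)
table = replace_zeros(table)
scaled = scale_features(table, "center")        # urine: mean-centering
model = PLSDA(scaled.study_matrix(), scaled.class_labels())
res = model.fit(seed=7, n_permutations=99)
print(res.summary())
```

A command-line interface wraps both pipelines
(`coldheat simulate | nlpca | plsda | report`); each stage writes CSV tables
and a schema-validated JSON report.

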