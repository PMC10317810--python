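# morphpred

Predicting antimanic medication response in youth with bipolar disorder
from regional brain morphometry.

In a two-arm randomized trial setting (quetiapine vs. lithium, six weeks),
a *responder* is a patient whose Young Mania Rating Scale (YMRS) score
drops by at least 50% from baseline to week 6. This package implements a
two-stage machine-learning pipeline that predicts that outcome from
structural MRI measures available long before week 6:

1. **Features.** Each subject is a 150-dimensional vector: cortical
   thickness (mm) and surface area (mm²) of the 68 Desikan–Killiany
   cortical regions, plus volumes (mm³) of 14 subcortical structures.
   Three feature sets are evaluated: **baseline** (pre-treatment scan),
   **1-week change** (baseline − week 1) and the **longitudinally joint**
   300-dimensional concatenation of baseline and week-1 features.
2. **Two-stage classifier.** Features are binarized per feature (median
   split fitted on training data), compressed by a stacked autoencoder
   (greedy layer-wise sigmoid/cross-entropy pre-training, then supervised
   fine-tuning with a softmax head), and the last-hidden-layer
   representations are classified by an SVM.
3. **Evaluation.** Leakage-safe stratified 10-fold cross-validation
   (binarizer, network and SVM refitted inside every fold), reporting
   balanced accuracy (BAC), sensitivity, specificity and AUC; significance
   by a label-permutation test with the add-one p-value
   `p = (1 + #{null ≥ observed}) / (n_perm + 1)`; cross-drug
   **transferability** (train on one whole arm, test on the other); and
   **feature-contribution** rankings (connection-weight path products
   through the encoder, or permutation importance), reported as top-10
   tables.

No patient data ships with the package. A synthetic cohort generator
(`morphpred.simulate`) draws two-arm trials with the published recruitment
flow, YMRS trajectories that realize a latent responder status exactly,
and arm-specific planted discriminative patterns, so the entire pipeline
is exercised and tested end to end on data with known ground truth.

## Worked example

The numbered scripts under `analysis/` reproduce the study layout on a
synthetic trial with the published flow (149 recruited → 121 analyzed:
71 quetiapine, 50 lithium) and disjoint planted patterns per arm
(temporal/subcortical for quetiapine, frontal/parietal for lithium,
standardized effect size 1.5 at both timepoints):

```bash
python analysis/01_simulate_cohort.py      # writes results/cohort/
python analysis/02_evaluate_models.py      # cross-validated performance
python analysis/03_transferability.py      # cross-drug transfer test
python analysis/04_feature_contributions.py
```

`02_evaluate_models.py` prints the pooled held-out metrics per arm and
feature set, e.g. (seed 0, reduced training schedule):

```
       arm feature_set  balanced_accuracy  ...      auc
quetiapine    baseline           0.802381  ... 0.892063
quetiapine      change           0.971429  ... 1.000000
quetiapine       joint           0.886905  ... 0.931746
   lithium    baseline           0.820000  ... 0.952000
   lithium      change           0.960000  ... 0.998400
   lithium       joint           0.760000  ... 0.848000
```

Planted signals are recovered well above the ~0.5 chance level.
`03_transferability.py` then shows the drug-specificity pattern — the
same models transferred across arms fall to chance (mean cross-drug BAC
44.4% on this draw) because the planted predictors are disjoint — and
`04_feature_contributions.py` recovers 8–9 of the 10 planted features per
arm in the top-10 contribution ranking.

A `morphpred` console command exposes the same steps
(`simulate`, `extract-features`, `evaluate`, `transfer`, `contributions`)
with YAML configs; `morphpred simulate --paper-flow --seed 1` writes a
121-subject cohort.

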