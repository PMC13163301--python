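# distressnet

Regularized partial-correlation network analysis of emotional-distress
symptoms in oncology cohorts: three-track node screening with
train/validation freezing, EBIC graphical-lasso network estimation,
centrality and bootstrap-stability analysis, residual and extended networks,
and a permutation-based network comparison test — all exercised end-to-end
on a synthetic cohort generator with known ground-truth structure.

## Who this is for

Researchers modelling patient-reported mood symptoms (e.g., a 30-item
mood-state inventory scored 0–4 across tension/anxiety, depression, anger,
fatigue, confusion, and vigor dimensions) as a *network*: nodes are
individual symptoms, edges are conditional associations, and questions of
interest include which symptoms are most central, whether demographic or
psychosocial variables attach to the symptom system, and whether the
network's topology differs between subgroups. Because participant-level
mood data are rarely shareable, the package ships a latent-Gaussian-copula
cohort generator so every stage of the analysis can be validated against a
known sparse truth.

## The model

A Gaussian graphical model represents symptoms as a sparse precision matrix
κ. Edge weights are regularized partial correlations

    ω_ij = −κ_ij / sqrt(κ_ii κ_jj),

the association between items *i* and *j* conditional on all other items.
κ is estimated by the graphical lasso (L1-penalized precision estimation)
over a logarithmic grid of 100 penalties; the penalty is selected by the
extended Bayesian information criterion

    EBIC = −2 logL + E log n + 4 E γ log p,

where E is the number of nonzero edges and γ (default 0.50) governs the
preference for sparsity. Node importance uses strength (Σ|ω|) and expected
influence (Σω); stability uses nonparametric bootstrap edge intervals and
case-dropping correlation-stability (CS) coefficients; subgroup topology is
compared by permutation tests of the maximum edge difference (M) and the
global-strength difference (S).

Before estimation, ordinal items pass a three-track screen (run on a
training split only, then frozen): a prevalence filter (>50% positive
responses), a Spearman track (|ρ| ≥ 0.30 with a leave-one-out distress
total and positive rate ≥ 0.50), a cross-validated lasso track, and a
repeated L1-logistic stability-selection track (retained if selected in
≥60% of repetitions), combined with 1/2/2 weighted votes and pruned for
redundancy at Spearman ρ > 0.80.

## Worked example

```python
from distressnet import (CohortConfig, sample_cohort, split_train_validation,
                         ScreeningConfig, screen_nodes, validate_nodes,
                         network_from_data, count_edges, global_strength,
                         centrality_table)
from distressnet.datatypes import ItemResponseMatrix

cohort = sample_cohort(CohortConfig(n=415, seed=1))
split = split_train_validation(cohort.items.values.index, 0.7, seed=4)
train = ItemResponseMatrix(cohort.items.values.loc[list(split.training_ids)],
                           dict(cohort.items.dimension_labels))
result = screen_nodes(train, ScreeningConfig(reps=25, seed=5))
net = network_from_data(cohort.items.values[result.frozen_nodes], gamma=0.5)
print(count_edges(net), round(global_strength(net), 3))
```

With these seeds the screen retains 16 of the 16 high-prevalence candidate
items (`TA2 … CB3`), the frozen-node sum score discriminates
median-dichotomized distress with validation AUC 0.936 (full sample 0.927),
and the estimated network has 16 nodes and 31 nonzero edges out of 120
possible, global strength 2.655, at selected penalty λ = 0.0881. The three
most central nodes by z-standardized strength are FI1 (1.27), DD2 (1.15),
and FI3 (1.12); for nodes whose incident edges are all positive, expected
influence equals strength exactly.

The same workflow is available from the shell:

```bash
distressnet simulate --n 415 --seed 1 --out cohort/
distressnet run-all --out run/ --n-perm 200 --b-boot 200 --b-case 200
```

`run-all` writes the screening report, network matrices and edge lists,
centrality tables, bootstrap and case-dropping summaries, the comparison
table for each psychosocial median split, and a manifest echoing every seed
and threshold.

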