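# sctwiner

Network-guided sparse logistic regression for tumor single-cell
transcriptomics: identify gene signatures that discriminate tumor cell
populations while preferentially retaining genes whose co-expression
network is *shared* between neoplastic populations.

## The problem

Glioblastoma tumors contain multiple neoplastic cell populations —
neoplastic astrocytes in the tumor core, infiltrating neoplastic astrocytes
in the peritumoral tissue, and normal astrocytes around them. Classifying
cells into these populations with a sparse model yields discriminative gene
signatures, but a plain sparsity penalty has no reason to prefer genes that
play the *same network role* in different neoplastic clones — precisely the
genes one would want as targets against multiple clones at once.

`sctwiner` implements the **twiner** (twin networks recovery) approach:
binary sparse logistic regression where each gene's elastic-net penalty is
scaled by how much its correlation network differs between two cell
populations. Writing σⱼ^A, σⱼ^B for gene j's correlation profile (column j
of the gene–gene correlation matrix) in populations A and B, the penalty
weight is the normalized angle between the two profiles:

    wⱼ = arccos( ⟨σⱼ^A, σⱼ^B⟩ / (‖σⱼ^A‖‖σⱼ^B‖) ) / max_k angle_k  ∈ [0, 1]

and the model minimizes

    (1/n) Σᵢ devᵢ(β₀, β)  +  λ { α ‖w∘β‖₁ + (1−α) ‖w∘β‖₂² },   0 < α < 1.

Genes with a preserved correlation pattern across the two neoplastic
populations (small angle) are penalized less and survive selection more
often. Signatures are made robust by stability selection — the model is
refitted on many stratified 75/25 train/test splits and genes selected in
more than 75% of runs form the consensus signature — and validated on bulk
expression survival data with a Cox model, median-risk stratification,
Kaplan–Meier curves and the log-rank test.

The package ships a synthetic-data generator with planted ground truth
(discriminative mean shifts, a co-expression module shared by both
neoplastic populations, a divergent module present in only one), so every
stage can be exercised and tested without access to protected tumor data.

## Worked example

```python
import numpy as np
from sctwiner import (SimulationDesign, simulate_cells, make_labels,
                      subset_population, correlation_matrix, twiner_weights,
                      run_protocol, T_CORE, T_PERIPHERY, N_PERIPHERY)
from sctwiner.containers import align_expression
from sctwiner.glm import WeightedLogit

# three astrocyte populations, 10 planted discriminative genes
design = SimulationDesign(n_core=200, n_periph_neo=200, n_periph_norm=200,
                          p=500, k_discriminative=10, effect_size=1.5,
                          dropout_rate=0.0, seed=0)
expr, ann, truth = simulate_cells(design)

# twiner weights from the two *neoplastic* populations
sigma_core = correlation_matrix(subset_population(expr, ann, T_CORE))
sigma_periph = correlation_matrix(subset_population(expr, ann, T_PERIPHERY))
w = twiner_weights(sigma_core, sigma_periph)

# Model III: neoplastic (core + periphery) vs normal
labels, _ = make_labels(ann, class1=[T_CORE, T_PERIPHERY], class0=[N_PERIPHERY])
em = align_expression(expr, labels)

model = WeightedLogit(em.values, labels.values, gene_ids=list(em.gene_ids),
                      penalty_weights=w)
cv = model.fit_cv(alpha_grid=[0.2, 0.5, 0.8], n_folds=10, n_lambda=30, seed=1)
print(cv.summary())

stability = run_protocol(em.values, labels.values, cv.config,
                         gene_ids=list(em.gene_ids), n_runs=100, seed=2)
print(stability.summary())
recovered = set(truth.discriminative_genes) & set(stability.consensus.gene_ids)
print(f"planted discriminative genes recovered: {len(recovered)}/10")
```

Output:

```
10-fold CV (Brier MSE)
grid: 3 alphas × 30 lambdas
best alpha:  0.8
best lambda: 0.012387
CV MSE:      0.0117109
selected genes at optimum: 20

Stability selection over 100 runs
==============================================
median selected genes: 25
median MSE    train/test: 0.0071 / 0.0127
median AUPRC  train/test: 1.000 / 1.000
median miscl. train/test: 2 / 2
consensus (> 75% of runs): 11 genes

planted discriminative genes recovered: 10/10
```

Reading this: cross-validation picked a fairly L1-heavy penalty (α = 0.8)
at λ ≈ 0.012, giving a Brier-score MSE of ~0.012 — on a 0/1 outcome this
means predicted class probabilities sit close to the true labels. Over 100
stratified 75/25 resampling runs the fitted models used a median of 25
genes, classified the held-out quarter nearly perfectly (median test AUPRC
1.000, 2 misclassifications out of 150 test cells), and 11 genes were
selected in more than 75% of runs — including all 10 genes the simulation
actually planted as class-discriminative.

The same analysis is available from the shell:

```bash
sctwiner simulate --out data/ --seed 0
sctwiner weights --expr data/expression.tsv --annotations data/annotations.tsv --out w.tsv
sctwiner run-model --config config.json --out results/
```

`run-model` chains subsetting → labels → weights → cross-validation →
stability selection → per-population networks → optional survival
validation, and writes a `manifest.json` from which the whole archive can
be reproduced bitwise (`sctwiner run-model --manifest ... --out ...`).

## Layout

| module | contents |
| --- | --- |
| `sctwiner.containers` | expression-matrix / annotation / signature containers and TSV/CSV/MatrixMarket I/O |
| `sctwiner.simulate` | three-population single-cell generator and survival-data generator, with ground truth |
| `sctwiner.weights` | correlation matrices and angle-based twiner penalty weights |
| `sctwiner.glm` | `WeightedLogit` model: weighted elastic-net logistic regression (numba coordinate descent), λ-paths, cross-validation |
| `sctwiner.resampling` | stratified splits, Brier MSE / AUPRC / misclassification metrics, stability selection, Naive Bayes benchmark |
| `sctwiner.network` | thresholded signed co-expression networks and network comparison |
| `sctwiner.survival` | Cox partial likelihood (Breslow ties), risk stratification, Kaplan–Meier, log-rank, signature validation |
| `sctwiner.pipeline`, `sctwiner.cli` | end-to-end orchestration and the `sctwiner` command |

See `docs/methods.md` for the statistical details and design choices.
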