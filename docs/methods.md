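# Methods

## Model

`sctwiner` classifies cells from log-scale expression matrices (cells in
rows, genes in columns; values assumed already normalized and
log-transformed upstream) into two groups built from (cell type, location)
populations. Three standard schemes are provided: Model I (T-core vs
T-periphery neoplastic), Model II (T-periphery neoplastic vs N-periphery
normal) and Model III (all neoplastic vs normal).

The classifier is binary logistic regression with a per-gene weighted
elastic-net penalty. With labels yᵢ ∈ {0,1}, P(Yᵢ=1|xᵢ) =
exp(β₀+xᵢᵀβ)/(1+exp(β₀+xᵢᵀβ)), the fit minimizes

    (1/n) Σᵢ [log(1+exp(ηᵢ)) − yᵢηᵢ]  +  λ { α‖w∘β‖₁ + (1−α)‖w∘β‖₂² }

* The penalty is written as added to a *maximized* log-likelihood in the
  classical presentation; the implementation minimizes the average negative
  log-likelihood plus the penalty, the convention of every elastic-net
  solver in practical use (a literal "maximize ℓ + F" is unbounded).
* An unpenalized intercept β₀ is always included; without it class
  imbalance would bias every coefficient.
* α is restricted to the open interval (0,1): pure LASSO and pure Ridge are
  excluded, both sparsity and grouping are always active.
* The L2 term is ‖w∘β‖₂² without the conventional 1/2 factor — the weight
  enters the L1 term linearly and the L2 term squared. The identity used in
  testing follows: rescaling columns X̃ⱼ = Xⱼ/wⱼ and fitting a *plain*
  elastic net in β̃ = w∘β is exactly the weighted problem.

### Twiner penalty weights

For two populations A and B, gene j's correlation profile σⱼ is column j of
the p×p Pearson (optionally Spearman) correlation matrix over that
population's cells — the self-correlation entry is included, which only
attenuates all angles uniformly. The weight is

    θⱼ = arccos( ⟨σⱼ^A, σⱼ^B⟩ / (‖σⱼ^A‖‖σⱼ^B‖) ),   wⱼ = θⱼ / max_k θ_k.

Weights live in [0,1]; the gene whose network role changes most gets weight
1; genes with preserved profiles approach 0 and are barely penalized.
Weights are always computed from the two *neoplastic* populations (T-core
and T-periphery), never from the normal one, and are applied in the Model
III classification.

Numerical choices:

* the arccos argument is clipped to [−1,1];
* zero-variance (degenerate) genes get correlation 0 with all others, a
  unit diagonal entry, and are flagged; if both profiles reduce to the unit
  self-entry the angle is 0 (minimal penalty);
* if the largest angle is below 1e-6 rad the two networks are numerically
  identical — arccos amplifies cosine round-off of order 1e-16 into angles
  of order 1e-8, so normalizing by such a maximum would turn pure noise
  into a full spread of weights. All weights are then set to 1, which
  reduces the model to the plain elastic net (setting them to 0 would
  nullify the penalty and change the model class).

## Solver

An IRLS outer loop (working weights clipped below at 1e-5) around cyclic
coordinate descent on the penalized weighted least-squares subproblem,
compiled with numba. The coordinate update is a soft-threshold with L1
threshold λαwⱼ and denominator dⱼ + 2λ(1−α)wⱼ². Each IRLS step is
safeguarded by step-halving on the penalized objective, so the objective is
non-increasing over iterations. Convergence: max coefficient change below
1e-7 (default). Features are standardized internally before penalization
(switchable flag) and coefficients returned on the original scale; constant
columns are dropped with a warning. Correctness is established in the test
suite against a generic convex optimizer (split-variable L-BFGS-B) and a
reference elastic-net solver, at 1e-6 / 1e-8 agreement.

λ paths run geometrically from λ_max (the smallest λ with an all-zero
penalized solution, computed from the score at the null model) down to
1e-4·λ_max (n > p) or 1e-2·λ_max (p ≥ n), 100 values by default,
warm-started. (λ, α) are tuned by stratified 10-fold cross-validation of
the Brier-score MSE — the mean of (p̂ᵢ − yᵢ)², the only reading of "MSE"
consistent with a probabilistic binary classifier; ties are broken toward
the larger λ (sparser model). The default α grid is {0.1, …, 0.9}. If the
smaller class cannot populate the requested folds the CV errors out
immediately rather than silently producing single-class folds.

## Stability selection

The tuned configuration is held fixed (a flag enables per-split re-tuning)
and refitted on repeated stratified splits: each class contributes
round(0.75·class size) cells to training, sampled without replacement, run
seeds derived deterministically from one master seed. 1000 runs is the
standard protocol; scaled-down counts are used in tests. Per run the
package records train/test Brier MSE, area under the precision–recall
curve (step rule, ties pooled; an AUROC option exists), misclassification
counts at threshold 0.5 with the ≥ convention, and the selected gene set.
Genes selected in strictly more than 75% of runs form the consensus
signature; each consensus gene carries its selection frequency, a
regulation direction (sign of the class-1 minus class-0 mean difference —
a deliberate simplification of moderated differential-expression testing),
and its mean nonzero coefficient.

The Gaussian Naive Bayes benchmark applies the same split protocol, feeding
NB the genes selected by the penalized fit of that run (default) or one
fixed gene list. Variances are floored at 1e-9 times the largest feature
variance; priors are training frequencies.

## Networks

Over a signature's genes within one population, edges join gene pairs with
|r| > threshold (strict; default 0.2 — the magnitude reading is the only
one consistent with displaying signed edges). Nodes without edges are kept:
signature membership, not connectivity, is the node criterion. Networks are
compared by edge-set Jaccard index and sign agreement on shared edges.
Exports: edge-list TSV and GraphML.

## Survival validation

A multivariable Cox proportional-hazards model is fitted on the signature
genes jointly (the alternative — a risk score from univariate fits — is
deliberately not used). The partial likelihood uses Breslow tie handling;
Newton–Raphson iterates until the gradient norm per event falls below 1e-8
(the gradient is a sum over events, so an absolute norm is meaningless at
large n), with step-halving and a 1e-6 ridge on the Hessian only — the
solution still solves the unpenalized score equations, the ridge merely
stabilizes steps when p approaches n, and it is recorded in the results.
Samples are split at the median fitted linear predictor (ties to "low"),
Kaplan–Meier curves are estimated per group and compared with the
two-group log-rank test (no events ⇒ statistic 0, p = 1). Kaplan–Meier and
log-rank computations are delegated to lifelines behind this module's
interface; the Cox solver is in-package because the tie convention and the
ridge-stabilized Newton contract are pinned here.

## Synthetic data generator

`simulate_cells` emulates the three-population astrocyte design:

| parameter | default | meaning |
| --- | --- | --- |
| n_core / n_periph_neo / n_periph_norm | 300 each | cells per population |
| p | 1000 | genes |
| k_discriminative | 10 | genes mean-shifted between the classes |
| effect_size | 1.5 | shift in log-expression units (≈ units of noise SD) |
| k_shared_module | 20 | module co-expressed identically in both neoplastic populations |
| k_divergent_module | 20 | module co-expressed in T-core only |
| module_correlation | 0.6 | target pairwise correlation within a module |
| dropout_rate | 0.3 | probability of zeroing an entry |
| noise_sd | 1.0 | background noise SD |
| baseline_mean | 4.0 | baseline log-expression level |

Modules follow a one-factor model: gene = baseline + loading·factor +
noise with loading = √(c/(1−c))·noise_sd, which makes the within-module
pairwise correlation exactly c before dropout — an analytically known
target to test against. The shared module loads identically in both
neoplastic populations (zero in normal cells); the divergent module loads
in T-core only. Dropout is independent Bernoulli zeroing after generation
(missing completely at random); values are clipped at 0 so matrices look
like nonnegative log-expression. The returned ground truth lists exactly
the genes the generator touched.

What the generator does *not* emulate: library-size variation, count-level
noise, expression-dependent dropout, realistic marginal distributions or
gene names, cell–cell covariance beyond the planted modules. Passing tests
therefore demonstrate correctness of the machinery and recoverability of
planted structure under clean conditions, not performance on real tumor
data.

A note on dropout and signal strength: the discriminative effect size is
defined on the pre-dropout scale. With the default baseline of 4, 30%
dropout inflates the effective per-gene SD to ≈2 and attenuates the class
shift to ≈0.7·effect, so quantitative recovery checks (planted-gene
consensus, module-correlation and network checks) are run at dropout 0,
where the stated signal-to-noise is a property of the generated data; the
default dropout is kept for realism in qualitative use.

`simulate_survival` draws expression as independent standard normals and
event times from an exponential with rate baseline_hazard·exp(xᵀβ_true);
censoring times are exponential with their rate calibrated by bisection so
the expected censored fraction matches the requested rate.

The null-calibration check of the survival chain uses a single-gene
signature deliberately: with one gene the median split of the fitted risk
is the median split of that gene regardless of the estimated sign or
magnitude, so the log-rank p-value is exactly uniform under the null. With
several genes the fitted risk direction is chosen by the same data and the
post-selection p-value is mildly anti-conservative — a known property of
risk-score stratification, not a defect of the implementation.

## Problem sizes in tests and the acceptance script

The stability protocol in tests and in `scripts/acceptance.py` uses 100
runs on 900 cells × 1000 genes with a 3-point α grid and 30-λ paths;
weight-recovery checks use ten 2000-cell × 500-gene replicates; Cox
recovery uses n = 2000. These sizes were chosen so the full pipeline
rechecks in about a minute while every comparison retains comfortable
statistical margin.

## Known limitations

* Binary outcomes only; no multinomial extension of the weight scheme.
* Penalty weights compare exactly two populations.
* The regulation-direction label is a raw mean difference, not a moderated
  statistic.
* The Cox stage has no penalized variable selection; very large signatures
  relative to sample size rely on the ridge-stabilized Newton steps.
* No count-level preprocessing, HDF5 storage, or graph layout/visualization.
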