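"""Stability selection protocol: repeated stratified splits, accuracy metrics,
consensus gene signatures and the Gaussian Naive Bayes benchmark.

The protocol mirrors the classification study design: the penalty
configuration is tuned once by cross-validation on the full data, the model
is then refitted on many stratified 75/25 train/test partitions, performance
is summarized by median Brier MSE, area under the precision-recall curve and
misclassification counts, and genes selected in more than 75% of the runs
form the consensus signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score
from sklearn.naive_bayes import GaussianNB

from .containers import ExpressionMatrix, GeneSignature, LabelVector
from .glm import PenaltyConfig, WeightedLogit, WeightedLogitResults


# ---------------------------------------------------------------------------
# splits and metrics
# ---------------------------------------------------------------------------


def stratified_split(
    y: np.ndarray, train_fraction: float = 0.75, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-class random train/test partition without replacement.

    Each class contributes round(train_fraction · class size) samples to the
    training set, so both classes are represented in both sets.
    """
    y = np.asarray(y)
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        n_train = int(round(train_fraction * len(idx)))
        if n_train < 1 or n_train >= len(idx):
            raise ValueError(
                f"class {cls} (size {len(idx)}) cannot appear in both train and test"
            )
        perm = rng.permutation(idx)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def mse(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """Brier-score MSE: mean of (p̂ − y)²."""
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, float)
    if len(p) != len(y):
        raise ValueError("probabilities and labels differ in length")
    if len(p) == 0:
        raise ValueError("empty input")
    return float(np.mean((p - y) ** 2))


def auprc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the precision-recall curve (step rule, ties pooled)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to compute AUPRC")
    return float(average_precision_score(y, np.asarray(scores, float)))


def misclassifications(
    probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> int:
    """Count of (p̂ ≥ threshold) disagreeing with y (the ≥ convention)."""
    p = np.asarray(probabilities, float)
    y = np.asarray(labels, int)
    if len(p) != len(y):
        raise ValueError("probabilities and labels differ in length")
    return int(np.sum((p >= threshold).astype(int) != y))


def regulation_direction(
    X: np.ndarray,
    y: np.ndarray,
    genes: list[str],
    gene_ids: list[str],
) -> dict[str, str]:
    """Label genes up/down/unchanged by the sign of the class-1 minus class-0
    mean expression difference."""
    X = np.asarray(X, float)
    y = np.asarray(y)
    pos = {g: j for j, g in enumerate(gene_ids)}
    missing = [g for g in genes if g not in pos]
    if missing:
        raise KeyError(f"genes not in matrix: {missing[:5]}")
    m1 = X[y == 1].mean(axis=0)
    m0 = X[y == 0].mean(axis=0)
    out = {}
    for g in genes:
        d = m1[pos[g]] - m0[pos[g]]
        out[g] = "up" if d > 0 else ("down" if d < 0 else "unchanged")
    return out


# ---------------------------------------------------------------------------
# the resampling protocol
# ---------------------------------------------------------------------------


@dataclass
class StabilityResult:
    """Selection frequencies, per-run metrics and the consensus signature."""

    selection_frequency: pd.Series  # indexed by gene_id
    metrics: pd.DataFrame  # one row per run
    consensus_threshold: float
    consensus: GeneSignature
    median_summary: pd.Series

    def consensus_at(self, threshold: float) -> list[str]:
        """Genes selected in strictly more than ``threshold`` of the runs."""
        freq = self.selection_frequency
        return list(freq.index[freq > threshold])

    def summary(self) -> str:
        med = self.median_summary
        lines = [
            f"Stability selection over {len(self.metrics)} runs",
            "=" * 46,
            f"median selected genes: {med['n_selected']:.0f}",
            f"median MSE    train/test: {med['mse_train']:.4f} / {med['mse_test']:.4f}",
            f"median AUPRC  train/test: {med['auc_train']:.3f} / {med['auc_test']:.3f}",
            f"median miscl. train/test: {med['miscl_train']:.0f} / {med['miscl_test']:.0f}",
            f"consensus (> {self.consensus_threshold:.0%} of runs): "
            f"{len(self.consensus)} genes",
        ]
        return "\n".join(lines)


_METRIC_COLS = [
    "split_id",
    "mse_train",
    "mse_test",
    "auc_train",
    "auc_test",
    "miscl_train",
    "miscl_test",
    "n_selected",
]


def _run_metrics(split_id, p_tr, y_tr, p_te, y_te, n_selected) -> dict:
    return {
        "split_id": split_id,
        "mse_train": mse(p_tr, y_tr),
        "mse_test": mse(p_te, y_te),
        "auc_train": auprc(p_tr, y_tr),
        "auc_test": auprc(p_te, y_te),
        "miscl_train": misclassifications(p_tr, y_tr),
        "miscl_test": misclassifications(p_te, y_te),
        "n_selected": n_selected,
    }


def run_protocol(
    X,
    y,
    config: PenaltyConfig,
    *,
    gene_ids: list[str] | None = None,
    n_runs: int = 1000,
    train_fraction: float = 0.75,
    consensus_threshold: float = 0.75,
    seed: int = 0,
    retune_each_split: bool = False,
    cv_kwargs: dict | None = None,
    standardize: bool = True,
) -> StabilityResult:
    """Repeated stratified-split fitting with selection-frequency aggregation.

    ``config`` (λ, α, optional twiner weights) is held fixed across splits
    unless ``retune_each_split`` re-runs cross-validation inside each
    training set. Run seeds are derived deterministically from ``seed``.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    p = X.shape[1]
    gene_ids = list(gene_ids) if gene_ids is not None else [f"x{j}" for j in range(p)]
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)

    counts = np.zeros(p)
    coef_sums = np.zeros(p)
    rows = []
    warm: WeightedLogitResults | None = None
    for r in range(n_runs):
        tr, te = stratified_split(y, train_fraction, int(run_seeds[r]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = WeightedLogit(
                X[tr],
                y[tr],
                gene_ids=gene_ids,
                penalty_weights=config.weights,
                standardize=standardize,
            )
            if retune_each_split:
                cv = model.fit_cv(seed=int(run_seeds[r]), **(cv_kwargs or {}))
                res = cv.best_fit
            else:
                res = model.fit(config.lam, config.alpha, start=warm)
                warm = res
        nz = res.coefficients != 0
        counts += nz
        coef_sums += np.where(nz, res.coefficients, 0.0)
        p_tr = res.predict_probability(X[tr])
        p_te = res.predict_probability(X[te])
        rows.append(_run_metrics(r, p_tr, y[tr], p_te, y[te], int(nz.sum())))

    metrics = pd.DataFrame(rows, columns=_METRIC_COLS)
    freq = pd.Series(counts / n_runs, index=gene_ids, name="selection_frequency")
    consensus_mask = freq.to_numpy() > consensus_threshold
    cons_genes = [g for g, m in zip(gene_ids, consensus_mask) if m]
    directions = regulation_direction(X, y, cons_genes, gene_ids)
    with np.errstate(invalid="ignore"):
        mean_coef = np.where(counts > 0, coef_sums / np.maximum(counts, 1), 0.0)
    consensus = GeneSignature(
        cons_genes,
        freq.to_numpy()[consensus_mask],
        [directions[g] for g in cons_genes],
        mean_coef[consensus_mask],
    )
    median_summary = metrics.drop(columns="split_id").median()
    return StabilityResult(freq, metrics, consensus_threshold, consensus, median_summary)


# ---------------------------------------------------------------------------
# Gaussian Naive Bayes benchmark
# ---------------------------------------------------------------------------


def gaussian_nb(train_X, train_y, test_X) -> np.ndarray:
    """Class-1 posterior of a Gaussian Naive Bayes classifier.

    Per-feature Gaussian likelihoods with class priors set to the training
    frequencies; variances are floored at 1e-9 times the largest feature
    variance for numerical safety.
    """
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training set must contain both classes")
    clf = GaussianNB()  # var_smoothing default = 1e-9 · max feature variance
    clf.fit(np.asarray(train_X, float), train_y)
    proba = clf.predict_proba(np.asarray(test_X, float))
    return proba[:, list(clf.classes_).index(1)]


def nb_benchmark(
    X,
    y,
    config: PenaltyConfig,
    *,
    gene_ids: list[str] | None = None,
    n_runs: int = 100,
    train_fraction: float = 0.75,
    seed: int = 0,
    fixed_genes: list[str] | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Naive Bayes on the genes selected by the penalized fit, per run.

    By default each run refits the penalized model on its training split and
    hands the selected genes to the NB classifier; ``fixed_genes`` instead
    evaluates NB on one fixed (e.g. consensus) gene list. Returns the per-run
    metrics table (same columns as the stability protocol).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, int)
    p = X.shape[1]
    gene_ids = list(gene_ids) if gene_ids is not None else [f"x{j}" for j in range(p)]
    pos = {g: j for j, g in enumerate(gene_ids)}
    if fixed_genes is not None and not fixed_genes:
        raise ValueError("fixed_genes must be nonempty when given")
    run_seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)

    rows = []
    warm = None
    for r in range(n_runs):
        tr, te = stratified_split(y, train_fraction, int(run_seeds[r]))
        if fixed_genes is not None:
            genes = fixed_genes
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = WeightedLogit(
                    X[tr],
                    y[tr],
                    gene_ids=gene_ids,
                    penalty_weights=config.weights,
                    standardize=standardize,
                )
                res = model.fit(config.lam, config.alpha, start=warm)
                warm = res
            genes = res.selected_genes
        if not genes:
            raise ValueError(f"run {r}: penalized fit selected no genes")
        cols = [pos[g] for g in genes]
        p_tr = gaussian_nb(X[np.ix_(tr, cols)], y[tr], X[np.ix_(tr, cols)])
        p_te = gaussian_nb(X[np.ix_(tr, cols)], y[tr], X[np.ix_(te, cols)])
        rows.append(_run_metrics(r, p_tr, y[tr], p_te, y[te], len(genes)))
    return pd.DataFrame(rows, columns=_METRIC_COLS)
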