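"""Sparse logistic regression with (weighted) elastic-net penalties.

The model minimizes the average logistic deviance plus a penalty acting on
the Hadamard product of per-gene penalty factors w and the coefficients β:

    (1/n) Σ_i dev_i(β0, β)  +  λ { α ‖w∘β‖₁ + (1−α) ‖w∘β‖₂² }

With w ≡ 1 this is the elastic net; with angle-based twiner weights genes
whose correlation profiles agree across two populations are penalized less.
The intercept is never penalized. α is restricted to (0, 1) so that both the
sparsity (L1) and grouping (L2) components are active.

The solver is an IRLS outer loop around a cyclic coordinate-descent inner
solve of the penalized weighted least-squares subproblem (compiled with
numba), with step-halving to keep the penalized objective monotone.
λ paths are fitted warm-started from large to small λ.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit
from sklearn.model_selection import StratifiedKFold

from .containers import ExpressionMatrix, LabelVector
from .weights import TwinerWeights

_WEIGHT_CLIP = 1e-5  # floor on IRLS working weights, glmnet-style


@dataclass
class PenaltyConfig:
    """Elastic-net penalty configuration.

    ``lam`` is the overall strength λ ≥ 0, ``alpha`` the L1/L2 balance in
    (0, 1), ``weights`` optional per-gene factors in [0, 1] (None ⇒ all 1).
    """

    lam: float
    alpha: float
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, float)
            if np.any((self.weights < 0) | (self.weights > 1)):
                raise ValueError("penalty weights must lie in [0, 1]")


@njit(cache=False)
def _wls_cd(X, irls_w, z, pen1, pen2, lam, alpha, beta, b0, tol, max_sweeps):
    """Cyclic coordinate descent on the penalized weighted least squares.

    Minimizes (1/2n) Σ irls_w_i (z_i − b0 − x_iᵀβ)²
              + λ α Σ pen1_j |β_j| + λ(1−α) Σ pen2_j β_j².
    Updates beta in place; returns (b0, sweeps used).
    """
    n, p = X.shape
    d = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += irls_w[i] * X[i, j] * X[i, j]
        d[j] = s / n
    wsum = irls_w.sum()

    r = z.copy()
    for i in range(n):
        r[i] -= b0
    for j in range(p):
        if beta[j] != 0.0:
            bj = beta[j]
            for i in range(n):
                r[i] -= X[i, j] * bj

    l1 = lam * alpha
    l2 = 2.0 * lam * (1.0 - alpha)
    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        delta = 0.0
        # intercept (unpenalized)
        num = 0.0
        for i in range(n):
            num += irls_w[i] * (r[i] + b0)
        b0_new = num / wsum
        db = b0_new - b0
        if db != 0.0:
            for i in range(n):
                r[i] -= db
            b0 = b0_new
            if abs(db) > delta:
                delta = abs(db)
        for j in range(p):
            if d[j] == 0.0:
                continue
            bj = beta[j]
            s = 0.0
            for i in range(n):
                s += irls_w[i] * X[i, j] * r[i]
            s = s / n + d[j] * bj
            thr = l1 * pen1[j]
            if s > thr:
                bnew = (s - thr) / (d[j] + l2 * pen2[j])
            elif s < -thr:
                bnew = (s + thr) / (d[j] + l2 * pen2[j])
            else:
                bnew = 0.0
            if bnew != bj:
                diff = bnew - bj
                for i in range(n):
                    r[i] -= diff * X[i, j]
                beta[j] = bnew
                if abs(diff) > delta:
                    delta = abs(diff)
        if delta < tol:
            break
    return b0, sweeps


def _deviance(y: np.ndarray, eta: np.ndarray) -> float:
    # average logistic deviance, computed overflow-safely:
    # (1/n) Σ [log(1+e^η) − y η]
    return float(np.mean(np.logaddexp(0.0, eta) - y * eta))


def penalized_objective(
    X: np.ndarray,
    y: np.ndarray,
    beta: np.ndarray,
    intercept: float,
    config: PenaltyConfig,
) -> float:
    """Average logistic deviance plus the (weighted) elastic-net penalty."""
    w = config.weights if config.weights is not None else np.ones(X.shape[1])
    eta = intercept + X @ beta
    wb = w * beta
    pen = config.lam * (
        config.alpha * np.abs(wb).sum() + (1 - config.alpha) * np.square(wb).sum()
    )
    return _deviance(y, eta) + pen


@dataclass
class WeightedLogitResults:
    """Fitted coefficients and diagnostics of one penalized logistic fit."""

    model: "WeightedLogit"
    coefficients: np.ndarray  # on the original feature scale
    intercept: float
    config: PenaltyConfig
    n_iter: int
    final_change: float
    objective: float

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.model.gene_ids, name="beta")

    @property
    def selected_genes(self) -> list[str]:
        return [g for g, b in zip(self.model.gene_ids, self.coefficients) if b != 0.0]

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != len(self.coefficients):
            raise ValueError(
                f"expected {len(self.coefficients)} features, got {X.shape[1]}"
            )
        return self.intercept + X @ self.coefficients

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        """P(Y=1|x) = exp(η)/(1+exp(η)), overflow-safe."""
        return expit(self.linear_predictor(X))

    def summary(self) -> str:
        sel = self.params[self.params != 0].sort_values(key=np.abs, ascending=False)
        lines = [
            "Weighted elastic-net logistic regression",
            "=" * 46,
            f"observations:     {self.model.n_obs}",
            f"features:         {self.model.n_features}",
            f"lambda:           {self.config.lam:.6g}",
            f"alpha:            {self.config.alpha:.3g}",
            f"penalty weights:  {'custom' if self.config.weights is not None else 'uniform'}",
            f"selected genes:   {self.n_selected}",
            f"intercept:        {self.intercept:.6g}",
            f"objective:        {self.objective:.6g}",
            f"iterations:       {self.n_iter} (final max |Δβ| {self.final_change:.2e})",
            "-" * 46,
        ]
        for g, b in sel.head(20).items():
            lines.append(f"{g:>20s}  {b:+.5f}")
        if len(sel) > 20:
            lines.append(f"... and {len(sel) - 20} more")
        return "\n".join(lines)


class WeightedLogit:
    """Binary logistic regression with per-gene weighted elastic-net penalty.

    Parameters
    ----------
    X : array (n_cells × n_genes)
        Expression matrix (cells in rows).
    y : array of 0/1
        Class labels; both classes must be present.
    penalty_weights : array in [0,1], optional
        Per-gene penalty factors (e.g. twiner angle weights). None ⇒ plain
        elastic net.
    standardize : bool
        Standardize columns to unit variance internally (coefficients are
        reported on the original scale). Constant columns are dropped with a
        warning, as in the reference elastic-net implementations.
    """

    def __init__(
        self,
        X,
        y,
        *,
        gene_ids: list[str] | None = None,
        penalty_weights=None,
        standardize: bool = True,
    ) -> None:
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in model input")
        classes = np.unique(y)
        if not np.isin(classes, (0.0, 1.0)).all() or len(classes) != 2:
            raise ValueError("y must contain both classes 0 and 1")
        self.X = X
        self.y = y
        self.n_obs, self.n_features = X.shape
        self.gene_ids = (
            list(gene_ids) if gene_ids is not None else [f"x{j}" for j in range(self.n_features)]
        )
        if len(self.gene_ids) != self.n_features:
            raise ValueError("gene_ids length must match number of columns")
        if penalty_weights is None:
            self.penalty_weights = None
        else:
            if isinstance(penalty_weights, TwinerWeights):
                if penalty_weights.gene_ids != self.gene_ids:
                    raise ValueError("penalty weight gene order must match X columns")
                penalty_weights = penalty_weights.weights
            self.penalty_weights = np.asarray(penalty_weights, float)
            if len(self.penalty_weights) != self.n_features:
                raise ValueError("penalty weights length must match number of columns")
        self.standardize = standardize

        self._mean = X.mean(axis=0)
        sd = X.std(axis=0)
        self._constant = sd == 0
        if self._constant.any():
            warnings.warn(
                f"dropping {int(self._constant.sum())} constant column(s) from the fit",
                stacklevel=2,
            )
        self._sd = np.where(self._constant, 1.0, sd)
        if standardize:
            Xw = (X - self._mean) / self._sd
        else:
            Xw = X.copy()
        Xw[:, self._constant] = 0.0
        self._Xw = np.asfortranarray(Xw)

    @classmethod
    def from_expression(
        cls,
        expr: ExpressionMatrix,
        labels: LabelVector,
        *,
        penalty_weights=None,
        standardize: bool = True,
    ) -> "WeightedLogit":
        from .containers import align_expression

        expr = align_expression(expr, labels)
        return cls(
            expr.values,
            labels.values,
            gene_ids=list(expr.gene_ids),
            penalty_weights=penalty_weights,
            standardize=standardize,
        )

    # -- internals ---------------------------------------------------------

    def _pens(self) -> tuple[np.ndarray, np.ndarray]:
        w = (
            self.penalty_weights
            if self.penalty_weights is not None
            else np.ones(self.n_features)
        )
        return w, w * w

    def lambda_max(self, alpha: float) -> float:
        """Smallest λ for which every penalized coefficient is zero."""
        ybar = self.y.mean()
        grad = np.abs(self._Xw.T @ (self.y - ybar)) / self.n_obs
        pen1, _ = self._pens()
        active = (pen1 > 0) & ~self._constant
        if not active.any():
            raise ValueError("no penalized, non-constant feature")
        return float((grad[active] / (alpha * pen1[active])).max())

    def lambda_path(self, alpha: float, n_lambda: int = 100) -> np.ndarray:
        """Geometric λ path from λ_max down, glmnet-style."""
        lmax = self.lambda_max(alpha)
        eps = 1e-4 if self.n_obs > self.n_features else 1e-2
        return np.geomspace(lmax, lmax * eps, n_lambda)

    def _fit_std(
        self,
        lam: float,
        alpha: float,
        beta0: np.ndarray | None,
        b00: float | None,
        tol: float,
        max_outer: int,
        max_sweeps: int,
    ) -> tuple[np.ndarray, float, int, float]:
        """Solve on the working (standardized) scale; returns β_std, b0, iters, change."""
        X, y, n = self._Xw, self.y, self.n_obs
        pen1, pen2 = self._pens()
        cfg_w = pen1
        beta = np.zeros(self.n_features) if beta0 is None else beta0.copy()
        b0 = float(np.log(y.mean() / (1 - y.mean()))) if b00 is None else b00

        def obj(beta, b0):
            eta = b0 + X @ beta
            wb = cfg_w * beta
            return _deviance(y, eta) + lam * (
                alpha * np.abs(wb).sum() + (1 - alpha) * np.square(wb).sum()
            )

        cur = obj(beta, b0)
        change = np.inf
        it = 0
        for it in range(1, max_outer + 1):
            eta = b0 + X @ beta
            p_hat = expit(eta)
            irls_w = np.clip(p_hat * (1 - p_hat), _WEIGHT_CLIP, None)
            z = eta + (y - p_hat) / irls_w
            beta_old, b0_old = beta.copy(), b0
            beta_new = beta.copy()
            b0_new, _ = _wls_cd(
                X, irls_w, z, pen1, pen2, lam, alpha, beta_new, b0, tol * 0.1, max_sweeps
            )
            # step-halving keeps the penalized objective monotone
            step = 1.0
            for _ in range(30):
                beta_try = beta_old + step * (beta_new - beta_old)
                b0_try = b0_old + step * (b0_new - b0_old)
                new = obj(beta_try, b0_try)
                if new <= cur + 1e-12:
                    break
                step *= 0.5
            beta, b0 = beta_try, b0_try
            cur = new
            change = max(np.abs(beta - beta_old).max(initial=0.0), abs(b0 - b0_old))
            if change < tol:
                break
        return beta, b0, it, change

    # -- public fitting API ------------------------------------------------

    def fit(
        self,
        lam: float,
        alpha: float,
        *,
        start: WeightedLogitResults | None = None,
        tol: float = 1e-7,
        max_outer: int = 200,
        max_sweeps: int = 10_000,
    ) -> WeightedLogitResults:
        """Fit at one (λ, α); optionally warm-started from a previous fit."""
        config = PenaltyConfig(lam, alpha, self.penalty_weights)
        beta0 = b00 = None
        if start is not None:
            if self.standardize:
                beta0 = start.coefficients * self._sd
                b00 = start.intercept + float(self._mean @ start.coefficients)
            else:
                beta0 = start.coefficients.copy()
                b00 = start.intercept
        beta_std, b0, it, change = self._fit_std(
            lam, alpha, beta0, b00, tol, max_outer, max_sweeps
        )
        if self.standardize:
            beta = beta_std / self._sd
            intercept = b0 - float(self._mean @ beta)
        else:
            beta, intercept = beta_std, b0
        beta[self._constant] = 0.0
        objective = penalized_objective(
            self._Xw, self.y, beta_std, b0, PenaltyConfig(lam, alpha, self.penalty_weights)
        )
        return WeightedLogitResults(self, beta, intercept, config, it, change, objective)

    def fit_path(
        self,
        alpha: float,
        lambdas: np.ndarray | None = None,
        n_lambda: int = 100,
        tol: float = 1e-7,
    ) -> list[WeightedLogitResults]:
        """Warm-started fits along a decreasing λ path."""
        if lambdas is None:
            lambdas = self.lambda_path(alpha, n_lambda)
        lambdas = np.asarray(lambdas, float)
        if np.any(np.diff(lambdas) > 0):
            raise ValueError("lambda path must be non-increasing")
        out: list[WeightedLogitResults] = []
        prev = None
        for lam in lambdas:
            prev = self.fit(lam, alpha, start=prev, tol=tol)
            out.append(prev)
        return out

    def fit_cv(
        self,
        alpha_grid=None,
        n_folds: int = 10,
        n_lambda: int = 100,
        seed: int = 0,
        tol: float = 1e-6,
    ) -> "CVResults":
        """Choose (λ, α) by stratified K-fold CV of the Brier-score MSE.

        For each α a λ path is laid out on the full data from λ_max downward;
        every fold refits the whole path warm-started. The configuration with
        the smallest mean CV MSE wins; ties go to the sparser (larger λ) one.
        """
        return cross_validate(
            self, alpha_grid=alpha_grid, n_folds=n_folds, n_lambda=n_lambda,
            seed=seed, tol=tol,
        )


@dataclass
class CVResults:
    """Cross-validation surface and the selected penalty configuration."""

    model: WeightedLogit
    config: PenaltyConfig
    cv_table: pd.DataFrame  # columns: alpha, lam, mse_mean, mse_se
    best_fit: WeightedLogitResults

    def summary(self) -> str:
        return (
            "10-fold CV (Brier MSE)\n"
            f"grid: {self.cv_table.alpha.nunique()} alphas × "
            f"{self.cv_table.groupby('alpha').size().iloc[0]} lambdas\n"
            f"best alpha:  {self.config.alpha:.3g}\n"
            f"best lambda: {self.config.lam:.6g}\n"
            f"CV MSE:      {self.cv_table.mse_mean.min():.6g}\n"
            f"selected genes at optimum: {self.best_fit.n_selected}"
        )


def cross_validate(
    model: WeightedLogit,
    alpha_grid=None,
    n_folds: int = 10,
    n_lambda: int = 100,
    seed: int = 0,
    tol: float = 1e-6,
) -> CVResults:
    """Stratified K-fold cross-validation over an (α, λ) grid."""
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.1, 1.0, 0.1), 10)
    alpha_grid = list(alpha_grid)
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    y = model.y
    n1, n0 = int(y.sum()), int(len(y) - y.sum())
    if min(n1, n0) < n_folds:
        raise ValueError(
            f"smallest class ({min(n1, n0)}) cannot populate {n_folds} stratified folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(model.X, y))

    rows = []
    for alpha in alpha_grid:
        lambdas = model.lambda_path(alpha, n_lambda)
        fold_mse = np.empty((n_folds, len(lambdas)))
        for k, (tr, te) in enumerate(folds):
            sub = WeightedLogit(
                model.X[tr],
                y[tr],
                gene_ids=model.gene_ids,
                penalty_weights=model.penalty_weights,
                standardize=model.standardize,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits = sub.fit_path(alpha, lambdas=lambdas, tol=tol)
            for m, res in enumerate(fits):
                p_hat = res.predict_probability(model.X[te])
                fold_mse[k, m] = float(np.mean((p_hat - y[te]) ** 2))
        for m, lam in enumerate(lambdas):
            rows.append(
                {
                    "alpha": alpha,
                    "lam": float(lam),
                    "mse_mean": float(fold_mse[:, m].mean()),
                    "mse_se": float(fold_mse[:, m].std(ddof=1) / np.sqrt(n_folds)),
                }
            )
    table = pd.DataFrame(rows)
    # argmin with sparser-model (larger lambda) tie-break
    best = table.sort_values(["mse_mean", "lam"], ascending=[True, False]).iloc[0]
    best_fit = model.fit(float(best.lam), float(best.alpha))
    config = PenaltyConfig(float(best.lam), float(best.alpha), model.penalty_weights)
    return CVResults(model, config, table, best_fit)


def predict_probability(x: np.ndarray, fit: WeightedLogitResults) -> np.ndarray:
    """Functional alias for :meth:`WeightedLogitResults.predict_probability`."""
    return fit.predict_probability(x)
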