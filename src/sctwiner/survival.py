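"""Survival validation of a gene signature on bulk expression data.

A multivariable Cox proportional-hazards model is fitted on the signature
genes (partial likelihood, Breslow tie handling, Newton iterations with a
small ridge stabilizer on the Hessian). Samples are split into high- and
low-risk groups at the median of the fitted relative risk, Kaplan-Meier
curves are estimated per group, and the separation is tested with the
two-group log-rank test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .containers import GeneSignature


# ---------------------------------------------------------------------------
# Cox proportional hazards (Breslow ties, Newton-Raphson)
# ---------------------------------------------------------------------------


def _breslow_loglik_grad_hess(
    x: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood, gradient and Hessian."""
    n, p = x.shape
    order = np.argsort(-time, kind="stable")  # decreasing time
    xs, ts, es = x[order], time[order], event[order]
    eta = xs @ beta
    w = np.exp(eta)

    loglik = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    s0 = 0.0
    s1 = np.zeros(p)
    s2 = np.zeros((p, p))
    i = 0
    while i < n:
        t = ts[i]
        j = i
        while j < n and ts[j] == t:  # everyone tied at this time enters risk set
            s0 += w[j]
            s1 += w[j] * xs[j]
            s2 += w[j] * np.outer(xs[j], xs[j])
            j += 1
        d_idx = [k for k in range(i, j) if es[k] == 1]
        d = len(d_idx)
        if d:
            xbar = s1 / s0
            loglik += float(eta[d_idx].sum() - d * np.log(s0))
            grad += xs[d_idx].sum(axis=0) - d * xbar
            hess -= d * (s2 / s0 - np.outer(xbar, xbar))
        i = j
    return loglik, grad, hess


@dataclass
class CoxPHResults:
    """Estimates and diagnostics of one Cox partial-likelihood fit."""

    model: "CoxPH"
    coefficients: np.ndarray
    loglik: float
    n_iter: int
    grad_norm: float
    ridge: float

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.coefficients, index=self.model.gene_ids, name="coef")

    def standard_errors(self) -> pd.Series:
        _, _, hess = _breslow_loglik_grad_hess(
            self.model.X, self.model.time, self.model.event, self.coefficients
        )
        cov = np.linalg.inv(-hess + self.ridge * np.eye(len(self.coefficients)))
        return pd.Series(np.sqrt(np.diag(cov)), index=self.model.gene_ids, name="se")

    def linear_predictor(self, X: np.ndarray | None = None) -> np.ndarray:
        X = self.model.X if X is None else np.asarray(X, float)
        return X @ self.coefficients

    def summary(self) -> str:
        se = self.standard_errors()
        lines = [
            "Cox proportional hazards (Breslow ties)",
            "=" * 46,
            f"samples: {len(self.model.time)}  events: {int(self.model.event.sum())}",
            f"partial log-likelihood: {self.loglik:.4f}",
            f"Newton iterations: {self.n_iter} (|grad| {self.grad_norm:.2e}, "
            f"Hessian ridge {self.ridge:g})",
            "-" * 46,
            f"{'gene':>20s}  {'coef':>9s}  {'HR':>8s}  {'se':>8s}",
        ]
        for g, b in self.params.items():
            lines.append(f"{g:>20s}  {b:+9.4f}  {np.exp(b):8.4f}  {se[g]:8.4f}")
        return "\n".join(lines)


class CoxPH:
    """Multivariable Cox proportional-hazards model for a gene signature."""

    def __init__(self, X, time, event, *, gene_ids: list[str] | None = None) -> None:
        self.X = np.atleast_2d(np.asarray(X, float))
        if self.X.shape[0] == 1 and len(np.asarray(time)) != 1:
            self.X = self.X.T
        self.time = np.asarray(time, float)
        self.event = np.asarray(event, int)
        if np.any(self.time <= 0):
            raise ValueError("all times must be positive")
        if self.event.sum() < 1:
            raise ValueError("need at least one observed event")
        p = self.X.shape[1]
        self.gene_ids = list(gene_ids) if gene_ids is not None else [f"x{j}" for j in range(p)]
        sd = self.X.std(axis=0)
        const = np.flatnonzero(sd == 0)
        if len(const):
            raise ValueError(
                f"constant covariate(s): {[self.gene_ids[j] for j in const]}"
            )

    def fit(
        self, *, ridge: float = 1e-6, tol: float = 1e-8, max_iter: int = 100
    ) -> CoxPHResults:
        """Newton-Raphson to per-event gradient norm < tol; ridge stabilizes
        the Hessian (the solution still solves the unpenalized score
        equations). The gradient is a sum over events, so the convergence
        norm is scaled by the event count to stay meaningful at large n.
        """
        p = self.X.shape[1]
        scale = max(1.0, float(self.event.sum()))
        beta = np.zeros(p)
        loglik, grad, hess = _breslow_loglik_grad_hess(
            self.X, self.time, self.event, beta
        )
        it = 0
        for it in range(1, max_iter + 1):
            if np.linalg.norm(grad) / scale < tol:
                break
            step = np.linalg.solve(-(hess) + ridge * np.eye(p), grad)
            # step-halving safeguards against overshoot
            damp = 1.0
            for _ in range(40):
                cand = beta + damp * step
                ll_new, g_new, h_new = _breslow_loglik_grad_hess(
                    self.X, self.time, self.event, cand
                )
                if np.isfinite(ll_new) and ll_new >= loglik - 1e-12:
                    break
                damp *= 0.5
            beta, loglik, grad, hess = cand, ll_new, g_new, h_new
        gnorm = float(np.linalg.norm(grad)) / scale
        if gnorm >= max(tol, 1e-6):
            raise RuntimeError(
                f"Cox Newton did not converge in {it} iterations "
                f"(gradient norm {gnorm:.3e})"
            )
        return CoxPHResults(self, beta, loglik, it, gnorm, ridge)


def cox_fit(expr, time, event, *, gene_ids=None, ridge: float = 1e-6) -> CoxPHResults:
    """Functional wrapper: fit a Cox model on a samples × genes matrix."""
    return CoxPH(expr, time, event, gene_ids=gene_ids).fit(ridge=ridge)


# ---------------------------------------------------------------------------
# risk stratification, Kaplan-Meier, log-rank
# ---------------------------------------------------------------------------


@dataclass
class RiskStratification:
    """Median split of the fitted relative risk into high/low groups."""

    linear_predictor: np.ndarray
    risk_group: np.ndarray  # "high" / "low"
    cut_value: float


def stratify(expr: np.ndarray, coefficients: np.ndarray) -> RiskStratification:
    """Split samples at the median linear predictor; ties go to 'low'."""
    lp = np.asarray(expr, float) @ np.asarray(coefficients, float)
    cut = float(np.median(lp))
    group = np.where(lp > cut, "high", "low")
    return RiskStratification(lp, group, cut)


@dataclass
class KaplanMeierCurve:
    """Product-limit survival estimate with risk-set bookkeeping."""

    event_times: np.ndarray  # distinct observed times, increasing
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray
    events: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


def kaplan_meier(time, event) -> KaplanMeierCurve:
    """Kaplan-Meier product-limit estimate Ŝ(t) = Π (1 − d_i/n_i)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if len(time) == 0:
        raise ValueError("empty input")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    table = kmf.event_table.iloc[1:] if 0.0 not in time else kmf.event_table
    # drop the t=0 bookkeeping row lifelines adds when no observation is at 0
    times = table.index.to_numpy(float)
    surv = kmf.survival_function_.loc[times, "KM_estimate"].to_numpy(float)
    return KaplanMeierCurve(
        times,
        surv,
        table["at_risk"].to_numpy(int),
        table["observed"].to_numpy(int),
    )


def logrank_test(time, event, group) -> tuple[float, float]:
    """Two-group log-rank test: chi-square statistic U²/V and its p-value.

    With no events in either group (V = 0) the statistic is 0 and p = 1.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    labels = np.unique(group)
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {list(labels)}")
    m0, m1 = group == labels[0], group == labels[1]
    if event.sum() == 0:
        return 0.0, 1.0
    res = _ll_logrank(time[m0], time[m1], event[m0], event[m1])
    stat = float(res.test_statistic)
    p = float(res.p_value)
    if not np.isfinite(stat):  # degenerate risk sets
        return 0.0, 1.0
    return stat, p


@dataclass
class SignatureValidationReport:
    """End-to-end survival validation of one gene signature."""

    gene_ids: list[str]
    coefficients: pd.Series
    stratification: RiskStratification
    km_high: KaplanMeierCurve
    km_low: KaplanMeierCurve
    logrank_statistic: float
    logrank_p: float
    cox_ridge: float

    def to_json(self, path: str | Path) -> None:
        payload = {
            "genes": self.gene_ids,
            "coefficients": {g: float(b) for g, b in self.coefficients.items()},
            "risk_cut_value": float(self.stratification.cut_value),
            "n_high": int((self.stratification.risk_group == "high").sum()),
            "n_low": int((self.stratification.risk_group == "low").sum()),
            "logrank_statistic": float(self.logrank_statistic),
            "logrank_p": float(self.logrank_p),
            "cox_hessian_ridge": float(self.cox_ridge),
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    def summary(self) -> str:
        n_high = int((self.stratification.risk_group == "high").sum())
        n_low = int((self.stratification.risk_group == "low").sum())
        return (
            f"Signature survival validation ({len(self.gene_ids)} genes)\n"
            f"high-risk n={n_high}, low-risk n={n_low} "
            f"(cut at median relative risk)\n"
            f"log-rank chi2 = {self.logrank_statistic:.4f}, "
            f"p = {self.logrank_p:.3g}"
        )


def validate_signature(
    expr: np.ndarray,
    time,
    event,
    signature: GeneSignature | list[str],
    *,
    gene_ids: list[str] | None = None,
    ridge: float = 1e-6,
) -> SignatureValidationReport:
    """Cox fit → median-risk stratification → per-group KM → log-rank."""
    sig_genes = (
        signature.gene_ids if isinstance(signature, GeneSignature) else list(signature)
    )
    expr = np.asarray(expr, float)
    if gene_ids is not None:
        pos = {g: j for j, g in enumerate(gene_ids)}
        missing = [g for g in sig_genes if g not in pos]
        if missing:
            raise KeyError(f"signature genes absent from expression: {missing[:5]}")
        x = expr[:, [pos[g] for g in sig_genes]]
    else:
        x = expr
        if x.shape[1] != len(sig_genes):
            raise ValueError("expression columns must match signature genes")
    res = CoxPH(x, time, event, gene_ids=sig_genes).fit(ridge=ridge)
    strat = stratify(x, res.coefficients)
    hi = strat.risk_group == "high"
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    km_h = kaplan_meier(time[hi], event[hi])
    km_l = kaplan_meier(time[~hi], event[~hi])
    stat, p = logrank_test(time, event, strat.risk_group)
    return SignatureValidationReport(
        sig_genes, res.params, strat, km_h, km_l, stat, p, ridge
    )
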