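"""Independent brute-force reference implementations used only by the tests.

Each function here is deliberately written in the most literal way possible
(loops, definitions applied term by term) so it can serve as an oracle for
the vectorized / library-backed implementations in the package.
"""

import math

import numpy as np


def pearson_brute(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation straight from the covariance/stddev definition."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = math.sqrt(sum((a - mx) ** 2 for a in x) / n)
    sy = math.sqrt(sum((b - my) ** 2 for b in y) / n)
    return cov / (sx * sy)


def correlation_matrix_brute(values: np.ndarray) -> np.ndarray:
    """Entry-by-entry Pearson correlation matrix (cells × genes input)."""
    p = values.shape[1]
    out = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            out[i, j] = out[j, i] = pearson_brute(values[:, i], values[:, j])
    return out


def angles_brute(sigma_a: np.ndarray, sigma_b: np.ndarray) -> np.ndarray:
    """arccos of the cosine between corresponding columns."""
    p = sigma_a.shape[1]
    ang = np.empty(p)
    for j in range(p):
        a, b = sigma_a[:, j], sigma_b[:, j]
        cos = float(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
        ang[j] = math.acos(min(1.0, max(-1.0, cos)))
    return ang


def auprc_brute(scores: np.ndarray, labels: np.ndarray) -> float:
    """Step-rule area under the PR curve by explicit threshold enumeration.

    Thresholds are the distinct score values in decreasing order; ties are
    processed as one threshold. AUPRC = Σ (R_k − R_{k−1}) · P_k.
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = int(labels.sum())
    area = 0.0
    r_prev = 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int(((labels == 1) & pred).sum())
        fp = int(((labels == 0) & pred).sum())
        precision = tp / (tp + fp)
        recall = tp / n_pos
        area += (recall - r_prev) * precision
        r_prev = recall
    return area


def gaussian_nb_brute(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray
) -> np.ndarray:
    """Closed-form Gaussian Naive Bayes posterior for class 1.

    Matches the package convention: per-class means, biased (ML) variances
    floored by 1e-9 times the largest overall feature variance, priors =
    training class frequencies.
    """
    train_x = np.atleast_2d(np.asarray(train_x, float))
    test_x = np.atleast_2d(np.asarray(test_x, float))
    eps = 1e-9 * float(np.var(train_x, axis=0).max())
    out = []
    classes = [0, 1]
    priors = {c: float(np.mean(train_y == c)) for c in classes}
    stats = {}
    for c in classes:
        xc = train_x[np.asarray(train_y) == c]
        stats[c] = (xc.mean(axis=0), xc.var(axis=0) + eps)
    for row in test_x:
        like = {}
        for c in classes:
            mu, var = stats[c]
            logp = math.log(priors[c])
            for v, m, s2 in zip(row, mu, var):
                logp += -0.5 * math.log(2 * math.pi * s2) - (v - m) ** 2 / (2 * s2)
            like[c] = logp
        m = max(like.values())
        z = sum(math.exp(v - m) for v in like.values())
        out.append(math.exp(like[1] - m) / z)
    return np.array(out)


def km_brute(time: np.ndarray, event: np.ndarray):
    """Product-limit estimate by direct multiplication over event times."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    times = sorted(set(time))
    surv = {}
    s = 1.0
    for t in times:
        n_at_risk = int((time >= t).sum())
        d = int(((time == t) & (event == 1)).sum())
        if d:
            s *= 1.0 - d / n_at_risk
        surv[t] = s
    return surv


def logrank_brute(time, event, group) -> tuple[float, float]:
    """Two-group log-rank statistic from the hypergeometric moments."""
    import scipy.stats

    time = np.asarray(time, float)
    event = np.asarray(event, int)
    group = np.asarray(group)
    labels = sorted(set(group))
    u = 0.0
    v = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & (group == labels[1])).sum())
        d = int(((time == t) & (event == 1)).sum())
        d1 = int(((time == t) & (event == 1) & (group == labels[1])).sum())
        u += d1 - d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if v == 0:
        return 0.0, 1.0
    stat = u * u / v
    return stat, float(scipy.stats.chi2.sf(stat, 1))


def cox_loglik_breslow(x, time, event, beta) -> float:
    """Breslow partial log-likelihood computed by literal summation."""
    x = np.atleast_2d(np.asarray(x, float))
    if x.shape[0] != len(time):
        x = x.T
    beta = np.atleast_1d(np.asarray(beta, float))
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        risk = np.flatnonzero(time >= t)
        deaths = np.flatnonzero((time == t) & (event == 1))
        denom = sum(math.exp(float(x[i] @ beta)) for i in risk)
        for i in deaths:
            ll += float(x[i] @ beta) - math.log(denom)
    return ll


def penalized_logistic_oracle(X, y, weights, lam, alpha):
    """Generic convex-optimizer solution of the penalized deviance.

    Splits β = β⁺ − β⁻ so the L1 term is smooth on the positive orthant and
    minimizes with L-BFGS-B; returns (intercept, beta, objective).
    """
    from scipy.optimize import minimize

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape
    w = np.ones(p) if weights is None else np.asarray(weights, float)

    def obj(z):
        b0, bp, bm = z[0], z[1 : 1 + p], z[1 + p :]
        b = bp - bm
        eta = b0 + X @ b
        dev = np.mean(np.logaddexp(0.0, eta) - y * eta)
        pen = lam * (alpha * np.sum(w * (bp + bm)) + (1 - alpha) * np.sum((w * b) ** 2))
        return dev + pen

    res = minimize(
        obj,
        np.zeros(1 + 2 * p),
        method="L-BFGS-B",
        bounds=[(None, None)] + [(0.0, None)] * (2 * p),
        options={"maxiter": 200000, "maxfun": 200000, "ftol": 1e-18, "gtol": 1e-12},
    )
    b = res.x[1 : 1 + p] - res.x[1 + p :]
    return res.x[0], b, float(res.fun)
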