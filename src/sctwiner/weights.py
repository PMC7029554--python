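"""Angle-based penalty weights from two population correlation networks.

For each gene j, its correlation profile σ_j (column j of the gene-gene
correlation matrix, self-correlation included) is computed separately in two
cell populations A and B. The penalty weight is the angle between σ_j^A and
σ_j^B, normalized by the largest angle over all genes:

    w_j = arccos( ⟨σ_j^A, σ_j^B⟩ / (‖σ_j^A‖ ‖σ_j^B‖) ) / max_k angle_k

Genes whose correlation pattern is preserved across the two populations get a
small weight and hence a small elastic-net penalty, so shared-network genes
are preferentially retained by the classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .containers import ExpressionMatrix


@dataclass
class ClassCorrelationMatrix:
    """Gene-gene correlation matrix of one cell population."""

    matrix: np.ndarray
    gene_ids: list[str]
    population_label: str = ""
    degenerate: np.ndarray | None = None  # zero-variance genes

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        p = len(self.gene_ids)
        if self.matrix.shape != (p, p):
            raise ValueError("correlation matrix shape must match gene_ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if self.degenerate is None:
            self.degenerate = np.zeros(p, dtype=bool)


@dataclass
class TwinerWeights:
    """Per-gene penalty factors in [0, 1] and the underlying angles."""

    weights: np.ndarray
    angles: np.ndarray
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, float)
        self.angles = np.asarray(self.angles, float)
        if np.any((self.weights < 0) | (self.weights > 1)):
            raise ValueError("weights must lie in [0, 1]")


def correlation_matrix(
    expr: ExpressionMatrix, method: str = "pearson", population_label: str = ""
) -> ClassCorrelationMatrix:
    """Pairwise gene correlations over the cells of one population.

    Zero-variance genes get correlation 0 with every other gene, a unit
    diagonal entry, and are flagged as degenerate.
    """
    if expr.n_cells < 2:
        raise ValueError("need at least 2 cells to compute correlations")
    x = expr.values
    if method == "spearman":
        x = scipy.stats.rankdata(x, axis=0)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")
    sd = x.std(axis=0)
    degenerate = sd == 0
    xc = x - x.mean(axis=0)
    safe_sd = np.where(degenerate, 1.0, sd)
    xs = xc / safe_sd
    corr = (xs.T @ xs) / x.shape[0]
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    np.clip(corr, -1.0, 1.0, out=corr)
    return ClassCorrelationMatrix(corr, list(expr.gene_ids), population_label, degenerate)


def twiner_weights(
    sigma_a: ClassCorrelationMatrix, sigma_b: ClassCorrelationMatrix
) -> TwinerWeights:
    """Angle-based weights from two correlation matrices over the same genes."""
    if sigma_a.gene_ids != sigma_b.gene_ids:
        raise ValueError("correlation matrices must share identical gene_ids order")
    a, b = sigma_a.matrix, sigma_b.matrix
    norm_a = np.linalg.norm(a, axis=0)
    norm_b = np.linalg.norm(b, axis=0)
    if np.any(norm_a == 0) or np.any(norm_b == 0):
        raise ValueError("zero-norm correlation profile")
    cos = np.einsum("ij,ij->j", a, b) / (norm_a * norm_b)
    angles = np.arccos(np.clip(cos, -1.0, 1.0))
    # arccos amplifies cosine round-off near 1 into angles of order 1e-8;
    # a maximal angle below 1e-6 rad is indistinguishable from identical
    # networks, where uniform weights keep the plain elastic net.
    max_angle = angles.max()
    if max_angle > 1e-6:
        w = angles / max_angle
    else:
        w = np.ones_like(angles)
    return TwinerWeights(np.clip(w, 0.0, 1.0), angles, list(sigma_a.gene_ids))


def weight_report(
    w: TwinerWeights, top_k: int
) -> list[tuple[str, float, float]]:
    """The ``top_k`` least-penalized genes as (gene_id, weight, angle) rows.

    Ascending by weight; ties broken by gene id.
    """
    p = len(w.gene_ids)
    if not 1 <= top_k <= p:
        raise ValueError(f"top_k must be in [1, {p}]")
    order = sorted(range(p), key=lambda j: (w.weights[j], w.gene_ids[j]))
    return [
        (w.gene_ids[j], float(w.weights[j]), float(w.angles[j]))
        for j in order[:top_k]
    ]


def write_weights(w: TwinerWeights, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {"gene_id": w.gene_ids, "angle_radians": w.angles, "weight": w.weights}
    ).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_weights(path) -> TwinerWeights:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return TwinerWeights(
        df["weight"].to_numpy(), df["angle_radians"].to_numpy(), list(df["gene_id"])
    )
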