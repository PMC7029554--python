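"""Synthetic single-cell expression and survival data with known ground truth.

The cell generator emulates the three astrocyte populations of a glioblastoma
single-cell study design: neoplastic cells from the tumor core (T-core),
infiltrating neoplastic cells from the tumor periphery (T-periphery), and
normal astrocytes from the periphery (N-periphery). It plants

* ``k_discriminative`` genes whose mean is shifted by ``effect_size`` in the
  neoplastic cells (class-discriminative signal),
* a *shared* co-expression module driven by one latent factor with identical
  loadings in both neoplastic populations and zero loading in normal cells,
* a *divergent* module co-expressed in the T-core population only,

on top of independent Gaussian background noise, followed by independent
Bernoulli dropout (zeroing) and clipping at zero so values look like
log-scale single-cell expression. For a target within-module pairwise
correlation c the factor loading is sqrt(c/(1-c))·noise_sd, which gives the
module genes correlation exactly c before dropout/clipping.

The survival generator draws exponential event times whose rate is
baseline_hazard·exp(xᵀβ) with independent standard-normal expression, and
calibrates an independent exponential censoring time so the expected censored
fraction matches ``censoring_rate``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .containers import (
    CellAnnotation,
    ExpressionMatrix,
    N_PERIPHERY,
    Population,
    T_CORE,
    T_PERIPHERY,
    write_annotations,
    write_expression,
)

#: which populations carry the discriminative mean shift
_CONTRASTS = ("neoplastic_vs_normal", "core_vs_periphery")


@dataclass
class SimulationDesign:
    """Parameters of the three-population cell simulation.

    Defaults are the package's standard study conditions: 300 cells per
    population, 1000 genes, 10 discriminative genes shifted by 1.5 noise SD,
    20-gene shared and divergent modules at pairwise correlation 0.6, and a
    30% dropout rate typical of the sparsity of single-cell data.
    """

    n_core: int = 300
    n_periph_neo: int = 300
    n_periph_norm: int = 300
    p: int = 1000
    k_discriminative: int = 10
    effect_size: float = 1.5
    k_shared_module: int = 20
    k_divergent_module: int = 20
    module_correlation: float = 0.6
    dropout_rate: float = 0.3
    noise_sd: float = 1.0
    baseline_mean: float = 4.0
    seed: int = 0
    # "neoplastic_vs_normal" (default) shifts discriminative genes in all
    # neoplastic cells; "core_vs_periphery" shifts them in T-core only.
    contrast: str = "neoplastic_vs_normal"

    def __post_init__(self) -> None:
        if self.k_discriminative + self.k_shared_module + self.k_divergent_module > self.p:
            raise ValueError("planted gene sets exceed the total number of genes")
        if not 0 < self.module_correlation < 1:
            raise ValueError("module_correlation must lie in (0, 1)")
        if not 0 <= self.dropout_rate <= 1:
            raise ValueError("dropout_rate must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.contrast not in _CONTRASTS:
            raise ValueError(f"contrast must be one of {_CONTRASTS}")
        if min(self.n_core, self.n_periph_neo, self.n_periph_norm) < 1:
            raise ValueError("every population needs at least one cell")


@dataclass
class SimulationTruth:
    """Ground truth of one simulation: exactly the genes the generator touched."""

    discriminative_genes: list[str]
    shared_module_genes: list[str]
    divergent_module_genes: list[str]
    population_of_cell: dict[str, Population]

    def to_json(self, path: str | Path, design: SimulationDesign | None = None) -> None:
        payload = {
            "discriminative_genes": self.discriminative_genes,
            "shared_module_genes": self.shared_module_genes,
            "divergent_module_genes": self.divergent_module_genes,
            "population_of_cell": {k: list(v) for k, v in self.population_of_cell.items()},
        }
        if design is not None:
            payload["design"] = asdict(design)
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def simulate_cells(
    design: SimulationDesign,
) -> tuple[ExpressionMatrix, list[CellAnnotation], SimulationTruth]:
    """Generate one three-population expression matrix with known ground truth."""
    rng = np.random.default_rng(design.seed)
    n = design.n_core + design.n_periph_neo + design.n_periph_norm
    p = design.p

    populations = (
        [T_CORE] * design.n_core
        + [T_PERIPHERY] * design.n_periph_neo
        + [N_PERIPHERY] * design.n_periph_norm
    )
    width = len(str(n))
    cell_ids = [f"cell{i:0{width}d}" for i in range(n)]
    gwidth = len(str(p))
    gene_ids = [f"g{j:0{gwidth}d}" for j in range(p)]

    is_core = np.array([pop == T_CORE for pop in populations])
    is_neo = np.array([pop[0] == "neoplastic" for pop in populations])

    kd, ks, kv = design.k_discriminative, design.k_shared_module, design.k_divergent_module
    disc = slice(0, kd)
    shared = slice(kd, kd + ks)
    divergent = slice(kd + ks, kd + ks + kv)

    x = design.baseline_mean + design.noise_sd * rng.standard_normal((n, p))

    c = design.module_correlation
    loading = np.sqrt(c / (1.0 - c)) * design.noise_sd
    if ks:
        f = rng.standard_normal(n)
        x[:, shared] += np.where(is_neo, f, 0.0)[:, None] * loading
    if kv:
        g = rng.standard_normal(n)
        x[:, divergent] += np.where(is_core, g, 0.0)[:, None] * loading
    if kd:
        shifted = is_neo if design.contrast == "neoplastic_vs_normal" else is_core
        x[:, disc] += np.where(shifted, design.effect_size, 0.0)[:, None]

    np.maximum(x, 0.0, out=x)
    if design.dropout_rate > 0:
        x[rng.random((n, p)) < design.dropout_rate] = 0.0

    expr = ExpressionMatrix(x, cell_ids, gene_ids)
    ann = [CellAnnotation(cid, *pop) for cid, pop in zip(cell_ids, populations)]
    truth = SimulationTruth(
        discriminative_genes=gene_ids[disc],
        shared_module_genes=gene_ids[shared],
        divergent_module_genes=gene_ids[divergent],
        population_of_cell=dict(zip(cell_ids, populations)),
    )
    return expr, ann, truth


def write_dataset(
    out_dir: str | Path,
    expr: ExpressionMatrix,
    ann: list[CellAnnotation],
    truth: SimulationTruth | None = None,
    design: SimulationDesign | None = None,
) -> dict[str, str]:
    """Write expression/annotations (and truth sidecar) as text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": str(out / "expression.tsv"),
        "annotations": str(out / "annotations.tsv"),
    }
    write_expression(expr, paths["expression"])
    write_annotations(ann, paths["annotations"])
    if truth is not None:
        paths["truth"] = str(out / "truth.json")
        truth.to_json(paths["truth"], design)
    return paths


# ---------------------------------------------------------------------------
# survival data
# ---------------------------------------------------------------------------


@dataclass
class SurvivalDataset:
    """Bulk-expression survival dataset with right censoring."""

    sample_ids: list[str]
    expression: np.ndarray
    gene_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    true_coefficients: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        self.event = np.asarray(self.event, int)
        if np.any(self.time <= 0):
            raise ValueError("all times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicators must be 0/1")
        if self.expression.shape[0] != len(self.time):
            raise ValueError("expression rows must match number of times")


def simulate_survival(
    n_samples: int,
    gene_ids: list[str],
    nonzero_coefficients: dict[str, float] | None = None,
    baseline_hazard: float = 0.1,
    censoring_rate: float = 0.0,
    seed: int = 0,
) -> SurvivalDataset:
    """Exponential proportional-hazards survival data with known coefficients."""
    if not 0 <= censoring_rate < 1:
        raise ValueError("censoring_rate must lie in [0, 1)")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    rng = np.random.default_rng(seed)
    p = len(gene_ids)
    beta = np.zeros(p)
    for g, b in (nonzero_coefficients or {}).items():
        beta[gene_ids.index(g)] = b

    x = rng.standard_normal((n_samples, p))
    rate = baseline_hazard * np.exp(x @ beta)
    t_event = rng.exponential(1.0 / rate)

    if censoring_rate > 0:
        # With C ~ Exp(mu) independent of T_i ~ Exp(rate_i),
        # P(censored | rate_i) = mu / (mu + rate_i); calibrate mu by bisection.
        def expected_censored(mu: float) -> float:
            return float(np.mean(mu / (mu + rate)))

        lo, hi = 1e-12, 1e12
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            if expected_censored(mid) < censoring_rate:
                lo = mid
            else:
                hi = mid
        mu = np.sqrt(lo * hi)
        t_cens = rng.exponential(1.0 / mu, size=n_samples)
    else:
        t_cens = np.full(n_samples, np.inf)

    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    width = len(str(n_samples))
    sample_ids = [f"s{i:0{width}d}" for i in range(n_samples)]
    return SurvivalDataset(sample_ids, x, list(gene_ids), time, event, beta)


def write_survival(ds: SurvivalDataset, out_dir: str | Path) -> dict[str, str]:
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr_path = out / "survival_expression.tsv"
    clin_path = out / "survival_clinical.tsv"
    pd.DataFrame(ds.expression, index=ds.sample_ids, columns=ds.gene_ids).to_csv(
        expr_path, sep="\t", float_format="%.17g"
    )
    pd.DataFrame(
        {"sample_id": ds.sample_ids, "time": ds.time, "event": ds.event}
    ).to_csv(clin_path, sep="\t", index=False, float_format="%.17g")
    return {"expression": str(expr_path), "clinical": str(clin_path)}
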