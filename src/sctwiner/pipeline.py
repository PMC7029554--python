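"""End-to-end orchestration of the Model I/II/III classification analyses.

A model run chains: population subsetting → binary labels → (twiner weights
from the two neoplastic populations, when requested) → cross-validation of
(λ, α) → the resampling stability protocol → consensus signature →
per-population correlation networks → optional survival validation. Every
output is written as text together with a manifest holding all parameters
and seeds plus input digests, sufficient to reproduce the archive exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .containers import (
    ExpressionMatrix,
    N_PERIPHERY,
    Population,
    T_CORE,
    T_PERIPHERY,
    align_expression,
    make_labels,
    read_annotations,
    read_expression,
    subset_population,
    write_signature,
)
from .glm import WeightedLogit
from .network import build_network, compare_networks, write_edge_list, write_graphml
from .resampling import run_protocol
from .survival import validate_signature
from .weights import correlation_matrix, twiner_weights, write_weights

#: class-1 / class-0 population schemes of the three classification models
MODEL_SCHEMES: dict[str, tuple[list[Population], list[Population]]] = {
    "I": ([T_CORE], [T_PERIPHERY]),
    "II": ([T_PERIPHERY], [N_PERIPHERY]),
    "III": ([T_CORE, T_PERIPHERY], [N_PERIPHERY]),
}


@dataclass
class AnalysisConfig:
    """Declarative configuration of one model run."""

    expression_path: str
    annotations_path: str
    model: str = "III"  # I / II / III
    regularizer: str = "en"  # en / twiner
    alpha_grid: list[float] = field(default_factory=lambda: [round(a, 1) for a in np.arange(0.1, 1.0, 0.1)])
    n_folds: int = 10
    n_lambda: int = 100
    n_runs: int = 1000
    train_fraction: float = 0.75
    consensus_threshold: float = 0.75
    network_threshold: float = 0.2
    seed: int = 0
    survival_expression_path: str | None = None
    survival_clinical_path: str | None = None

    def __post_init__(self) -> None:
        if self.model not in MODEL_SCHEMES:
            raise ValueError(f"model must be one of {sorted(MODEL_SCHEMES)}")
        if self.regularizer not in ("en", "twiner"):
            raise ValueError("regularizer must be 'en' or 'twiner'")
        if self.regularizer == "twiner" and self.model != "III":
            raise ValueError(
                "twiner weights compare the two neoplastic populations and "
                "apply to Model III (neoplastic vs normal) only"
            )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_model(config: AnalysisConfig, out_dir: str | Path) -> dict:
    """Execute one full analysis; returns the manifest dictionary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

        return _Ctx()

    manifest: dict = {
        "sctwiner_version": __version__,
        "config": asdict(config),
        "inputs": {
            "expression_sha256": _sha256(config.expression_path),
            "annotations_sha256": _sha256(config.annotations_path),
        },
        "outputs": {},
    }

    with stage("load"):
        expr = read_expression(config.expression_path)
        ann = read_annotations(config.annotations_path, expr=expr)

    class1, class0 = MODEL_SCHEMES[config.model]
    with stage("labels"):
        labels, excluded = make_labels(ann, class1, class0)
        expr_model = align_expression(expr, labels)
        manifest["n_class1"], manifest["n_class0"] = labels.counts()
        manifest["n_excluded"] = len(excluded)

    penalty_weights = None
    if config.regularizer == "twiner":
        with stage("twiner_weights"):
            sa = correlation_matrix(
                subset_population(expr, ann, T_CORE), population_label="T-core"
            )
            sb = correlation_matrix(
                subset_population(expr, ann, T_PERIPHERY),
                population_label="T-periphery",
            )
            tw = twiner_weights(sa, sb)
            penalty_weights = tw
            wpath = out / "twiner_weights.tsv"
            write_weights(tw, wpath)
            manifest["outputs"]["twiner_weights"] = wpath.name

    with stage("cross_validate"):
        model = WeightedLogit(
            expr_model.values,
            labels.values,
            gene_ids=list(expr_model.gene_ids),
            penalty_weights=penalty_weights,
        )
        cv = model.fit_cv(
            alpha_grid=config.alpha_grid,
            n_folds=config.n_folds,
            n_lambda=config.n_lambda,
            seed=config.seed,
        )
        cv_path = out / "cv_table.tsv"
        cv.cv_table.to_csv(cv_path, sep="\t", index=False, float_format="%.17g")
        manifest["outputs"]["cv_table"] = cv_path.name
        manifest["chosen_lambda"] = cv.config.lam
        manifest["chosen_alpha"] = cv.config.alpha

    with stage("stability"):
        stab = run_protocol(
            expr_model.values,
            labels.values,
            cv.config,
            gene_ids=list(expr_model.gene_ids),
            n_runs=config.n_runs,
            train_fraction=config.train_fraction,
            consensus_threshold=config.consensus_threshold,
            seed=config.seed,
        )
        stab.metrics.to_csv(out / "run_metrics.tsv", sep="\t", index=False, float_format="%.17g")
        stab.selection_frequency.rename_axis("gene_id").reset_index().to_csv(
            out / "selection_frequency.tsv", sep="\t", index=False, float_format="%.17g"
        )
        write_signature(stab.consensus, out / "consensus_signature.tsv")
        summary = {k: float(v) for k, v in stab.median_summary.items()}
        (out / "median_metrics.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        manifest["outputs"].update(
            {
                "run_metrics": "run_metrics.tsv",
                "selection_frequency": "selection_frequency.tsv",
                "consensus_signature": "consensus_signature.tsv",
                "median_metrics": "median_metrics.json",
            }
        )
        manifest["n_consensus_genes"] = len(stab.consensus)

    if len(stab.consensus) >= 2:
        with stage("networks"):
            nets = []
            for pop, label in (
                (T_CORE, "T-core"),
                (T_PERIPHERY, "T-periphery"),
                (N_PERIPHERY, "N-periphery"),
            ):
                try:
                    sub = subset_population(expr, ann, pop)
                except ValueError:
                    continue
                net = build_network(
                    sub,
                    stab.consensus,
                    config.network_threshold,
                    population_label=label,
                )
                write_edge_list(net, out / f"network_{label}.tsv")
                write_graphml(net, out / f"network_{label}.graphml")
                manifest["outputs"][f"network_{label}"] = f"network_{label}.tsv"
                nets.append(net)
            if len(nets) >= 2:
                cmp_path = out / "network_comparison.tsv"
                compare_networks(nets).to_csv(
                    cmp_path, sep="\t", index=False, float_format="%.17g"
                )
                manifest["outputs"]["network_comparison"] = cmp_path.name

    if config.survival_expression_path and len(stab.consensus) >= 1:
        with stage("survival"):
            sexpr = read_expression(config.survival_expression_path)
            clin = pd.read_csv(config.survival_clinical_path, sep="\t")
            clin = clin.set_index("sample_id").loc[sexpr.cell_ids]
            present = [g for g in stab.consensus.gene_ids if g in set(sexpr.gene_ids)]
            report = validate_signature(
                sexpr.values,
                clin["time"].to_numpy(float),
                clin["event"].to_numpy(int),
                present,
                gene_ids=list(sexpr.gene_ids),
            )
            report.to_json(out / "survival_report.json")
            report.km_high.to_dataframe().to_csv(
                out / "km_high.tsv", sep="\t", index=False, float_format="%.17g"
            )
            report.km_low.to_dataframe().to_csv(
                out / "km_low.tsv", sep="\t", index=False, float_format="%.17g"
            )
            manifest["inputs"]["survival_expression_sha256"] = _sha256(
                config.survival_expression_path
            )
            manifest["inputs"]["survival_clinical_sha256"] = _sha256(
                config.survival_clinical_path
            )
            manifest["outputs"]["survival_report"] = "survival_report.json"
            manifest["logrank_p"] = report.logrank_p

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def run_from_manifest(manifest_path: str | Path, out_dir: str | Path) -> dict:
    """Re-execute a run from its manifest (must reproduce outputs exactly)."""
    manifest = json.loads(Path(manifest_path).read_text())
    config = AnalysisConfig(**manifest["config"])
    return run_model(config, out_dir)
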