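"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: synthetic cohort generation → SWC quality
control → morphometry feature table → bootstrap variable importance →
balanced-subsample census → agreement statistics → rendering → CNN
cross-validation.  Every stage is seeded deterministically from the global
seed, writes its outputs into the run directory, and is recorded in a
manifest with SHA-256 checksums, so identical configs reproduce identical
manifests bit for bit.

Printed protocol constants (feature subset size 10, 5000 repetitions,
50 cells per class, lr 1e-4, 10 epochs, batch 16, 224-pixel images) are the
library defaults; the pipeline config scales them down for desk runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import agreement, cnn, morphometry, rendering, swc_io, synthetic, tabular_ml

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGE_ORDER = (
    "synth", "qc", "features", "selection", "census", "agreement",
    "render", "cnn",
)

_STAGE_DEPS = {
    "qc": ("synth",),
    "features": ("synth",),
    "selection": ("features",),
    "census": ("features",),
    "agreement": ("selection",),
    "render": ("synth",),
    "cnn": ("render",),
}


@dataclass
class PipelineConfig:
    """Stage toggles and per-stage parameters for one analysis run."""

    output_dir: str = "venmorph_run"
    seed: int = 0
    stages: tuple[str, ...] = _STAGE_ORDER
    n_ven: int = 60
    n_pyr: int = 60
    importance_subset_size: int = 6
    importance_n_reps: int = 200
    census_n_per_class: int = 30
    census_n_reps: int = 200
    n_experts: int = 7
    image_size: int = 64
    render_style: str = "diameter_enhanced"
    cnn_epochs: int = 6
    cnn_folds: int = 2
    cnn_subset: int = 80  # images used for the CNN stage

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the run manifest.

    Each stage writes its artifacts under ``config.output_dir`` and the
    manifest records every file with its checksum.  A stage whose
    dependency is disabled raises a dependency error naming the stage.
    """
    enabled = [s for s in _STAGE_ORDER if s in config.stages]
    for stage in enabled:
        for dep in _STAGE_DEPS.get(stage, ()):
            if dep not in enabled:
                raise ValueError(
                    f"stage {stage!r} requires stage {dep!r} to be enabled"
                )

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    state: dict = {}

    def save_df(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path)
        manifest["artifacts"][name] = _sha256(path)

    def save_json(obj, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float))
        manifest["artifacts"][name] = _sha256(path)

    if "synth" in enabled:
        gen = synthetic.GeneratorConfig(
            n_ven=config.n_ven, n_pyr=config.n_pyr,
            seed=_stage_seed(config.seed, "synth"),
        )
        trees, labels = synthetic.generate_cohort(gen)
        state["trees"], state["labels"] = trees, labels
        labels_df = pd.DataFrame(
            {"label": pd.Series(labels)}).rename_axis("cell_id")
        save_df(labels_df, "labels.csv")
        manifest["stages"]["synth"] = {"n_cells": len(trees)}

    if "qc" in enabled:
        reports = {
            cid: swc_io.run_qc(tree).to_dict()
            for cid, tree in state["trees"].items()
        }
        save_json(reports, "qc_reports.json")
        n_pass = sum(1 for r in reports.values() if r["passed"])
        manifest["stages"]["qc"] = {"n_pass": n_pass, "n_total": len(reports)}

    if "features" in enabled:
        table = morphometry.feature_table(state["trees"], state["labels"])
        state["features"] = table
        save_df(table, "features.csv")
        manifest["stages"]["features"] = {"n_rows": len(table)}

    if "selection" in enabled:
        adapters = tabular_ml.default_adapters(fast=True)
        ranking = tabular_ml.bootstrap_importance(
            state["features"], adapters,
            subset_size=config.importance_subset_size,
            n_reps=config.importance_n_reps,
            seed=_stage_seed(config.seed, "selection"),
        )
        state["ranking"] = ranking
        save_df(ranking.summary, "importance_summary.csv")
        corr, mean_r, sd_r = tabular_ml.rank_correlation_between_adapters(
            ranking.per_adapter
        )
        save_df(corr, "adapter_rank_correlations.csv")
        manifest["stages"]["selection"] = {
            "top_feature": ranking.consensus_order()[0],
            "mean_inter_adapter_rho": mean_r,
            "sd_inter_adapter_rho": sd_r,
        }

    if "census" in enabled:
        adapters = tabular_ml.default_adapters(fast=True)
        census = tabular_ml.subsample_census(
            state["features"], adapters,
            n_per_class=config.census_n_per_class,
            n_reps=config.census_n_reps,
            seed=_stage_seed(config.seed, "census"),
        )
        save_df(census, "census.csv")
        worst = tabular_ml.misclassified_by_at_least(census, len(adapters))
        manifest["stages"]["census"] = {
            "n_misclassified_by_all": len(worst),
            "misclassified_by_all": worst[:10],
        }

    if "agreement" in enabled:
        rng = np.random.default_rng(_stage_seed(config.seed, "agreement"))
        per_adapter = state["ranking"].per_adapter
        algo_ranks = pd.DataFrame({
            name: df["median_rank"] for name, df in per_adapter.items()
        }).T
        n_vars = algo_ranks.shape[1]
        # synthetic expert panel: noisy permutations of the consensus order
        consensus = algo_ranks.mean(axis=0).rank().to_numpy()
        experts = {}
        for i in range(config.n_experts):
            noise = rng.normal(0, n_vars / 2.0, size=n_vars)
            experts[f"expert_{i}"] = pd.Series(
                pd.Series(consensus + noise).rank().to_numpy(),
                index=algo_ranks.columns,
            )
        expert_ranks = pd.DataFrame(experts).T
        matrix = agreement.RankingMatrix(
            ranks=pd.concat([expert_ranks, algo_ranks]),
            kinds={**{r: agreement.EXPERT for r in expert_ranks.index},
                   **{r: agreement.ALGORITHM for r in algo_ranks.index}},
        )
        kappa = agreement.fleiss_kappa(expert_ranks.round())
        rho = agreement.spearman_between(
            expert_ranks.mean(axis=0).rank(), algo_ranks.mean(axis=0).rank()
        )
        var_ratio = agreement.variance_consistency(matrix)
        save_json(
            {"fleiss_kappa": kappa, "spearman": rho,
             "variance": {k: v for k, v in var_ratio.items()
                          if k != "per_variable"}},
            "agreement.json",
        )
        manifest["stages"]["agreement"] = {
            "kappa": kappa["kappa"],
            "rho": rho["rho"],
            "expert_to_algorithm_ratio": var_ratio["expert_to_algorithm_ratio"],
        }

    if "render" in enabled:
        by_label: dict[str, list[str]] = {}
        for cid, lbl in state["labels"].items():
            by_label.setdefault(lbl, []).append(cid)
        per_class = max(1, config.cnn_subset // max(len(by_label), 1))
        subset = [c for cids in by_label.values() for c in cids[:per_class]]
        trees = {c: state["trees"][c] for c in subset}
        labels = {c: state["labels"][c] for c in subset}
        images, y = rendering.render_dataset(
            trees, labels, style=config.render_style, size=config.image_size
        )
        state["images"], state["image_labels"] = images, y
        rows = [
            {"cell_id": img.cell_id, "style": img.style, "mask": img.mask,
             "label": int(lbl)}
            for img, lbl in zip(images, y)
        ]
        save_df(pd.DataFrame(rows).set_index("cell_id"), "render_manifest.csv")
        manifest["stages"]["render"] = {"n_images": len(images)}

    if "cnn" in enabled:
        cfg = cnn.TrainConfig(
            profile="desk_small_cnn",
            epochs=config.cnn_epochs,
            input_size=config.image_size,
            seed=_stage_seed(config.seed, "cnn"),
        )
        cv = cnn.cross_validate(
            state["images"], state["image_labels"], cfg, k=config.cnn_folds
        )
        save_json(
            {"mean_accuracy": cv["mean_accuracy"],
             "sd_accuracy": cv["sd_accuracy"], "k": cv["k"],
             "folds": cv["folds"]},
            "cnn_cv.json",
        )
        manifest["stages"]["cnn"] = {
            "mean_accuracy": cv["mean_accuracy"],
            "sd_accuracy": cv["sd_accuracy"],
        }

    manifest_path = out / "manifest.json"
    manifest_path.write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=float)
    )
    return manifest
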