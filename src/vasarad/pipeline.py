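"""End-to-end workflow: simulate -> extract -> encode -> select -> model -> fuse.

Stages mirror the radiogenomics study design the package implements:

1. generate (or load) a cohort and split it, stratified by genotype, into
   training and validation subsets;
2. extract the 56 ADC radiomics features per subject and min-max normalize
   them with training-cohort bounds; encode the 23 VASARI traits;
3. select top-5 VASARI and top-10 radiomics features on the training cohort
   (mRMR pool, then single-feature 0.632+ bootstrap AUC ranking);
4. sweep model orders (1-5 VASARI, 1-10 radiomics) by training-cohort
   0.632+ bootstrap AUC and keep the optimal order of each type;
5. evaluate both optimal models and their probability-fusion (weight 0.5)
   on the validation cohort; compute the cross-type Pearson correlations;
   optionally test age/gender augmentation.

Nothing fitted on validation data is ever reused for validation scoring:
normalization bounds, selection decisions and model orders all come from
the training cohort alone.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .modeling import (
    ModelConfig,
    augment_with_clinical,
    evaluate,
    evaluate_fusion,
    feature_correlation,
    split_cohort,
    sweep_model_order,
)
from .radiomics import extract_table, normalize_features
from .selection import SelectionResult, select_top_features
from .synthetic import SyntheticCohort, SyntheticConfig, generate_cohort
from .types import FeatureTable


@dataclass
class PipelineConfig:
    """Structural and computational settings of one pipeline run.

    The structural defaults follow the study design this package models:
    a 67/102 training fraction, top-5 VASARI / top-10 radiomics selection,
    a 30-feature radiomics mRMR pool and fusion weight 0.5.  The replicate
    and forest sizes are the package's own desk-scale defaults.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    train_fraction: float = 67 / 102
    n_levels: int = 32
    k_vasari: int = 5
    k_radiomics: int = 10
    radiomics_pool: int = 30
    selection_replicates: int = 100
    selection_model: ModelConfig = field(default_factory=lambda: ModelConfig(n_trees=50))
    sweep_replicates: int = 100
    model: ModelConfig = field(default_factory=lambda: ModelConfig(n_trees=200))
    fusion_weight: float = 0.5
    include_clinical: bool = False
    seed: int = 0


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: SyntheticCohort
    split: object
    vasari_train: FeatureTable
    vasari_validation: FeatureTable
    radiomics_train: FeatureTable
    radiomics_validation: FeatureTable
    vasari_selection: SelectionResult
    radiomics_selection: SelectionResult
    vasari_sweep: object
    radiomics_sweep: object
    vasari_features: list[str]
    radiomics_features: list[str]
    vasari_report: object
    radiomics_report: object
    fusion_report: object
    clinical_report: object | None
    correlation: pd.DataFrame
    timings: dict[str, float]


def run_pipeline(config: PipelineConfig, cohort: SyntheticCohort | None = None) -> PipelineResult:
    """Execute the full workflow on a synthetic (or provided) cohort."""
    timings: dict[str, float] = {}

    def tic(stage):
        timings[stage] = time.perf_counter()

    def toc(stage):
        timings[stage] = time.perf_counter() - timings[stage]

    tic("simulate")
    if cohort is None:
        cohort = generate_cohort(config.synthetic)
    toc("simulate")

    labels = cohort.labels()
    split = split_cohort(
        list(labels), labels, config.train_fraction, seed=config.seed
    )

    tic("extract")
    radiomics_all = extract_table(cohort.radiomics_subjects(), n_levels=config.n_levels)
    toc("extract")
    lex = cohort.config.lexicon
    vasari_all = lex.encode_records(cohort.vasari_records(), labels)

    rad_train = normalize_features(radiomics_all.subset(split.train_ids))
    rad_val = normalize_features(
        radiomics_all.subset(split.validation_ids), bounds=rad_train.bounds
    )
    vas_train = normalize_features(vasari_all.subset(split.train_ids))
    vas_val = normalize_features(
        vasari_all.subset(split.validation_ids), bounds=vas_train.bounds
    )

    tic("select")
    vas_sel = select_top_features(
        vas_train, k=config.k_vasari, pool_size=len(vas_train.feature_names),
        model_config=config.selection_model,
        n_replicates=config.selection_replicates, seed=config.seed,
    )
    rad_sel = select_top_features(
        rad_train, k=config.k_radiomics, pool_size=config.radiomics_pool,
        model_config=config.selection_model,
        n_replicates=config.selection_replicates, seed=config.seed,
    )
    toc("select")

    tic("sweep")
    vas_sweep = sweep_model_order(
        vas_sel, vas_train, config.selection_model,
        n_replicates=config.sweep_replicates, seed=config.seed,
    )
    rad_sweep = sweep_model_order(
        rad_sel, rad_train, config.selection_model,
        n_replicates=config.sweep_replicates, seed=config.seed,
    )
    toc("sweep")
    vas_features = vas_sel.top(vas_sweep.optimal_order)
    rad_features = rad_sel.top(rad_sweep.optimal_order)

    tic("evaluate")
    model_cfg = ModelConfig(
        n_trees=config.model.n_trees, max_depth=config.model.max_depth,
        min_samples_leaf=config.model.min_samples_leaf,
        n_repeats=config.model.n_repeats, threshold=config.model.threshold,
        seed=config.seed,
    )
    vas_report = evaluate(vas_train, vas_val, vas_features, model_cfg)
    rad_report = evaluate(rad_train, rad_val, rad_features, model_cfg)
    fusion_report = evaluate_fusion(
        vas_train, rad_train, vas_val, rad_val,
        vas_features, rad_features, weight=config.fusion_weight, config=model_cfg,
    )
    toc("evaluate")

    clinical_report = None
    if config.include_clinical:
        age = pd.Series({s.id: s.age for s in cohort.subjects})
        gender = pd.Series({s.id: s.gender for s in cohort.subjects})
        vas_train_c = augment_with_clinical(vas_train, age, gender)
        vas_val_c = augment_with_clinical(vas_val, age, gender)
        clinical_report = evaluate_fusion(
            vas_train_c, rad_train, vas_val_c, rad_val,
            vas_features + ["age", "gender"], rad_features,
            weight=config.fusion_weight, config=model_cfg,
        )

    correlation = feature_correlation(
        vas_train.select_features(vas_features),
        rad_train.select_features(rad_features),
    )

    return PipelineResult(
        config=config, cohort=cohort, split=split,
        vasari_train=vas_train, vasari_validation=vas_val,
        radiomics_train=rad_train, radiomics_validation=rad_val,
        vasari_selection=vas_sel, radiomics_selection=rad_sel,
        vasari_sweep=vas_sweep, radiomics_sweep=rad_sweep,
        vasari_features=vas_features, radiomics_features=rad_features,
        vasari_report=vas_report, radiomics_report=rad_report,
        fusion_report=fusion_report, clinical_report=clinical_report,
        correlation=correlation, timings=timings,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(result: PipelineResult, out_dir, figures: bool = True) -> dict:
    """Write all stage outputs plus a run manifest with per-file hashes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    io.write_feature_table(result.radiomics_train, out / "radiomics_train.csv")
    io.write_feature_table(result.radiomics_validation, out / "radiomics_validation.csv")
    io.write_feature_table(result.vasari_train, out / "vasari_train.csv")
    io.write_feature_table(result.vasari_validation, out / "vasari_validation.csv")
    io.write_selection(result.vasari_selection, out / "selection_vasari.csv",
                       out / "selection_vasari.json")
    io.write_selection(result.radiomics_selection, out / "selection_radiomics.csv",
                       out / "selection_radiomics.json")
    result.correlation.to_csv(out / "correlation.csv")

    reports = {
        "vasari": result.vasari_report.as_dict(),
        "radiomics": result.radiomics_report.as_dict(),
        "fusion": result.fusion_report.as_dict(),
    }
    if result.clinical_report is not None:
        reports["fusion_with_clinical"] = result.clinical_report.as_dict()
    reports["vasari_optimal_order"] = result.vasari_sweep.optimal_order
    reports["radiomics_optimal_order"] = result.radiomics_sweep.optimal_order
    reports["vasari_features"] = result.vasari_features
    reports["radiomics_features"] = result.radiomics_features
    (out / "reports.json").write_text(json.dumps(reports, indent=2))

    for name, report in (
        ("vasari", result.vasari_report),
        ("radiomics", result.radiomics_report),
        ("fusion", result.fusion_report),
    ):
        pd.DataFrame({"fpr": report.roc.fpr, "tpr": report.roc.tpr}).to_csv(
            out / f"roc_{name}.csv", index=False
        )

    if figures:
        _write_figures(result, out)

    files = sorted(p for p in out.rglob("*") if p.is_file() and p.suffix != ".png")
    manifest = {
        "seed": result.config.seed,
        "stages": list(result.timings),
        "timings_s": {k: round(v, 3) for k, v in result.timings.items()},
        "hashes": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _write_figures(result: PipelineResult, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, report in (
        ("VASARI", result.vasari_report),
        ("radiomics", result.radiomics_report),
        ("fusion", result.fusion_report),
    ):
        ax.plot(report.roc.fpr, report.roc.tpr, label=f"{name} (AUC {report.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(out / "roc_overlay.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(result.correlation.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(result.correlation.columns)))
    ax.set_xticklabels(result.correlation.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(result.correlation.index)))
    ax.set_yticklabels(result.correlation.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    fig.savefig(out / "correlation_heatmap.png", dpi=120)
    plt.close(fig)


def render_report(result: PipelineResult) -> str:
    """Human-readable run summary: selection tables, sweeps, model comparison."""
    lines = ["# Pipeline report", ""]
    lines.append("## Selected features (single-feature 0.632+ bootstrap AUC)")
    lines.append("")
    lines.append("| VASARI feature | AUC | Radiomics feature | AUC |")
    lines.append("|---|---|---|---|")
    vs = result.vasari_selection
    rs = result.radiomics_selection
    for i in range(max(len(vs.features), len(rs.features))):
        v = f"{vs.features[i]} | {vs.aucs[i]:.3f}" if i < len(vs.features) else " | "
        r = f"{rs.features[i]} | {rs.aucs[i]:.3f}" if i < len(rs.features) else " | "
        lines.append(f"| {v} | {r} |")
    lines.append("")
    lines.append("## Model-order sweep (training 0.632+ AUC)")
    for name, sweep in (("VASARI", result.vasari_sweep), ("radiomics", result.radiomics_sweep)):
        aucs = ", ".join(f"{e.combined:.3f}" for e in sweep.estimates)
        lines.append(
            f"- {name}: orders {sweep.orders[0]}..{sweep.orders[-1]} -> [{aucs}]; "
            f"optimal order {sweep.optimal_order} (AUC {sweep.optimal_auc:.3f})"
        )
    lines.append("")
    lines.append("## Validation cohort performance (mean +/- sd over repeats)")
    rows = [
        ("VASARI", result.vasari_report),
        ("radiomics", result.radiomics_report),
        ("fusion", result.fusion_report),
    ]
    if result.clinical_report is not None:
        rows.append(("fusion + clinical", result.clinical_report))
    lines.append("| model | AUC | sensitivity | specificity | accuracy |")
    lines.append("|---|---|---|---|---|")
    for name, rep in rows:
        lines.append(
            f"| {name} | {rep.auc:.3f} ± {rep.auc_sd:.3f} "
            f"| {rep.sensitivity:.3f} ± {rep.sensitivity_sd:.3f} "
            f"| {rep.specificity:.3f} ± {rep.specificity_sd:.3f} "
            f"| {rep.accuracy:.3f} ± {rep.accuracy_sd:.3f} |"
        )
    lines.append("")
    corr = result.correlation.to_numpy()
    lines.append(
        f"Cross-type Pearson correlation: mean |r| = {np.abs(corr).mean():.3f}, "
        f"max |r| = {np.abs(corr).max():.3f}"
    )
    return "\n".join(lines)
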