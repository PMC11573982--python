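"""End-to-end orchestration of the reference-uncertainty experiment.

For a dataset (synthetic profile or user CSVs) the runner performs a
stratified 7:3 split, then for every (level, repetition) cell permutes the
training references, runs each configured selector once on the permuted
training set, trains each configured classifier under stratified CV, and
records AUC / accuracy / sensitivity / specificity on the three evaluation
surfaces.  Per (selector, level) it computes the multi-set Jaccard
stability of the selected sets across repetitions.

All randomness flows from one master seed through documented subkeys, so
re-running an identical configuration reproduces identical output tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._utils import derive_seed
from .classification import (
    CLASSIFIER_NAMES,
    PipelineSpec,
    crossval_train,
    default_cv_folds,
    predict_holdout,
)
from .data_model import (
    FeatureTable,
    ReferenceVector,
    ValidationError,
    read_feature_table,
    read_reference,
    stratified_split,
)
from .evaluation_metrics import compare_levels, comparison_to_frame, metrics_from_scores
from .feature_selection import SELECTOR_NAMES, jaccard_multi, run_selector
from .reference_permutation import (
    DEFAULT_LEVELS,
    PermutationPlan,
    generate_repetitions,
)
from .synthetic_data import generate, get_profile

log = logging.getLogger(__name__)

# master-seed subkeys; any cell of the experiment is reproducible in isolation
_KEY_DATA, _KEY_SPLIT, _KEY_PERM, _KEY_SELECT, _KEY_CLASSIFY = range(5)


@dataclass
class ExperimentConfig:
    """Fully serializable description of one experiment run.

    ``dataset`` is a named synthetic profile ("dataset1"/"dataset2"), a
    profile mapping, or a mapping with ``features_csv``/``labels_csv`` paths.
    ``cv_folds=None`` picks 10-fold for training sets of >= 150 samples and
    5-fold otherwise; ``n_target=None`` uses min(30, n_train // 5) for RFE
    and mRMR.
    """

    dataset: object = "dataset1"
    seed: int = 0
    split_ratio: float = 0.7
    levels: tuple[float, ...] = DEFAULT_LEVELS
    repetitions: int = 20
    selectors: tuple[str, ...] = SELECTOR_NAMES
    classifiers: tuple[str, ...] = CLASSIFIER_NAMES
    cv_folds: int | None = None
    n_target: int | None = None
    alpha: float = 0.05
    cutoff: float = 0.5
    rf_n_estimators: int = 500
    selection_in_cv: bool = True
    out_dir: str | None = None
    permissive: bool = False

    def __post_init__(self):
        self.levels = tuple(float(v) for v in self.levels)
        self.selectors = tuple(self.selectors)
        self.classifiers = tuple(self.classifiers)
        unknown = set(self.selectors) - set(SELECTOR_NAMES)
        if unknown:
            raise ValidationError(f"unknown selectors {sorted(unknown)}")
        unknown = set(self.classifiers) - set(CLASSIFIER_NAMES)
        if unknown:
            raise ValidationError(f"unknown classifiers {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = asdict(self)
        if not isinstance(d["dataset"], (str, dict)):
            d["dataset"] = asdict(self.dataset)
        for key in ("levels", "selectors", "classifiers"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


@dataclass
class ExperimentResult:
    """Tidy result tables plus the run manifest."""

    metrics: pd.DataFrame
    jsc: pd.DataFrame
    selection_sizes: pd.DataFrame
    comparisons: pd.DataFrame
    manifest: dict
    train_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    provenance: list[dict]


def _load_dataset(config: ExperimentConfig):
    if isinstance(config.dataset, dict) and "features_csv" in config.dataset:
        table = read_feature_table(config.dataset["features_csv"])
        ref = read_reference(config.dataset["labels_csv"], table)
        return table, ref, {"source": "csv", **config.dataset}
    profile = get_profile(config.dataset)
    ds = generate(profile, seed=derive_seed(config.seed, _KEY_DATA))
    return ds.features, ds.labels, {"source": "synthetic", "profile": asdict(profile)}


def run_experiment(config: ExperimentConfig) -> ExperimentResult:
    """Run the full levels x repetitions x pipelines factorial experiment."""
    table, ref, dataset_info = _load_dataset(config)
    split = stratified_split(
        table, ref, ratio=config.split_ratio, seed=derive_seed(config.seed, _KEY_SPLIT)
    )
    train_table = table.subset_rows(split.train_ids)
    test_table = table.subset_rows(split.test_ids)
    train_ref = ref.subset(split.train_ids)
    test_ref = ref.subset(split.test_ids)

    cv_folds = config.cv_folds or default_cv_folds(train_table.n)
    plan = PermutationPlan(
        levels=config.levels,
        repetitions=config.repetitions,
        master_seed=derive_seed(config.seed, _KEY_PERM),
    )
    perms = generate_repetitions(train_ref, plan)

    level_index = {lv: i for i, lv in enumerate(plan.levels)}
    metric_rows: list[dict] = []
    size_rows: list[dict] = []
    provenance: list[dict] = []
    selected_sets: dict[tuple[str, float], list[set]] = {}

    for perm in perms:
        li, ri = level_index[perm.level], perm.repetition
        provenance.append(
            {
                "level": perm.level, "repetition": ri, "seed": perm.seed,
                "flipped_pos_ids": list(perm.flipped_pos_ids),
                "flipped_neg_ids": list(perm.flipped_neg_ids),
            }
        )
        for si, selector in enumerate(config.selectors):
            # seeds vary by (level, selector, classifier) only: the sole
            # difference between repetitions is the flip draw itself, so
            # level-0 repetitions are exactly identical
            try:
                selection = run_selector(
                    selector, train_table, perm.labels,
                    alpha=config.alpha, n_target=config.n_target,
                    seed=derive_seed(config.seed, _KEY_SELECT, li, si),
                )
            except Exception:
                log.exception("selector %s failed at level=%s rep=%d", selector, perm.level, ri)
                if config.permissive:
                    continue
                raise
            selected_sets.setdefault((selector, perm.level), []).append(set(selection.selected))
            size_rows.append(
                {
                    "selector": selector, "level": perm.level, "repetition": ri,
                    "n_selected": len(selection.selected),
                    "prop_selected": len(selection.selected) / train_table.p,
                    "fallback_used": selection.fallback_used,
                }
            )
            if config.selection_in_cv:
                sel_seed = derive_seed(config.seed, _KEY_SELECT, li, si)

                def selector_fn(fold_table, fold_labels, fold,
                                _name=selector, _seed=sel_seed):
                    return run_selector(
                        _name, fold_table, fold_labels,
                        alpha=config.alpha, n_target=config.n_target,
                        seed=derive_seed(_seed, fold),
                    )
            else:
                selector_fn = None
            for ci, classifier in enumerate(config.classifiers):
                spec = PipelineSpec(
                    selector=selector, classifier=classifier, cv_folds=cv_folds,
                    seed=derive_seed(config.seed, _KEY_CLASSIFY, li, si, ci),
                )
                try:
                    pred = crossval_train(
                        train_table, perm, selection, spec,
                        rf_n_estimators=config.rf_n_estimators,
                        selector_fn=selector_fn,
                    )
                    holdout = predict_holdout(pred, test_table)
                except Exception:
                    log.exception("pipeline %s failed at level=%s rep=%d",
                                  spec.name, perm.level, ri)
                    if config.permissive:
                        continue
                    raise
                surfaces = [
                    ("train_vs_permuted", pred.oof_scores, perm.labels),
                    ("train_vs_true", pred.oof_scores, train_ref.labels),
                    ("holdout_vs_true", holdout, test_ref.labels),
                ]
                for surface, scores, labels in surfaces:
                    rec = metrics_from_scores(
                        spec.name, perm.level, ri, surface, scores, labels,
                        cutoff=config.cutoff,
                    )
                    metric_rows.append(asdict(rec))

    metrics = pd.DataFrame(metric_rows)
    selection_sizes = pd.DataFrame(size_rows)

    jsc_rows = []
    if config.repetitions >= 2:
        for (selector, level), sets in sorted(selected_sets.items()):
            if len(sets) >= 2:
                jsc_rows.append(
                    {"selector": selector, "level": level,
                     "jsc": jaccard_multi(sets), "n_sets": len(sets)}
                )
    jsc = pd.DataFrame(jsc_rows)

    comparison_frames = []
    if len(config.levels) >= 2 and config.repetitions >= 2 and not metrics.empty:
        for (pipeline, surface), grp in metrics.groupby(["pipeline", "surface"]):
            for metric in ("auc", "accuracy"):
                cmp = compare_levels(grp, metric=metric, pipeline=pipeline, surface=surface)
                comparison_frames.append(comparison_to_frame(cmp))
    comparisons = (
        pd.concat(comparison_frames, ignore_index=True)
        if comparison_frames
        else pd.DataFrame()
    )

    manifest = {
        "refnoise_version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "dataset": dataset_info,
        "n_train": train_table.n,
        "n_test": test_table.n,
        "train_prevalence": float(train_ref.prevalence),
        "cv_folds": cv_folds,
        "versions": _library_versions(),
    }
    result = ExperimentResult(
        metrics=metrics, jsc=jsc, selection_sizes=selection_sizes,
        comparisons=comparisons, manifest=manifest,
        train_ids=split.train_ids, test_ids=split.test_ids,
        provenance=provenance,
    )
    if config.out_dir:
        write_result(result, config.out_dir)
    return result


def _library_versions() -> dict[str, str]:
    import pandas
    import scipy
    import sklearn

    return {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pandas.__version__,
        "scikit-learn": sklearn.__version__,
    }


def summarize(result: ExperimentResult) -> dict[str, pd.DataFrame]:
    """Per-level summary tables: metric mean/SD/min/max and selection behaviour."""
    out: dict[str, pd.DataFrame] = {}
    if not result.metrics.empty:
        long = result.metrics.melt(
            id_vars=["pipeline", "surface", "level", "repetition"],
            value_vars=["auc", "accuracy", "sensitivity", "specificity"],
            var_name="metric",
        )
        out["metrics"] = (
            long.groupby(["pipeline", "surface", "level", "metric"])["value"]
            .agg(["mean", "std", "min", "max"])
            .reset_index()
        )
    if not result.selection_sizes.empty:
        sel = (
            result.selection_sizes.groupby(["selector", "level"])
            .agg(
                prop_selected=("prop_selected", "mean"),
                n_selected=("n_selected", "mean"),
                fallback_rate=("fallback_used", "mean"),
            )
            .reset_index()
        )
        if not result.jsc.empty:
            sel = sel.merge(result.jsc, on=["selector", "level"], how="left")
        out["selection"] = sel
    return out


def write_result(result: ExperimentResult, out_dir) -> dict[str, Path]:
    """Write all tidy tables, the manifest, and permutation provenance."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in [
        ("metrics", result.metrics),
        ("jsc", result.jsc),
        ("selection", result.selection_sizes),
        ("comparisons", result.comparisons),
    ]:
        paths[name] = out / f"{name}.csv"
        df.to_csv(paths[name], index=False)
    for name, df in summarize(result).items():
        paths[f"summary_{name}"] = out / f"summary_{name}.csv"
        df.to_csv(paths[f"summary_{name}"], index=False)
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
    paths["split"] = out / "split.csv"
    pd.DataFrame(
        {
            "sample_id": list(result.train_ids) + list(result.test_ids),
            "partition": ["train"] * len(result.train_ids) + ["test"] * len(result.test_ids),
        }
    ).to_csv(paths["split"], index=False)
    paths["provenance"] = out / "permutation_provenance.json"
    paths["provenance"].write_text(json.dumps(result.provenance, indent=2))
    return paths


def plot_result(result: ExperimentResult, out_dir) -> list[Path]:
    """PNG panels: metric degradation per surface, JSC and selection size per level."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    if not result.metrics.empty:
        for surface, grp in result.metrics.groupby("surface"):
            fig, ax = plt.subplots(figsize=(7, 4.5))
            for pipeline, g in grp.groupby("pipeline"):
                agg = g.groupby("level")["auc"].agg(["mean", "std"])
                ax.errorbar(agg.index, agg["mean"], yerr=agg["std"].fillna(0),
                            marker="o", capsize=3, label=pipeline)
            ax.set_xlabel("permutation level")
            ax.set_ylabel("AUC")
            ax.set_title(f"AUC vs reference permutation level ({surface})")
            ax.legend(fontsize=7)
            fig.tight_layout()
            path = out / f"auc_{surface}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written.append(path)

    if not result.jsc.empty:
        fig, ax = plt.subplots(figsize=(7, 4.5))
        for selector, g in result.jsc.groupby("selector"):
            g = g.sort_values("level")
            ax.plot(g["level"], g["jsc"], marker="o", label=selector)
        ax.set_xlabel("permutation level")
        ax.set_ylabel("JSC")
        ax.set_ylim(-0.02, 1.02)
        ax.set_title("Feature-selection stability across repetitions")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out / "jsc.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    if not result.selection_sizes.empty:
        fig, ax = plt.subplots(figsize=(7, 4.5))
        agg = result.selection_sizes.groupby(["selector", "level"])["prop_selected"].mean()
        for selector in agg.index.get_level_values(0).unique():
            s = agg.loc[selector]
            ax.plot(s.index, s.values, marker="o", label=selector)
        ax.set_xlabel("permutation level")
        ax.set_ylabel("mean proportion of features selected")
        ax.set_title("Selected-feature proportion per permutation level")
        ax.legend(fontsize=8)
        fig.tight_layout()
        path = out / "selection_proportion.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
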