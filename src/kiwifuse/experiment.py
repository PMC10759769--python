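"""End-to-end study orchestration: simulate, extract, fuse, train, report.

``run_experiment`` reproduces the full analysis on a synthetic dataset:
generate labeled fruit, extract the 46 visual and 13 aroma features, build
the requested feature sets (e-nose only, image only, fused), split 2/3-1/3,
reduce with PCA, grid-search an SVM region classifier and SVR regressors for
the physicochemical targets, and collect calibration / cross-validation /
test reports plus the per-region MSR summary and PCA explained-variance
table.  The whole run is deterministic from the experiment seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from kiwifuse.imgfeat import extract_image_features
from kiwifuse.model import (
    SVMConfig,
    fit_pca,
    fuse_features,
    grid_search_svm,
    grid_search_svr,
    split_indices,
)
from kiwifuse.nose import extract_enose_features, region_msr_summary
from kiwifuse.synth import DatasetConfig, RegionLabel, generate_dataset

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "DEFAULT_TARGETS",
    "run_experiment",
    "compare_feature_sets",
]

logger = logging.getLogger("kiwifuse")

#: Region classification plus the ten modeled quality indices (free sugars
#: are generated but not modeled by default).
DEFAULT_TARGETS = ("region", "firmness", "ssc", "ta", "bar", "ph",
                   "vitamin_c", "tp", "tac", "dpph", "frap")

#: Canonical feature-set order, also the tie-break order in rankings.
FEATURE_SET_ORDER = ("enose", "image", "fused")


@dataclass(frozen=True)
class ExperimentConfig:
    """Recipe for one end-to-end run."""

    dataset: DatasetConfig = field(default_factory=DatasetConfig)
    feature_sets: tuple = FEATURE_SET_ORDER
    targets: tuple = DEFAULT_TARGETS
    n_components: int = 4
    folds: int = 10
    seed: int = 0

    def __post_init__(self):
        if not self.feature_sets or not self.targets:
            raise ValueError("need at least one feature set and one target")
        bad = set(self.feature_sets) - set(FEATURE_SET_ORDER)
        if bad:
            raise ValueError(f"unknown feature sets: {sorted(bad)}")


@dataclass
class ExperimentReport:
    """Everything one run produced, JSON-serializable."""

    config: ExperimentConfig
    entries: dict            # (feature_set, target) -> {stage: FitReport}
    hyperparameters: dict    # (feature_set, target) -> (c, gamma)
    msr_summary: pd.DataFrame
    explained_variance: dict  # feature_set -> list of fractions

    def to_dict(self) -> dict:
        cfg = {
            "dataset": {
                "n_per_region": self.config.dataset.n_per_region,
                "seed": self.config.dataset.seed,
                "separation": self.config.dataset.separation,
                "noise_scale": self.config.dataset.noise_scale,
                "image_size": self.config.dataset.image_size,
            },
            "feature_sets": list(self.config.feature_sets),
            "targets": list(self.config.targets),
            "n_components": self.config.n_components,
            "folds": self.config.folds,
            "seed": self.config.seed,
        }
        models = {}
        for (fs, target), stages in sorted(self.entries.items()):
            c, g = self.hyperparameters[(fs, target)]
            models[f"{fs}:{target}"] = {
                "c": c, "gamma": g,
                "stages": {st: rep.as_dict() for st, rep in sorted(stages.items())},
            }
        return {
            "config": cfg,
            "models": models,
            "msr_summary": {r: [float(x) for x in row]
                            for r, row in self.msr_summary.iterrows()},
            "msr_sensors": list(self.msr_summary.columns),
            "explained_variance": {fs: [float(x) for x in ev]
                                   for fs, ev in sorted(self.explained_variance.items())},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def metric(self, feature_set: str, target: str, stage: str) -> float:
        """Accuracy (%) for region, R^2 (%) for regression targets."""
        rep = self.entries[(feature_set, target)][stage]
        return rep.accuracy if target == "region" else rep.r_squared


def _feature_matrices(samples, feature_sets):
    """Extract per-sample feature blocks once, then assemble the sets."""
    need_image = bool({"image", "fused"} & set(feature_sets))
    img_rows, eno_rows = [], []
    t0 = time.perf_counter()
    for s in samples:
        if need_image:
            img_rows.append(extract_image_features(s.whole_image, s.cut_image).values)
        eno_rows.append(extract_enose_features(s.enose))
    logger.info("feature extraction: %d samples in %.1f s",
                len(samples), time.perf_counter() - t0)
    eno_mat = np.vstack([v.values for v in eno_rows])
    out = {"enose": eno_mat}
    if need_image:
        img_mat = np.vstack(img_rows)
        out["image"] = img_mat
        out["fused"] = np.vstack([
            fuse_features(img_mat[i], eno_mat[i]).values
            for i in range(len(samples))])
    return out, eno_rows


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentReport:
    """Run the full pipeline for one configuration.

    If ``out_dir`` is given, ``report.json`` and one CSV per report table
    are written there.
    """
    t_start = time.perf_counter()
    samples = generate_dataset(config.dataset)
    logger.info("generated %d samples (%d per region)", len(samples),
                config.dataset.n_per_region)

    matrices, eno_vectors = _feature_matrices(samples, config.feature_sets)
    labels = np.array([int(s.label) for s in samples])
    cal_idx, test_idx = split_indices(labels, config.seed)

    msr = region_msr_summary(
        [(s.label, v) for s, v in zip(samples, eno_vectors)])

    entries, hyper, explained = {}, {}, {}
    svm_config = SVMConfig()
    for fs in config.feature_sets:
        X = matrices[fs]
        pca = fit_pca(X[cal_idx], n_components=config.n_components)
        explained[fs] = list(pca.explained_variance_ratio)
        S_cal = pca.transform(X[cal_idx])
        S_test = pca.transform(X[test_idx])
        for target in config.targets:
            t0 = time.perf_counter()
            if target == "region":
                res = grid_search_svm(S_cal, labels[cal_idx], svm_config,
                                      folds=config.folds, seed=config.seed,
                                      X_test=S_test, y_test=labels[test_idx])
            else:
                y = np.array([getattr(s.physchem, target) for s in samples])
                res = grid_search_svr(S_cal, y[cal_idx], svm_config,
                                      folds=config.folds, seed=config.seed,
                                      X_test=S_test, y_test=y[test_idx])
            entries[(fs, target)] = res.reports
            hyper[(fs, target)] = (res.best_c, res.best_gamma)
            logger.info("%s:%s fitted in %.1f s (c=%g, gamma=%g)", fs, target,
                        time.perf_counter() - t0, res.best_c, res.best_gamma)

    report = ExperimentReport(config=config, entries=entries,
                              hyperparameters=hyper, msr_summary=msr,
                              explained_variance=explained)
    logger.info("experiment complete in %.1f s", time.perf_counter() - t_start)
    if out_dir is not None:
        from kiwifuse import io as kio
        kio.write_report(report, out_dir)
    return report


def compare_feature_sets(report: ExperimentReport) -> pd.DataFrame:
    """Rank feature sets per target by the validation metric (descending).

    Ties keep the canonical order enose < image < fused.  Requires at least
    two feature sets in the report.
    """
    if len(report.config.feature_sets) < 2:
        raise ValueError("need at least two feature sets to compare")
    rows = []
    for target in report.config.targets:
        present = [fs for fs in FEATURE_SET_ORDER
                   if (fs, target) in report.entries]
        if not present:
            raise ValueError(f"no entries for target {target!r}")
        metrics = {fs: report.metric(fs, target, "validation") for fs in present}
        ranked = sorted(present, key=lambda fs: (-metrics[fs],
                                                 FEATURE_SET_ORDER.index(fs)))
        for rank, fs in enumerate(ranked, start=1):
            rows.append({"target": target, "rank": rank, "feature_set": fs,
                         "validation_metric": metrics[fs]})
    return pd.DataFrame(rows)
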