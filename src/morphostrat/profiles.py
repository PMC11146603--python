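"""Slide-level cluster-proportion profiles and the prognostic classifier.

Each slide is summarized as the probability distribution of its curated
patches over the K morphology clusters — a length-K proportion vector.  A
decision-tree classifier, tuned by grid search under the cohort's
cross-validation protocol, maps these profiles to short/long survivor
classes.  The positive class is the *long* survivor throughout: sensitivity
is confidence in predicting long survivors, specificity in predicting short
survivors.
"""

from __future__ import annotations


import json
from dataclasses import dataclass
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier, export_text

from .cohort import CohortSplit, fold_partitions
from .clustering import kmeans_fit, assign, silhouette_curve, select_k
from .reduction import fit_standardizer, apply_standardizer, fit_pca, project

__all__ = [
    "POSITIVE_CLASS",
    "DTGrid",
    "EvalResult",
    "build_profiles",
    "train_classifier",
    "evaluate",
    "fit_prognostic_pipeline",
    "variance_sweep",
    "PipelineArtifacts",
]

POSITIVE_CLASS = "long"


def build_profiles(patch_labels: pd.DataFrame, K: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-slide cluster proportions from per-patch cluster assignments.

    ``patch_labels`` needs columns patient_id, slide_id, cluster.  Returns
    (profiles, rejected): one profile row per slide keyed by patient, clusters
    absent from a slide filled with 0; slides with zero curated patches are
    reported in ``rejected`` rather than profiled.
    """
    required = {"patient_id", "slide_id", "cluster"}
    if not required.issubset(patch_labels.columns):
        raise ValueError(f"patch labels need columns {sorted(required)}")
    cl = patch_labels["cluster"].to_numpy()
    if len(cl) and (cl.min() < 0 or cl.max() >= K):
        raise ValueError(f"cluster labels must lie in [0, {K})")

    counts = (patch_labels.groupby(["patient_id", "cluster"]).size()
              .unstack(fill_value=0).reindex(columns=range(K), fill_value=0))
    totals = counts.sum(axis=1)
    rejected = pd.DataFrame({"patient_id": totals.index[totals == 0],
                             "reason": "zero_curated_patches"})
    counts = counts[totals > 0]
    profiles = counts.div(counts.sum(axis=1), axis=0)
    profiles.columns = [f"cluster_{j}" for j in range(K)]
    return profiles, rejected


@dataclass(frozen=True)
class DTGrid:
    """Hyperparameter grid for the decision tree: depth, minimum samples per
    leaf, minimum samples to split, and split criterion."""

    max_depth: tuple = (2, 3, 4, 5, None)
    min_samples_leaf: tuple = (1, 2, 5, 10)
    min_samples_split: tuple = (2, 5, 10)
    criterion: tuple = ("gini", "entropy")

    def __post_init__(self) -> None:
        if not (self.max_depth and self.min_samples_leaf
                and self.min_samples_split and self.criterion):
            raise ValueError("grid axes must be non-empty")

    def configs(self):
        for d, leaf, split, crit in product(self.max_depth, self.min_samples_leaf,
                                            self.min_samples_split, self.criterion):
            yield {"max_depth": d, "min_samples_leaf": leaf,
                   "min_samples_split": split, "criterion": crit}


def _tie_key(params: dict) -> tuple:
    # parsimony: shallower depth first (None = unbounded = deepest),
    # then larger min leaf
    depth = params["max_depth"]
    if depth is None or (isinstance(depth, float) and np.isnan(depth)):
        depth = np.inf
    return (depth, -params["min_samples_leaf"])


def train_classifier(profiles: pd.DataFrame, labels: pd.Series,
                     grid: DTGrid | None = None, folds: pd.Series | None = None,
                     n_folds: int = 10, seed: int = 0):
    """Grid-search a decision tree under the fold protocol and refit.

    Each configuration is scored by mean accuracy on the per-fold validation
    partitions; ties break toward shallower trees, then larger leaves.  The
    winning configuration is refit on all provided (experimentation) rows.
    Returns (fitted model, chosen params, cv results table).
    """
    grid = grid or DTGrid()
    ids = profiles.index.to_numpy()
    y = labels.loc[profiles.index].to_numpy()
    if np.unique(y).size < 2:
        raise ValueError("training data must contain both classes")
    if folds is None:
        rng = np.random.default_rng(seed)
        folds = pd.Series(np.arange(len(ids)) % n_folds, index=ids)
        folds = folds.iloc[rng.permutation(len(ids))].set_axis(ids)
    n_folds = int(folds.max()) + 1

    X = profiles.to_numpy()
    results = []
    for params in grid.configs():
        accs = []
        skipped = 0
        for i in range(n_folds):
            parts = fold_partitions(folds, i, n_folds)
            tr = np.isin(ids, parts["train"])
            va = np.isin(ids, parts["val"])
            if np.unique(y[tr]).size < 2 or va.sum() == 0:
                skipped += 1
                continue
            tree = DecisionTreeClassifier(random_state=seed, **params)
            tree.fit(X[tr], y[tr])
            accs.append(float((tree.predict(X[va]) == y[va]).mean()))
        if not accs:
            raise ValueError("all folds degenerate: cannot score the grid")
        results.append({**params, "mean_val_accuracy": float(np.mean(accs)),
                        "folds_scored": len(accs), "folds_skipped": skipped})

    table = pd.DataFrame(results)
    best_score = table["mean_val_accuracy"].max()
    tied = table[table["mean_val_accuracy"] >= best_score - 1e-12]
    best_row = min(tied.to_dict("records"),
                   key=lambda r: _tie_key(r))
    params = {k: best_row[k] for k in
              ("max_depth", "min_samples_leaf", "min_samples_split", "criterion")}
    if params["max_depth"] is not None and np.isnan(params["max_depth"]):
        params["max_depth"] = None
    else:
        params["max_depth"] = (None if params["max_depth"] is None
                               else int(params["max_depth"]))
    params["min_samples_leaf"] = int(params["min_samples_leaf"])
    params["min_samples_split"] = int(params["min_samples_split"])

    model = DecisionTreeClassifier(random_state=seed, **params)
    model.fit(X, y)
    return model, params, table


@dataclass
class EvalResult:
    tp: int
    fp: int
    tn: int
    fn: int
    positive_class: str = POSITIVE_CLASS

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    def to_dict(self) -> dict:
        return {"positive_class": self.positive_class,
                "TP": self.tp, "FP": self.fp, "TN": self.tn, "FN": self.fn,
                "accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity}


def evaluate(model, profiles: pd.DataFrame, labels: pd.Series) -> EvalResult:
    """Confusion counts and derived metrics with long survivor positive."""
    if len(profiles) == 0:
        raise ValueError("evaluation set is empty")
    y = labels.loc[profiles.index].to_numpy()
    pred = model.predict(profiles.to_numpy())
    pos = POSITIVE_CLASS
    return EvalResult(
        tp=int(((pred == pos) & (y == pos)).sum()),
        fp=int(((pred == pos) & (y != pos)).sum()),
        tn=int(((pred != pos) & (y != pos)).sum()),
        fn=int(((pred != pos) & (y == pos)).sum()),
    )


@dataclass
class PipelineArtifacts:
    """Everything fitted on the experimentation set, for leakage auditing."""

    standardizer: object
    pca: object
    kmeans: object
    classifier_params: dict
    classifier_rules: str
    chosen_k: int

    def fingerprint(self) -> bytes:
        return (self.standardizer.to_bytes() + self.pca.to_bytes()
                + self.kmeans.to_bytes()
                + json.dumps(self.classifier_params, sort_keys=True).encode()
                + self.classifier_rules.encode())


def fit_prognostic_pipeline(features, split: CohortSplit,
                            n_components: int | None = None,
                            variance_target: float | None = 0.6,
                            K: int | None = None,
                            k_grid: Sequence[int] = tuple(range(2, 11)),
                            grid: DTGrid | None = None,
                            seed: int = 0):
    """Standardize → PCA → K-means → profiles → decision tree, leakage-free.

    Every statistic is fit on experimentation-set patches/profiles only; the
    hold-out rows are pushed through the fitted transforms exactly once, for
    the final evaluation.  ``K=None`` selects K from the silhouette elbow on
    the experimentation set.  Returns (artifacts, EvalResult, profiles).
    """
    train_ids = set(split.train["patient_id"])
    holdout_ids = set(split.holdout["patient_id"])
    is_train = features.index["patient_id"].isin(train_ids).to_numpy()
    is_hold = features.index["patient_id"].isin(holdout_ids).to_numpy()

    Xtr = features.X[is_train]
    std = fit_standardizer(Xtr)
    Ztr_full = apply_standardizer(std, Xtr)
    pca = fit_pca(Ztr_full, n_components=n_components, variance_target=variance_target)
    Ztr = project(pca, Ztr_full).Z

    if K is None:
        curve = silhouette_curve(Ztr, k_grid, seed=seed)
        K = select_k(curve).chosen_k
    km = kmeans_fit(Ztr, K, seed=seed, n_init=5)

    labels_all = split.train.set_index("patient_id")["label"]
    patch_lab_tr = features.index[is_train][["patient_id", "slide_id"]].copy()
    patch_lab_tr["cluster"] = assign(km, Ztr)
    prof_tr, _ = build_profiles(patch_lab_tr, K)
    prof_tr = prof_tr.loc[[p for p in prof_tr.index if p in train_ids]]

    folds = split.folds.loc[[p for p in split.folds.index if p in prof_tr.index]]
    model, params, _ = train_classifier(prof_tr, labels_all, grid=grid,
                                        folds=folds, seed=seed)
    rules = export_text(model, feature_names=list(prof_tr.columns))
    artifacts = PipelineArtifacts(standardizer=std, pca=pca, kmeans=km,
                                  classifier_params=params,
                                  classifier_rules=rules, chosen_k=K)
    artifacts._classifier = model  # noqa: SLF001 - kept for evaluation

    # hold-out pass: same transforms, fit nothing
    Zh = project(pca, apply_standardizer(std, features.X[is_hold])).Z
    patch_lab_h = features.index[is_hold][["patient_id", "slide_id"]].copy()
    patch_lab_h["cluster"] = assign(km, Zh)
    prof_h, _ = build_profiles(patch_lab_h, K)
    labels_h = split.holdout.set_index("patient_id")["label"]
    result = evaluate(model, prof_h, labels_h)
    return artifacts, result, (prof_tr, prof_h)


def variance_sweep(features, split: CohortSplit,
                   variance_grid: Sequence[float] = (0.35, 0.5, 0.6, 0.7, 0.8, 0.85, 0.9),
                   K: int = 7, grid: DTGrid | None = None, seed: int = 0) -> pd.DataFrame:
    """Hold-out metrics per retained-variance target, shared cohort split.

    One end-to-end run per target; rows ordered by target.
    """
    rows = []
    for target in sorted(variance_grid):
        artifacts, result, _ = fit_prognostic_pipeline(
            features, split, variance_target=target, K=K, grid=grid, seed=seed)
        rows.append({"variance_target": target,
                     "n_components": artifacts.pca.n_components,
                     "accuracy": result.accuracy,
                     "sensitivity": result.sensitivity,
                     "specificity": result.specificity})
    return pd.DataFrame(rows)
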