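"""Reproduction experiments under synthetic study conditions.

Each function sets up the study conditions the method is designed for —
planted Gaussian-mixture cohorts, artifact-bearing synthetic slides,
class-conditional Dirichlet profile cohorts — runs the package end to end on
them, and measures how well the pipeline recovers the planted ground truth.
They are the backbone of the acceptance checks and are reusable for
benchmarking parameter changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clustering import (select_k, silhouette_curve,
                         stability_analysis)
from .cohort import SplitPlan, label_survival, split_cohort
from .curation import CurationConfig, curate
from .profiles import DTGrid, evaluate, fit_prognostic_pipeline, train_classifier
from .reduction import apply_standardizer, fit_pca, fit_standardizer, project
from .synthetic import (MixtureCohortSpec, ProfileCohortSpec, SyntheticSlideSpec,
                        make_mixture_cohort, make_profile_cohort, make_slide)
from .tiling import SlideHandle, extract_patches

__all__ = [
    "reduce_features",
    "planted_k_recovery",
    "planted_stability",
    "curation_truth_eval",
    "classifier_signal_recovery",
    "classifier_null_deviation",
    "leakage_audit",
]


def reduce_features(X: np.ndarray, n_components: int = 10) -> np.ndarray:
    """The pipeline's standardize -> PCA -> project chain on one matrix."""
    std = fit_standardizer(X)
    Z = apply_standardizer(std, X)
    return project(fit_pca(Z, n_components=n_components), Z).Z


def _mixture_reduced(k_true: int, seed: int, n_patients: int = 20,
                     patches_per_patient: int = 100, separation: float = 8.0,
                     n_components: int = 10):
    fm, labels = make_mixture_cohort(MixtureCohortSpec(
        n_patients=n_patients, patches_per_patient=patches_per_patient,
        k_true=k_true, separation=separation, seed=seed))
    return reduce_features(fm.X, n_components), labels


def planted_k_recovery(n_runs: int = 20, k_values: tuple = (3, 4, 5, 6, 7),
                       base_seed: int = 0, k_grid=tuple(range(2, 11))) -> dict:
    """Fraction of runs in which the silhouette-elbow selector returns k_true.

    Runs cycle through ``k_values``; each run draws a fresh 2000-patch
    mixture cohort at separation 8, reduces it with the pipeline's
    standardize+PCA chain, and selects K from the silhouette curve.
    """
    selections = []
    for r in range(n_runs):
        k_true = k_values[r % len(k_values)]
        seed = (base_seed + 1009 * r) % (2 ** 31)
        Z, _ = _mixture_reduced(k_true, seed)
        curve = silhouette_curve(Z, k_grid, seed=seed)
        selections.append((k_true, select_k(curve).chosen_k))
    correct = sum(k == s for k, s in selections)
    return {"recovery_rate": correct / len(selections), "n_runs": n_runs,
            "selections": selections}


def planted_stability(k_values: tuple = (3, 4, 5, 6, 7), n_permutations: int = 50,
                      base_seed: int = 0) -> dict:
    """Mean consecutive-pair Rand index at K = k_true, per planted k_true."""
    per_k = {}
    for k_true in k_values:
        seed = (base_seed + 104729 * k_true) % (2 ** 31)
        Z, _ = _mixture_reduced(k_true, seed)
        res = stability_analysis(Z, [k_true], n_permutations=n_permutations,
                                 base_seed=seed)
        per_k[k_true] = res.mean_ri(k_true)
    return {"per_k": per_k, "mean": float(np.mean(list(per_k.values()))),
            "min": float(min(per_k.values())), "n_permutations": n_permutations}


def _grid_patches_with_purity(slide):
    handle = SlideHandle(slide_id=f"s{slide.spec.seed}", patient_id="p",
                         base_magnification=slide.spec.declared_magnification,
                         _image=slide.image)
    factor = {"20X": 2, "40X": 4}[slide.spec.declared_magnification]
    artifact_kinds = [k for k in slide.truth_masks
                     if k not in ("tissue", "background")]
    out = []
    for patch in extract_patches(handle, None):
        sl = np.s_[patch.row * factor:(patch.row + 256) * factor,
                   patch.col * factor:(patch.col + 256) * factor]
        tissue = float(slide.truth_masks["tissue"][sl].mean())
        # purity within a *single* artifact kind: each curation rule targets
        # one artifact class, so a tile straddling two kinds (e.g. half pen,
        # half glass) is outside every rule's stated scope
        artifact = max((float(slide.truth_masks[k][sl].mean())
                        for k in artifact_kinds), default=0.0)
        out.append((patch, tissue, artifact))
    return out


def curation_truth_eval(base_seed: int = 0, n_slides: int = 2,
                        purity: float = 0.99) -> dict:
    """Curation vs generator truth on compact-artifact slides.

    Measures how many fully tissue tiles are discarded (should be none), the
    discard rate over fully artifactual tiles, and whether raising each
    rule's fraction threshold across a 3-point sweep is monotone
    (non-increasing discards).
    """
    tissue_total = tissue_discarded = 0
    artifact_total = artifact_discarded = 0
    tables = []
    for i in range(n_slides):
        slide = make_slide(SyntheticSlideSpec(
            width_px=4096, height_px=4096, tissue_fraction=0.6,
            artifact_spec=(("pen_mark", 0.08), ("glass_reflection", 0.08),
                           ("blank_background", 0.07)),
            seed=(base_seed + 17 * i) % (2 ** 31), shapes_per_artifact=1))
        tagged = _grid_patches_with_purity(slide)
        patches = [p for p, _, _ in tagged]
        _, report = curate(patches)
        decisions = report.table.set_index("patch_id")["decision"]
        tables.append(report.table)
        for patch, tis, art in tagged:
            discarded = decisions.loc[patch.patch_id] == "discard"
            if tis >= purity:
                tissue_total += 1
                tissue_discarded += discarded
            elif art >= purity:
                artifact_total += 1
                artifact_discarded += discarded

    # threshold monotonicity from the measured per-rule fractions
    fracs = pd.concat(tables, ignore_index=True)
    monotone = True
    base = CurationConfig()
    thresholds = {"frac_rule1": base.rule1_bad_pixel_fraction,
                  "frac_rule2": base.rule2_fraction,
                  "frac_rule3": base.rule3_fraction}
    for axis in thresholds:
        counts = []
        for t in (0.3, 0.6, 0.9):
            cut = dict(thresholds)
            cut[axis] = t
            disc = ((fracs["frac_rule1"] > cut["frac_rule1"])
                    | (fracs["frac_rule2"] > cut["frac_rule2"])
                    | (fracs["frac_rule3"] > cut["frac_rule3"])).sum()
            counts.append(int(disc))
        monotone &= counts[0] >= counts[1] >= counts[2]

    return {"tissue_patches": tissue_total,
            "tissue_discarded": int(tissue_discarded),
            "artifact_patches": artifact_total,
            "artifact_discarded": int(artifact_discarded),
            "artifact_discard_rate": (artifact_discarded / artifact_total
                                      if artifact_total else float("nan")),
            "threshold_monotone": bool(monotone)}


def classifier_signal_recovery(n_seeds: int = 20, n_patients: int = 200,
                               base_seed: int = 0, accuracy_floor: float = 0.85) -> dict:
    """Hold-out accuracy on 5:1 concentration-contrast Dirichlet cohorts.

    Each seed draws a fresh cohort, trains the grid-searched decision tree on
    a stratified 80% experimentation set under the 10-fold protocol, and
    evaluates once on the 20% hold-out.
    """
    accs = []
    for s in range(n_seeds):
        seed = (base_seed + 7907 * s) % (2 ** 31)
        prof, labels = make_profile_cohort(ProfileCohortSpec(
            n_patients=n_patients, seed=seed))
        split = _stratified_split(labels, seed)
        tr, ho = split
        model, _, _ = train_classifier(prof.loc[tr], labels.loc[tr],
                                       n_folds=10, seed=seed)
        accs.append(evaluate(model, prof.loc[ho], labels.loc[ho]).accuracy)
    rate = float(np.mean([a >= accuracy_floor for a in accs]))
    return {"accuracies": accs, "rate_above_floor": rate,
            "mean_accuracy": float(np.mean(accs))}


def classifier_null_deviation(n_seeds: int = 10, n_patients: int = 200,
                              base_seed: int = 0) -> dict:
    """No-signal control: identical class Dirichlets; hold-out accuracy
    should hover at the majority rate."""
    alpha = (2.0,) * 7
    gaps = []
    for s in range(n_seeds):
        seed = (base_seed + 6007 * s) % (2 ** 31)
        prof, labels = make_profile_cohort(ProfileCohortSpec(
            n_patients=n_patients, dirichlet_short=alpha, dirichlet_long=alpha,
            seed=seed))
        tr, ho = _stratified_split(labels, seed)
        model, _, _ = train_classifier(prof.loc[tr], labels.loc[tr],
                                       n_folds=10, seed=seed)
        acc = evaluate(model, prof.loc[ho], labels.loc[ho]).accuracy
        majority = max((labels.loc[ho] == "long").mean(),
                       (labels.loc[ho] == "short").mean())
        gaps.append(acc - majority)
    return {"gaps": gaps, "mean_gap": float(np.mean(gaps)),
            "max_abs_gap": float(np.max(np.abs(gaps)))}


def _stratified_split(labels: pd.Series, seed: int, test_fraction: float = 0.2):
    rng = np.random.default_rng(seed)
    tr, ho = [], []
    for cls in sorted(labels.unique()):
        ids = labels.index[labels == cls].to_numpy()
        ids = ids[rng.permutation(len(ids))]
        n_test = int(round(test_fraction * len(ids)))
        ho.extend(ids[:n_test])
        tr.extend(ids[n_test:])
    return list(tr), list(ho)


def leakage_audit(seed: int = 0) -> bool:
    """Perturb hold-out feature rows; True iff every fitted artifact
    (standardizer, PCA, K-means, classifier) is byte-identical."""
    n, k = 40, 3
    is_short = np.arange(n) % 2 == 0
    W = np.where(is_short[:, None], np.array([0.6, 0.2, 0.2]),
                 np.array([0.2, 0.6, 0.2]))
    fm, _ = make_mixture_cohort(MixtureCohortSpec(
        n_patients=n, patches_per_patient=40, feature_dim=32, k_true=k,
        separation=8.0, mixing_weights=W, seed=seed))
    clinical = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)],
                             "os_days": np.where(is_short, 100.0, 500.0)})
    split = split_cohort(label_survival(clinical), SplitPlan(cv_folds=5, seed=seed))
    grid = DTGrid(max_depth=(2, None), min_samples_leaf=(1, 5),
                  min_samples_split=(2,), criterion=("gini",))
    art1, _, _ = fit_prognostic_pipeline(fm, split, n_components=5,
                                         variance_target=None, K=k,
                                         grid=grid, seed=seed)
    hold = fm.index["patient_id"].isin(set(split.holdout["patient_id"])).to_numpy()
    fm.X[hold] += 41.0
    art2, _, _ = fit_prognostic_pipeline(fm, split, n_components=5,
                                         variance_target=None, K=k,
                                         grid=grid, seed=seed)
    return art1.fingerprint() == art2.fingerprint()
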