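"""Slide profiles, decision-tree training protocol, and evaluation metrics."""

import numpy as np
import pandas as pd
import pytest

from morphostrat.cohort import SplitPlan, label_survival, split_cohort
from morphostrat.profiles import (DTGrid, EvalResult, build_profiles, evaluate,
                                  fit_prognostic_pipeline, train_classifier,
                                  variance_sweep)
from morphostrat.synthetic import (MixtureCohortSpec, ProfileCohortSpec,
                                   make_mixture_cohort, make_profile_cohort)

SMALL_GRID = DTGrid(max_depth=(2, None), min_samples_leaf=(1, 5),
                    min_samples_split=(2,), criterion=("gini",))


def _patch_labels(clusters, patient="P0", slide="S0"):
    return pd.DataFrame({"patient_id": patient, "slide_id": slide,
                         "cluster": clusters})


class TestBuildProfiles:
    def test_single_cluster_slide(self):
        prof, _ = build_profiles(_patch_labels([2] * 5), K=7)
        assert np.allclose(prof.loc["P0"], [0, 0, 1, 0, 0, 0, 0])

    def test_proportions_by_counting(self):
        prof, _ = build_profiles(_patch_labels([0] * 4 + [1] * 6), K=2)
        assert np.allclose(prof.loc["P0"], [0.4, 0.6])

    def test_profiles_sum_to_one(self):
        rng = np.random.default_rng(0)
        labels = pd.concat([_patch_labels(rng.integers(0, 5, 20), f"P{i}", f"S{i}")
                            for i in range(8)])
        prof, _ = build_profiles(labels, K=5)
        assert np.allclose(prof.sum(axis=1), 1.0, atol=1e-12)

    def test_out_of_range_cluster_rejected(self):
        with pytest.raises(ValueError, match="lie in"):
            build_profiles(_patch_labels([0, 7]), K=7)


class TestEvaluate:
    def test_perfect_predictions(self):
        r = EvalResult(tp=10, fp=0, tn=10, fn=0)
        assert r.accuracy == r.sensitivity == r.specificity == 1.0

    def test_all_long_predictor_on_balanced_set(self):
        r = EvalResult(tp=10, fp=10, tn=0, fn=0)
        assert (r.sensitivity, r.specificity, r.accuracy) == (1.0, 0.0, 0.5)

    def test_holdout_confusion_arithmetic(self):
        r = EvalResult(tp=15, fn=3, tn=15, fp=3)
        assert r.accuracy == pytest.approx(30 / 36)
        assert r.sensitivity == pytest.approx(15 / 18)
        assert r.specificity == pytest.approx(15 / 18)

    def test_metric_identities_on_random_confusions(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tp, fp, tn, fn = rng.integers(1, 50, 4)
            r = EvalResult(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
            assert r.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            assert r.sensitivity == pytest.approx(tp / (tp + fn))
            assert r.specificity == pytest.approx(tn / (tn + fp))

    def test_empty_evaluation_set_fails(self):
        prof, labels = make_profile_cohort(ProfileCohortSpec(n_patients=10, seed=0))
        model, _, _ = train_classifier(prof, labels, grid=SMALL_GRID,
                                       n_folds=3, seed=0)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, prof.iloc[:0], labels)


class TestTrainClassifier:
    def test_strong_signal_generalizes(self):
        prof, labels = make_profile_cohort(ProfileCohortSpec(
            n_patients=200, k=4, dirichlet_short=(10, 1, 1, 1),
            dirichlet_long=(1, 10, 1, 1), seed=2))
        model, _, _ = train_classifier(prof.iloc[:100], labels.iloc[:100],
                                       grid=SMALL_GRID, n_folds=5, seed=0)
        res = evaluate(model, prof.iloc[100:], labels.iloc[100:])
        assert res.accuracy >= 0.9

    def test_unbounded_depth_fits_training_perfectly(self):
        prof, labels = make_profile_cohort(ProfileCohortSpec(
            n_patients=80, k=4, dirichlet_short=(10, 1, 1, 1),
            dirichlet_long=(1, 10, 1, 1), seed=3))
        grid = DTGrid(max_depth=(None,), min_samples_leaf=(1,),
                      min_samples_split=(2,), criterion=("gini",))
        model, _, _ = train_classifier(prof, labels, grid=grid, n_folds=4, seed=0)
        assert (model.predict(prof.to_numpy()) == labels.to_numpy()).mean() == 1.0

    def test_deterministic_given_seed(self):
        prof, labels = make_profile_cohort(ProfileCohortSpec(n_patients=60, seed=4))
        _, p1, _ = train_classifier(prof, labels, n_folds=5, seed=7)
        _, p2, _ = train_classifier(prof, labels, n_folds=5, seed=7)
        assert p1 == p2

    def test_single_class_fails(self):
        prof, labels = make_profile_cohort(ProfileCohortSpec(n_patients=20, seed=5))
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(prof, pd.Series("short", index=prof.index),
                             grid=SMALL_GRID, n_folds=4, seed=0)


def _feature_split(n=40, k=3, seed=0):
    """Mixture features whose mixing weights depend on the survival class."""
    is_short = np.arange(n) % 2 == 0
    w_short = np.array([0.6, 0.2, 0.2])
    w_long = np.array([0.2, 0.6, 0.2])
    W = np.where(is_short[:, None], w_short, w_long)
    fm, _ = make_mixture_cohort(MixtureCohortSpec(
        n_patients=n, patches_per_patient=40, feature_dim=32, k_true=k,
        separation=8.0, mixing_weights=W, seed=seed))
    clinical = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)],
                             "os_days": np.where(is_short, 100.0, 500.0)})
    split = split_cohort(label_survival(clinical),
                         SplitPlan(cv_folds=5, seed=seed))
    return fm, split


class TestEndToEndFeaturePipeline:
    def test_leakage_guard_holdout_perturbation(self):
        """Perturbing hold-out feature rows leaves every fitted artifact
        byte-identical."""
        fm, split = _feature_split(seed=1)
        art1, _, _ = fit_prognostic_pipeline(fm, split, n_components=5,
                                             variance_target=None, K=3,
                                             grid=SMALL_GRID, seed=0)
        hold_ids = set(split.holdout["patient_id"])
        mask = fm.index["patient_id"].isin(hold_ids).to_numpy()
        fm.X[mask] += 37.0
        art2, _, _ = fit_prognostic_pipeline(fm, split, n_components=5,
                                             variance_target=None, K=3,
                                             grid=SMALL_GRID, seed=0)
        assert art1.fingerprint() == art2.fingerprint()

    def test_variance_sweep_layout_and_signal(self):
        fm, split = _feature_split(n=60, seed=2)
        tbl = variance_sweep(fm, split, variance_grid=(0.5, 0.35, 0.8), K=3,
                             grid=SMALL_GRID, seed=0)
        assert list(tbl["variance_target"]) == [0.35, 0.5, 0.8]
        assert (tbl["specificity"] >= 0.8).all()

    def test_single_point_sweep(self):
        fm, split = _feature_split(seed=3)
        tbl = variance_sweep(fm, split, variance_grid=(0.6,), K=3,
                             grid=SMALL_GRID, seed=0)
        assert len(tbl) == 1
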