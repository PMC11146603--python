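"""Generator contracts: reproducibility, mask partitions, planted structure."""

import numpy as np
import pytest

from morphostrat.synthetic import (ClinicalTableSpec, MixtureCohortSpec,
                                   ProfileCohortSpec, SyntheticSlideSpec,
                                   make_clinical_table, make_mixture_cohort,
                                   make_profile_cohort, make_slide)
from morphostrat.clustering import kmeans_fit, rand_index


class TestSlideGenerator:
    def test_degenerate_full_tissue(self):
        slide = make_slide(SyntheticSlideSpec(width_px=512, height_px=512,
                                              tissue_fraction=1.0, seed=0))
        assert slide.truth_masks["tissue"].all()

    def test_infeasible_budget_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            SyntheticSlideSpec(width_px=512, height_px=512, tissue_fraction=0.8,
                               artifact_spec=(("pen_mark", 0.3),))

    def test_masks_partition_image(self, artifact_slide):
        total = np.zeros(artifact_slide.image.shape[:2], dtype=int)
        for m in artifact_slide.truth_masks.values():
            total += m
        assert (total == 1).all()

    def test_area_fractions_near_spec(self, artifact_slide):
        masks = artifact_slide.truth_masks
        assert abs(masks["tissue"].mean() - 0.6) <= 0.2 * 0.6
        assert abs(masks["pen_mark"].mean() - 0.1) <= 0.2 * 0.1
        assert abs(masks["glass_reflection"].mean() - 0.1) <= 0.2 * 0.1

    def test_bit_reproducible(self):
        spec = SyntheticSlideSpec(width_px=512, height_px=512, tissue_fraction=0.5,
                                  artifact_spec=(("pen_mark", 0.1),), seed=3)
        a, b = make_slide(spec), make_slide(spec)
        assert np.array_equal(a.image, b.image)
        for k in a.truth_masks:
            assert np.array_equal(a.truth_masks[k], b.truth_masks[k])


class TestMixtureCohort:
    def test_single_component_all_same_label(self):
        _, lab = make_mixture_cohort(MixtureCohortSpec(
            n_patients=3, patches_per_patient=10, feature_dim=8, k_true=1, seed=0))
        assert (lab == 0).all()

    def test_embedding_impossible(self):
        with pytest.raises(ValueError, match="feature_dim"):
            MixtureCohortSpec(n_patients=2, patches_per_patient=5,
                              feature_dim=3, k_true=4)

    def test_separation_zero_components_coincide(self):
        fm, lab = make_mixture_cohort(MixtureCohortSpec(
            n_patients=5, patches_per_patient=50, feature_dim=16, k_true=3,
            separation=0.0, seed=1))
        means = np.array([fm.X[lab == k].mean(axis=0) for k in range(3)])
        # all component means indistinguishable at noise scale
        assert np.abs(means - means.mean(axis=0)).max() < 0.5

    def test_geometry_matches_spec(self):
        spec = MixtureCohortSpec(n_patients=10, patches_per_patient=200,
                                 feature_dim=32, k_true=4, separation=8.0, seed=2)
        fm, lab = make_mixture_cohort(spec)
        centers = np.array([fm.X[lab == k].mean(axis=0) for k in range(4)])
        for i in range(4):
            within = fm.X[lab == i] - centers[i]
            assert abs(within.std() - 1.0) <= 0.1
            for j in range(i + 1, 4):
                d = np.linalg.norm(centers[i] - centers[j])
                assert abs(d - 8.0) <= 0.8

    def test_kmeans_recovers_planted_labels(self):
        fm, lab = make_mixture_cohort(MixtureCohortSpec(
            n_patients=20, patches_per_patient=100, k_true=4, separation=8.0, seed=1))
        model = kmeans_fit(fm.X, 4, seed=0, n_init=5)
        assert rand_index(model.labels_, lab) >= 0.99

    def test_reproducible(self):
        spec = MixtureCohortSpec(n_patients=4, patches_per_patient=20,
                                 feature_dim=16, k_true=3, seed=9)
        (a, la), (b, lb) = make_mixture_cohort(spec), make_mixture_cohort(spec)
        assert np.array_equal(a.X, b.X) and np.array_equal(la, lb)


class TestProfileCohort:
    def test_profiles_sum_to_one(self):
        prof, labels = make_profile_cohort(ProfileCohortSpec(n_patients=50, seed=0))
        assert np.allclose(prof.sum(axis=1), 1.0)
        assert set(labels.unique()) <= {"short", "long"}

    def test_invalid_concentration(self):
        with pytest.raises(ValueError):
            ProfileCohortSpec(k=2, dirichlet_short=(1.0, 0.0),
                              dirichlet_long=(1.0, 1.0))


class TestClinicalTable:
    def test_empty(self):
        assert len(make_clinical_table(ClinicalTableSpec(n=0))) == 0

    def test_point_mass_in_excluded_band(self):
        from morphostrat.cohort import label_survival
        table = make_clinical_table(ClinicalTableSpec(
            n=20, os_days_distribution=("point", (300.0,)), seed=0))
        labeled = label_survival(table)
        assert (labeled.table["label"] == "excluded_middle").all()

    def test_nonnegative_and_reproducible(self):
        spec = ClinicalTableSpec(n=100, os_days_distribution=("lognormal", (5.5, 0.8)),
                                 seed=4)
        a, b = make_clinical_table(spec), make_clinical_table(spec)
        assert (a["os_days"] >= 0).all()
        assert a.equals(b)
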