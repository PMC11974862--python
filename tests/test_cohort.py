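"""Theil-Sen bias correction, BAG records, regional profiles, at-risk
ranking and the statistics dispatch."""

import numpy as np
import pytest

from elastoage.cohort import (BiasModel, cohort_profile, compare_groups,
                              compute_bag, fit_bias, flag_at_risk,
                              leave_cohort_out_refit, predict_disease_bags,
                              regional_refit_and_profile)
from elastoage.evaluation import build_phantom_dataset
from elastoage.synthetic import REGIONS, CohortSpec, build_atlas


def _brute_theilsen(y, x):
    slopes = [(y[j] - y[i]) / (x[j] - x[i])
              for i in range(len(x)) for j in range(i + 1, len(x)) if x[j] != x[i]]
    slope = np.median(slopes)
    return slope, np.median(y - slope * x)


class TestBias:
    def test_identity_fit(self):
        ages = np.array([20.0, 40.0, 60.0, 80.0])
        b = fit_bias(ages, ages)
        assert b.slope == pytest.approx(1.0) and b.intercept == pytest.approx(0.0)

    def test_exact_linear(self):
        ages = np.linspace(20, 80, 7)
        b = fit_bias(0.5 * ages + 10.0, ages)
        assert b.slope == pytest.approx(0.5, abs=1e-12)
        assert b.intercept == pytest.approx(10.0, abs=1e-12)

    def test_outlier_immunity_vs_brute_force(self):
        ages = np.linspace(20, 80, 9)
        preds = 0.8 * ages + 5.0
        preds[4] += 200.0  # one wild outlier
        b = fit_bias(preds, ages)
        slope, intercept = _brute_theilsen(preds, ages)
        assert b.slope == pytest.approx(slope, abs=1e-12)
        assert b.intercept == pytest.approx(intercept, abs=1e-12)
        assert b.slope == pytest.approx(0.8, abs=1e-9)  # unmoved by the outlier

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            fit_bias([1.0, 2.0], [30.0, 40.0])
        with pytest.raises(ValueError):
            fit_bias([1.0, 2.0, 3.0], [30.0, 30.0, 30.0])


class TestBag:
    def test_affine_predictions_zero_bag(self):
        """Bias-correction exactness: affine rules map to exactly zero BAG."""
        ages = np.linspace(25, 75, 11)
        preds = 0.7 * ages + 12.0
        bias = fit_bias(preds, ages)
        bags = compute_bag(preds, ages, bias)
        assert np.max(np.abs(bags["bag"])) < 1e-10
        assert np.allclose(bags["corrected_prediction"], bags["age"], atol=1e-10)

    def test_identity_bias_constant_offset(self):
        ages = np.array([30.0, 50.0, 70.0])
        bags = compute_bag(ages + 5.0, ages, BiasModel(slope=1.0, intercept=0.0))
        assert np.allclose(bags["bag"], 5.0)

    def test_control_median_bag_near_zero_with_noise(self, rng):
        ages = rng.uniform(20, 80, 200)
        preds = 1.1 * ages - 3.0 + rng.normal(0, 2.0, 200)
        bias = fit_bias(preds, ages)
        bags = compute_bag(preds, ages, bias)
        assert abs(np.median(bags["bag"])) < 0.5


class TestLeaveCohortOut:
    def test_training_set_excludes_controls_and_disease(self, disease_ds):
        model, state, (tr, ctrl, dis) = leave_cohort_out_refit(
            disease_ds, "MCI", "pca_gp", "mre", seed=0)
        part = disease_ds.participants
        assert len(tr) == 40 - 8
        assert set(tr) & set(ctrl) == set()
        assert set(tr) & set(dis) == set()
        assert all(part["cohort"].iloc[i] == "healthy" for i in tr)
        assert all(part["control_for"].iloc[i] == "MCI" for i in ctrl)

    def test_refit_deterministic(self, disease_ds):
        from elastoage.models import predict
        from elastoage.evaluation import modality_volumes
        from elastoage.mech import normalize
        out = []
        for _ in range(2):
            model, state, (tr, ctrl, dis) = leave_cohort_out_refit(
                disease_ds, "AD", "pca_gp", "mre", seed=1)
            bags = predict_disease_bags(disease_ds, model, state, ctrl, dis, "mre")
            out.append(bags["bag"].to_numpy())
        assert np.array_equal(out[0], out[1])

    def test_ad_bag_elevated_and_significant(self, disease_ds):
        model, state, (tr, ctrl, dis) = leave_cohort_out_refit(
            disease_ds, "AD", "pca_gp", "mre", seed=0)
        bags = predict_disease_bags(disease_ds, model, state, ctrl, dis, "mre")
        ad = bags.loc[bags.cohort == "AD", "bag"]
        controls = bags.loc[bags.cohort == "control", "bag"]
        assert ad.median() > 0
        rep = compare_groups(ad, controls)
        assert rep.p_value < 0.05


@pytest.fixture(scope="module")
def ad_profiles(disease_ds):
    atlas = build_atlas((24, 24, 24), 2.0, seed=0)
    return regional_refit_and_profile(disease_ds, atlas, "AD", "pca_gp", "mre", seed=0)


class TestRegional:
    def test_profile_ordering_stable(self, ad_profiles):
        assert list(ad_profiles.columns[-12:]) == list(REGIONS)

    def test_ad_profile_peaks_at_thalamus(self, ad_profiles):
        profile = cohort_profile(ad_profiles, "AD")
        assert profile.idxmax() == "thalamus"
        assert profile["thalamus"] > profile.drop("thalamus").max() + 1.0

    def test_control_profile_near_zero(self, ad_profiles):
        profile = cohort_profile(ad_profiles, "control")
        assert np.max(np.abs(profile.to_numpy())) < 2.0

    def test_cohort_profile_midpoint_and_permutation(self, ad_profiles):
        two = ad_profiles[ad_profiles["cohort"] == "AD"].iloc[:2]
        mid = cohort_profile(two, "AD")
        manual = (two[list(REGIONS)].iloc[0] + two[list(REGIONS)].iloc[1]) / 2
        assert np.allclose(mid, manual)
        shuffled = cohort_profile(ad_profiles.sample(frac=1, random_state=0), "AD")
        assert np.allclose(shuffled, cohort_profile(ad_profiles, "AD"))

    def test_empty_cohort_fails(self, ad_profiles):
        with pytest.raises(ValueError):
            cohort_profile(ad_profiles, "parkinson")


class TestAtRisk:
    def test_identical_and_negated_profiles(self, ad_profiles):
        reference = cohort_profile(ad_profiles, "AD")
        controls = ad_profiles[ad_profiles["cohort"] == "control"].copy()
        controls.iloc[0, -12:] = reference.to_numpy()
        controls.iloc[1, -12:] = -reference.to_numpy()
        ranking = flag_at_risk(controls, reference, threshold=0.7)
        top = ranking.iloc[0]
        assert top["participant_id"] == controls.iloc[0]["participant_id"]
        assert top["similarity"] == pytest.approx(1.0)
        assert top["flagged"]
        bottom = ranking.iloc[-1]
        assert bottom["similarity"] == pytest.approx(-1.0)
        assert not bottom["flagged"]

    def test_zero_variance_excluded(self, ad_profiles):
        reference = cohort_profile(ad_profiles, "AD")
        controls = ad_profiles[ad_profiles["cohort"] == "control"].copy()
        controls.iloc[0, -12:] = 0.0
        with pytest.warns(UserWarning, match="zero-variance"):
            ranking = flag_at_risk(controls, reference)
        assert controls.iloc[0]["participant_id"] not in set(ranking["participant_id"])


class TestStatsDispatch:
    def test_identical_groups_not_significant(self, rng):
        a = rng.normal(size=30)
        rep = compare_groups(a, a, paired=False)
        assert rep.p_value > 0.05

    def test_gaussian_groups_use_t_test(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 50)
        b = rng.normal(2, 1, 50)
        rep = compare_groups(a, b)
        assert rep.test_name == "independent t-test"
        assert rep.p_value < 0.05
        rep_p = compare_groups(a, b, paired=True)
        assert rep_p.test_name == "paired t-test"

    def test_heavy_tails_use_nonparametric(self):
        rng = np.random.default_rng(43)
        a = rng.standard_cauchy(50)
        b = rng.standard_cauchy(50) + 5
        rep = compare_groups(a, b)
        assert rep.test_name == "Mann-Whitney U"
        rep_p = compare_groups(a, b, paired=True)
        assert rep_p.test_name == "Wilcoxon signed-rank"

    def test_paired_unequal_lengths_fail(self, rng):
        with pytest.raises(ValueError):
            compare_groups(rng.normal(size=5), rng.normal(size=6), paired=True)
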