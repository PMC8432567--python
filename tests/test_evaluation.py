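import numpy as np
import pytest
from scipy import stats

from orthoplan.datasets import example_cohort
from orthoplan.evaluation import (
    evaluate_case,
    ks_normality,
    landmark_linear_discrepancy,
    occlusal_angular_discrepancy,
    one_way_anova,
    pairwise_bonferroni,
    pearson_correlation,
    summarize_displacements,
)
from orthoplan.geometry import RigidTransform, euler_compose
from orthoplan.io import TOOTH_LANDMARKS, LandmarkSet
from orthoplan.planning import Displacement6
from orthoplan import fixtures as fx


@pytest.fixture()
def tooth_landmarks(rng):
    lm = LandmarkSet.from_mapping(
        {name: rng.normal(size=3) * 25 for name in TOOTH_LANDMARKS})
    return lm


class TestLinearDiscrepancy:
    def test_identical_sets_give_zeros(self, tooth_landmarks):
        table = landmark_linear_discrepancy(tooth_landmarks, tooth_landmarks)
        assert np.allclose(table.to_numpy(), 0)

    def test_uniform_offset(self, tooth_landmarks):
        shifted = tooth_landmarks.transformed(
            RigidTransform(np.eye(3), [1.0, 0.0, 0.0]))
        table = landmark_linear_discrepancy(tooth_landmarks, shifted)
        assert np.allclose(table["dx"], 1.0)
        assert np.allclose(table[["dy", "dz"]], 0.0)
        assert np.allclose(table["rms"], 1.0)

    def test_rms_hand_computation(self, tooth_landmarks):
        shifted = LandmarkSet.from_mapping(dict(tooth_landmarks))
        shifted["right incisor"] = tooth_landmarks["right incisor"] + [0.48, 0.79, 1.03]
        table = landmark_linear_discrepancy(tooth_landmarks, shifted)
        # sqrt(0.2304 + 0.6241 + 1.0609) = sqrt(1.9154)
        assert table.loc["right incisor", "rms"] == pytest.approx(1.3840, abs=1e-4)

    def test_rms_identity_invariant(self, tooth_landmarks, rng):
        noisy = LandmarkSet.from_mapping(
            {k: v + rng.normal(0, 1, 3) for k, v in tooth_landmarks.items()})
        table = landmark_linear_discrepancy(tooth_landmarks, noisy)
        rms2 = table["rms"] ** 2
        comp2 = table["dx"] ** 2 + table["dy"] ** 2 + table["dz"] ** 2
        assert np.allclose(rms2, comp2, atol=1e-9)
        assert (table["rms"] + 1e-12 >=
                table[["abs_dx", "abs_dy", "abs_dz"]].max(axis=1)).all()

    def test_missing_landmark_rejected(self, tooth_landmarks):
        with pytest.raises(KeyError):
            landmark_linear_discrepancy(tooth_landmarks, LandmarkSet())


class TestAngularDiscrepancy:
    @pytest.fixture()
    def occlusal_set(self):
        return LandmarkSet.from_mapping({
            "mesiobuccal cusp right 1st molar": [-25.0, -20.0, 0.0],
            "mesiobuccal cusp left 1st molar": [25.0, -20.0, 0.0],
            "central-incisor midpoint": [0.0, 5.0, 0.0],
        })

    def test_identical_sets_give_zero(self, occlusal_set):
        a = occlusal_angular_discrepancy(occlusal_set, occlusal_set)
        assert a.as_array() == pytest.approx([0, 0, 0], abs=1e-12)

    def test_pure_pitch_recovered(self, occlusal_set):
        rot = euler_compose((1.43, 0, 0))
        rotated = occlusal_set.transformed(RigidTransform(rot, np.zeros(3)))
        a = occlusal_angular_discrepancy(occlusal_set, rotated)
        assert a.as_array() == pytest.approx([1.43, 0, 0], abs=1e-6)

    def test_collinear_landmarks_propagate_error(self, occlusal_set):
        bad = LandmarkSet.from_mapping({
            "mesiobuccal cusp right 1st molar": [-1.0, 0, 0],
            "mesiobuccal cusp left 1st molar": [1.0, 0, 0],
            "central-incisor midpoint": [0.0, 0, 0],
        })
        with pytest.raises(Exception):
            occlusal_angular_discrepancy(bad, bad)


class TestSummarizeDisplacements:
    def test_cohort_signed_means_match_published_summary(self):
        summary = summarize_displacements(example_cohort())
        assert summary.loc["mean"].round(2).tolist() == [
            0.11, 0.37, 0.88, 5.48, 0.70, -0.35]

    def test_cohort_signed_sds_match_published_summary(self):
        summary = summarize_displacements(example_cohort())
        assert summary.loc["sd"].round(2).tolist() == [
            1.40, 1.40, 1.98, 3.18, 2.63, 1.79]

    def test_cohort_absolute_means(self):
        summary = summarize_displacements(example_cohort())
        abs_mean = summary.loc["abs_mean"].round(2)
        assert abs_mean["advance_setback"] == 1.00
        assert abs_mean["impaction_elongation"] == 1.67
        assert abs_mean["roll"] == 2.14
        assert abs_mean["yaw"] == 1.41

    def test_sign_symmetric_column(self):
        summary = summarize_displacements([[1.0], [-1.0]])
        assert summary.loc["mean", 0] == pytest.approx(0.0)
        assert summary.loc["abs_mean", 0] == pytest.approx(1.0)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            summarize_displacements([[1.0, 2.0]])


class TestAnova:
    def test_identical_groups_give_f_zero(self):
        res = one_way_anova([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_group_example(self):
        # SSB = 13.5, SSW = 4, df = (1, 4): F = 13.5 / 1 = 13.5
        res = one_way_anova([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(13.5, abs=1e-9)
        assert res.p_value == pytest.approx(0.0213, abs=2e-4)
        assert res.df == (1, 4)

    def test_two_group_f_equals_t_squared(self, rng):
        a = rng.normal(size=12)
        b = rng.normal(loc=0.5, size=15)
        f = one_way_anova(a, b).statistic
        t = stats.ttest_ind(a, b).statistic
        assert f == pytest.approx(t**2, abs=1e-9)

    def test_degenerate_zero_variance_equal_means(self):
        res = one_way_anova([2.0, 2.0], [2.0, 2.0])
        assert res.statistic == 0.0
        assert res.p_value == 1.0


class TestPearson:
    def test_perfect_positive(self):
        res = pearson_correlation([1, 2, 3, 4], [1, 2, 3, 4])
        assert res.statistic == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = pearson_correlation(x, -2 * x + 3)
        assert res.statistic == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        # cov = 5.5/3, var_x = 5/3, var_y = 8.75/3 -> r = 5.5 / sqrt(43.75)
        res = pearson_correlation([1, 2, 3, 4], [1, 3, 2, 5])
        assert res.statistic == pytest.approx(5.5 / np.sqrt(43.75), abs=1e-9)
        assert res.statistic == pytest.approx(0.8315, abs=1e-4)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])


class TestKSNormality:
    def test_large_normal_sample_passes(self):
        accepted = 0
        for seed in range(100):
            x = np.random.default_rng(seed).normal(size=1000)
            if ks_normality(x).p_value > 0.05:
                accepted += 1
        assert accepted >= 95

    def test_equally_spaced_quantiles_give_small_d(self):
        n = 200
        q = (np.arange(1, n + 1) - 0.5) / n
        x = stats.norm.ppf(q)
        res = ks_normality(x)
        assert res.statistic <= 1 / (2 * n) + 0.01

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            ks_normality(np.ones(10))


class TestPairwisePosthoc:
    def test_bonferroni_scales_p_values(self, rng):
        a, b, c = rng.normal(size=(3, 20))
        table = pairwise_bonferroni(a, b, c)
        assert len(table) == 3
        assert (table["p_bonferroni"] >= table["p_raw"]).all()
        assert (table["p_bonferroni"] <= 1.0).all()


class TestEvaluateCase:
    def test_postop_equal_to_sim_gives_zero_report(self, phantom):
        case = fx.make_postop_case(
            phantom.mesh, phantom.landmarks, phantom.maxilla_indices,
            Displacement6(0, 0, 0, 0, 0, 0))
        report = evaluate_case(phantom.mesh, phantom.landmarks,
                               case.mesh, case.landmarks, case.cranial_indices)
        assert np.allclose(report.linear.to_numpy(), 0, atol=1e-6)
        assert report.angular.as_array() == pytest.approx([0, 0, 0], abs=1e-6)

    def test_recovers_pure_translation_despite_global_pose(self, phantom):
        applied = Displacement6(0.5, -0.8, 1.0, 0, 0, 0)
        pose = RigidTransform(euler_compose((6, -9, 12)), [15, -10, 8])
        case = fx.make_postop_case(
            phantom.mesh, phantom.landmarks, phantom.maxilla_indices,
            applied, global_pose=pose)
        report = evaluate_case(phantom.mesh, phantom.landmarks,
                               case.mesh, case.landmarks, case.cranial_indices)
        assert np.allclose(report.linear["dx"], 0.5, atol=0.02)
        assert np.allclose(report.linear["dy"], -0.8, atol=0.02)
        assert np.allclose(report.linear["dz"], 1.0, atol=0.02)

    def test_report_csv_round_trip(self, phantom, tmp_path):
        case = fx.make_postop_case(
            phantom.mesh, phantom.landmarks, phantom.maxilla_indices,
            Displacement6(0.3, 0.2, -0.1, 0.5, 0.2, -0.4))
        report = evaluate_case(phantom.mesh, phantom.landmarks,
                               case.mesh, case.landmarks, case.cranial_indices)
        path = tmp_path / "report.csv"
        report.to_csv(path)
        text = path.read_text()
        assert "right incisor" in text
        assert "pitch_deg" in text

    def test_empty_mask_rejected(self, phantom):
        with pytest.raises(ValueError):
            evaluate_case(phantom.mesh, phantom.landmarks,
                          phantom.mesh, phantom.landmarks, [])
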