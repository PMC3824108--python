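"""Quadrant classification, ROC sweep, AUCs and the iterative calibration."""

import numpy as np
import pytest
from scipy import stats

import panbalance as pb


def brute_force_step_auc(distances, low_mask):
    """Oracle: P(d_low > d_high) over all pairs, counting ties as concordant
    (the upper-step rectangle convention)."""
    d = np.asarray(distances, dtype=float)
    lo, hi = d[np.asarray(low_mask, bool)], d[~np.asarray(low_mask, bool)]
    pairs = lo[:, None] >= hi[None, :]
    return pairs.mean()


class TestClassify:
    def test_quadrant_fixture(self):
        d = [0.0, 9.0, 0.0, 9.0]
        y = [200.0, 50.0, 50.0, 200.0]
        labels = pb.classify(d, y, critical_distance=4.0, yield_cutoff=128.5)
        assert labels.tolist() == ["TN", "TP", "FN", "FP"]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pb.classify([], [], 1.0, 1.0)


class TestROCCurve:
    def test_hand_fixture_perfect_at_interior_threshold(self):
        curve = pb.roc_curve([1.0, 2.0, 3.0, 4.0], [False, False, True, True])
        i = np.where(curve.thresholds == 2.0)[0][0]
        assert curve.sensitivity[i] == 1.0 and curve.specificity[i] == 1.0

    def test_monotone_operating_points(self):
        rng = np.random.default_rng(0)
        curve = pb.roc_curve(rng.exponential(size=100), rng.random(100) < 0.4)
        assert (np.diff(curve.sensitivity) <= 1e-12).all()
        assert (np.diff(curve.specificity) >= -1e-12).all()

    def test_degenerate_identical_distances(self):
        curve = pb.roc_curve(np.ones(10), np.arange(10) < 4)
        assert (curve.sensitivity + curve.specificity <= 1 + 1e-12).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            pb.roc_curve([1.0, 2.0], [True, True])


class TestYouden:
    def test_perfect_separation(self):
        curve = pb.roc_curve([1, 2, 3, 4], [False, False, True, True])
        t, j = pb.youden_optimal(curve)
        assert t == 2.0 and j == 1.0

    def test_random_labels_give_small_j(self):
        rng = np.random.default_rng(1)
        curve = pb.roc_curve(rng.normal(size=2000), rng.random(2000) < 0.5)
        _, j = pb.youden_optimal(curve)
        assert j < 0.15

    def test_tie_breaks_to_smallest_threshold(self):
        curve = pb.roc_curve([1.0, 2.0], [False, True])
        t, j = pb.youden_optimal(curve)
        assert j == 1.0 and t == 1.0  # t=1.0 ties t just below 2; smaller wins


class TestStepAUC:
    def test_perfect_separation_is_one(self):
        curve = pb.roc_curve([1, 2, 3, 4], [False, False, True, True])
        assert pb.auc_step(curve) == 1.0

    def test_matches_pairwise_oracle(self):
        rng = np.random.default_rng(2)
        d = rng.normal(size=60)
        mask = rng.random(60) < 0.5
        got = pb.auc_step(pb.roc_curve(d, mask))
        np.testing.assert_allclose(got, brute_force_step_auc(d, mask), atol=1e-12)

    def test_four_point_exact_rational(self):
        d = [1.0, 2.0, 3.0, 2.5]
        mask = [False, True, True, False]
        got = pb.auc_step(pb.roc_curve(d, mask))
        np.testing.assert_allclose(got, brute_force_step_auc(d, mask))
        np.testing.assert_allclose(got, 0.75)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=2000)
        curve = pb.roc_curve(d, rng.permutation(2000) < 1000)
        assert abs(pb.auc_step(curve) - 0.5) < 0.03


class TestBinormalAUC:
    def test_symmetric_model_gives_half(self):
        # equal score distributions: sens == 1 - spec, i.e. a = 0, b = 1
        rng = np.random.default_rng(4)
        scores = rng.normal(size=4000)
        curve = pb.roc_curve(scores, np.arange(4000) % 2 == 0)
        auc, lo, hi = pb.auc_binormal(curve)
        assert abs(auc - 0.5) < 0.02 and lo <= auc <= hi

    def test_recovers_known_binormal_auc(self):
        # negatives ~ N(0,1), positives ~ N(1.5,1): a=1.5, b=1,
        # AUC = Phi(1.5/sqrt(2))
        rng = np.random.default_rng(5)
        d = np.concatenate([rng.normal(size=5000), rng.normal(1.5, 1.0, 5000)])
        mask = np.arange(10000) >= 5000
        auc, lo, hi = pb.auc_binormal(pb.roc_curve(d, mask))
        expected = stats.norm.cdf(1.5 / np.sqrt(2))
        assert abs(auc - expected) < 0.02
        assert lo <= auc <= hi

    def test_agrees_with_step_auc_on_smooth_curves(self):
        rng = np.random.default_rng(6)
        d = np.concatenate([rng.normal(size=3000), rng.normal(1.0, 1.0, 3000)])
        mask = np.arange(6000) >= 3000
        curve = pb.roc_curve(d, mask)
        assert abs(pb.auc_binormal(curve)[0] - pb.auc_step(curve)) < 0.05

    def test_degenerate_curve_rejected(self):
        curve = pb.roc_curve([1.0, 2.0], [False, True])  # no interior points
        with pytest.raises(ValueError, match="interior"):
            pb.auc_binormal(curve)


class TestConfusionMetrics:
    def test_all_tn(self):
        m = pb.confusion_metrics(["TN"] * 5)
        assert m["specificity"] == 1.0 and m["accuracy"] == 1.0
        assert np.isnan(m["sensitivity"]) and np.isnan(m["PPV"])

    def test_survey_like_table(self):
        labels = ["TP"] * 143 + ["FP"] * 1 + ["FN"] * 11 + ["TN"] * 20
        m = pb.confusion_metrics(labels)
        np.testing.assert_allclose(m["PPV"], 143 / 144)
        np.testing.assert_allclose(m["NPV"], 20 / 31)
        np.testing.assert_allclose(m["accuracy"], 163 / 175)

    def test_symmetric_table(self):
        labels = ["TP"] * 5 + ["FP"] * 5 + ["FN"] * 5 + ["TN"] * 5
        assert all(v == 0.5 for v in pb.confusion_metrics(labels).values())


class TestClassSumOfSquares:
    def test_equal_means_give_zero(self):
        assert pb.class_sum_of_squares([1.0, 2.0, 1.0, 2.0], [True, True, False, False]) == 0.0

    def test_hand_value(self):
        assert pb.class_sum_of_squares([0.0, 0.0, 10.0, 10.0], [False, False, True, True]) == 100.0

    def test_best_split_of_bimodal_sample_lands_in_the_gap(self):
        rng = np.random.default_rng(7)
        y = np.sort(np.concatenate([rng.normal(0, 0.5, 30), rng.normal(10, 0.5, 30)]))
        best = max(range(1, 60), key=lambda k: pb.class_sum_of_squares(y, np.arange(60) >= k))
        assert best == 30  # the boundary between the two modes

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            pb.class_sum_of_squares([1.0, 2.0], [True, True])


class TestIterateReference:
    def test_tight_cluster_converges_immediately(self):
        rng = np.random.default_rng(8)
        z = np.concatenate([rng.normal(0, 0.3, (40, 3)), rng.normal(4, 0.8, (40, 3))])
        y = np.concatenate([rng.normal(180, 5, 40), rng.normal(80, 5, 40)])
        norms, labels, curve, d, iters, conv = pb.iterate_reference(z, y, 128.5)
        assert conv and iters <= 2
        assert (labels[:40] == "TN").all() and (labels[40:] == "TP").all()

    def test_single_yield_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            pb.iterate_reference(np.random.default_rng(9).normal(size=(10, 2)),
                                 np.full(10, 200.0), 128.5)

    def test_generator_defaults_converge(self):
        _, y, _, bal = pb.generate_tissue(pb.GeneratorConfig(n=175, seed=1))
        norms, labels, curve, d, iters, conv = pb.iterate_reference(bal, y, 128.5)
        assert conv and iters <= 10
        assert (labels == "TN").sum() >= 20
        assert norms.critical_distance is not None and norms.yield_cutoff == 128.5


class TestCalibrate:
    def test_two_cluster_recovery(self):
        rng = np.random.default_rng(10)
        z = np.concatenate([rng.normal(0, 0.3, (50, 3)), rng.normal(4, 0.8, (50, 3))])
        y = np.concatenate([rng.normal(180, 5, 50), rng.normal(80, 5, 50)])
        res = pb.calibrate(z, y, min_tn=20)
        assert 95 < res.yield_cutoff < 170  # lands in the yield gap
        assert res.auc_step > 0.95
        assert (res.labels == "TN").sum() >= 20

    def test_min_tn_larger_than_sample_rejected(self):
        with pytest.raises(ValueError, match="min_tn"):
            pb.calibrate(np.ones((5, 2)), np.arange(5.0), min_tn=10)

    def test_sbp_invariance_end_to_end(self, basis):
        import warnings

        from conftest import random_sbp_codes

        comp, y, _, _ = pb.generate_tissue(pb.GeneratorConfig(n=100, seed=11))
        basis2 = pb.build_basis(
            pb.validate_sbp(random_sbp_codes(12, np.random.default_rng(12)), basis.part_labels)
        )
        results = []
        for b in (basis, basis2):
            z = pb.ilr(comp, b)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # tiny trial references
                results.append(pb.calibrate(z, y, min_tn=15))
        assert results[0].yield_cutoff == results[1].yield_cutoff
        np.testing.assert_allclose(results[0].distances, results[1].distances, atol=1e-8)
        np.testing.assert_allclose(results[0].auc_step, results[1].auc_step, atol=1e-10)
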