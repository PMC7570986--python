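import numpy as np
import pandas as pd
import pytest

from fluorosep import (
    ValidationError,
    cloud_from_points,
    metric_correlations,
    overall_rating,
    qda_sensitivity,
    svm_sensitivity,
    total_sensitivity,
)


def two_clusters(separation, n=5, spread=0.1, seed=0):
    rng = np.random.default_rng(seed)
    a = spread * rng.standard_normal((n, 2))
    b = spread * rng.standard_normal((n, 2)) + [separation, 0.0]
    pts = np.vstack([a, b])
    labels = np.array(["A"] * n + ["B"] * n)
    return cloud_from_points(pts, labels)


class TestTotalSensitivity:
    def test_perfect_separation(self):
        cloud = two_clusters(separation=10.0, spread=0.1)
        ts, membership = total_sensitivity(cloud, threshold=4.0)
        assert ts == 1.0
        assert set(membership.statuses) == {"correct"}

    def test_ambiguous_point_is_multiclass_not_correct(self):
        """A well within D_M <= 4 of two classes counts as potentially
        misclassified, so TS drops to (n-1)/n."""
        a = np.array([[0, 0], [0.5, 0.1], [-0.5, -0.1], [0.1, 0.5], [-0.1, -0.5]])
        b = a + [40.0, 0.0]
        midpoint = np.array([[20.0, 0.0]])  # huge D_M to both: not this one
        # stretch class A with one replicate reaching halfway to B
        a_amb = np.vstack([a[:4], [[20.0, 0.0]]])
        # give both classes enough spread that the shared point is within 4
        a_wide = np.array([[0, 0], [10, 1], [-10, -1], [5, -2], [-5, 2.0]])
        b_wide = a_wide + [8.0, 0.0]
        pts = np.vstack([a_wide, b_wide])
        labels = np.array(["A"] * 5 + ["B"] * 5)
        cloud = cloud_from_points(pts, labels)
        ts, membership = total_sensitivity(cloud, threshold=4.0)
        statuses = membership.statuses.tolist()
        n_multi = statuses.count("multi-class")
        assert n_multi >= 1
        assert ts == pytest.approx((10 - statuses.count("multi-class")
                                    - statuses.count("unowned")
                                    - statuses.count("misassigned")) / 10)
        assert ts < 1.0

    def test_own_replicate_at_center_is_correct_when_unambiguous(self):
        cloud = two_clusters(separation=100.0, spread=0.5, seed=3)
        ts, membership = total_sensitivity(cloud)
        d_own = membership.distances.iloc[0]["A"]
        assert d_own <= 4.0
        assert membership.statuses.iloc[0] == "correct"

    def test_affine_invariance(self):
        """Mahalanobis distances are affine invariants, so TS is unchanged
        under any invertible affine map of the score plane."""
        cloud = two_clusters(separation=3.0, spread=1.0, seed=5)
        ts0, _ = total_sensitivity(cloud)
        rng = np.random.default_rng(6)
        for _ in range(5):
            amat = rng.standard_normal((2, 2))
            while abs(np.linalg.det(amat)) < 0.1:
                amat = rng.standard_normal((2, 2))
            shift = rng.standard_normal(2)
            pts, labels = cloud.labels()
            mapped = cloud_from_points(pts @ amat.T + shift, labels)
            ts1, _ = total_sensitivity(mapped)
            assert ts1 == pytest.approx(ts0)

    def test_leave_one_out_not_higher_than_training(self):
        cloud = two_clusters(separation=4.0, spread=1.0, seed=9, n=8)
        ts_train, _ = total_sensitivity(cloud)
        ts_loo, _ = total_sensitivity(cloud, leave_one_out=True)
        assert ts_loo <= ts_train + 1e-12

    def test_small_class_errors(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [10, 0], [11, 0], [10, 1.0]])
        labels = np.array(["A", "A", "B", "B", "B", "B"])
        cloud = cloud_from_points(pts, labels)
        with pytest.raises(ValidationError, match="'A'"):
            total_sensitivity(cloud)


class TestQdaSensitivity:
    def test_equal_covariance_reduces_to_mahalanobis_rule(self):
        """When both classes share a covariance the QDA log-det terms cancel
        and assignment is by plain Mahalanobis distance."""
        rng = np.random.default_rng(2)
        shape = rng.standard_normal((6, 2))
        shape -= shape.mean(axis=0)
        a = shape
        b = shape + [2.0, 0.5]  # identical sample covariance by construction
        pts = np.vstack([a, b])
        labels = np.array(["A"] * 6 + ["B"] * 6)
        cloud = cloud_from_points(pts, labels)
        sens = qda_sensitivity(cloud)

        cov = np.cov(shape, rowvar=False, ddof=1)
        prec = np.linalg.inv(cov)
        centers = {"A": a.mean(axis=0), "B": b.mean(axis=0)}
        correct = 0
        for p, lab in zip(pts, labels):
            d = {c: (p - m) @ prec @ (p - m) for c, m in centers.items()}
            if min(d, key=d.get) == lab:
                correct += 1
        assert sens == pytest.approx(correct / len(pts))

    def test_mirrored_classes_split_by_axis(self):
        rng = np.random.default_rng(7)
        right = rng.standard_normal((10, 2)) * [1, 2] + [3.0, 0.0]
        left = right * [-1, 1]
        cloud = cloud_from_points(np.vstack([left, right]),
                                  np.array(["L"] * 10 + ["R"] * 10))
        assert qda_sensitivity(cloud) == 1.0

    def test_balanced_identical_classes_at_least_chance(self):
        rng = np.random.default_rng(8)
        pts = rng.standard_normal((30, 2))
        labels = np.array(["A", "B", "C"] * 10)
        cloud = cloud_from_points(pts, labels)
        assert qda_sensitivity(cloud) >= 1 / 3 - 0.15


class TestSvmSensitivity:
    def test_linearly_separable(self):
        cloud = two_clusters(separation=10.0, spread=0.2, seed=1)
        assert svm_sensitivity(cloud, "linear") == 1.0

    def test_identical_classes_near_chance(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((10, 2))
        doubled = np.vstack([pts, pts])
        labels = np.array(["A"] * 10 + ["B"] * 10)
        cloud = cloud_from_points(doubled, labels)
        assert svm_sensitivity(cloud, "linear") == pytest.approx(0.5, abs=0.1)

    def test_xor_pattern_rbf_beats_linear(self):
        rng = np.random.default_rng(4)
        quads = []
        labels = []
        for (sx, sy), lab in [((1, 1), "A"), ((-1, -1), "A"),
                              ((1, -1), "B"), ((-1, 1), "B")]:
            quads.append(rng.standard_normal((8, 2)) * 0.3 + [2 * sx, 2 * sy])
            labels += [lab] * 8
        cloud = cloud_from_points(np.vstack(quads), np.array(labels))
        assert svm_sensitivity(cloud, "rbf") > svm_sensitivity(cloud, "linear")

    def test_unknown_kernel_errors(self):
        cloud = two_clusters(10.0)
        with pytest.raises(ValidationError, match="kernel"):
            svm_sensitivity(cloud, "sigmoid")


class TestMetricCorrelations:
    def _report(self):
        return pd.DataFrame({
            "condition": list("abcd"),
            "crn": [10.0, 8.0, 4.0, 2.0],
            "rp": [1.0, 2.0, 5.0, 9.0],
            "ts_mah": [0.3, 0.5, 0.8, 0.9],
        })

    def test_identical_columns_correlate_perfectly(self):
        rep = self._report()
        rep["rp"] = rep["ts_mah"]
        corr = metric_correlations(rep)
        assert corr.loc["rp", "ts_mah"] == pytest.approx(1.0)

    def test_negated_column(self):
        rep = self._report()
        rep["crn"] = -rep["rp"]
        assert metric_correlations(rep).loc["crn", "rp"] == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        rep = self._report()
        x, y = rep["crn"].to_numpy(), rep["rp"].to_numpy()
        xm, ym = x - x.mean(), y - y.mean()
        expected = float(np.sum(xm * ym)
                         / np.sqrt(np.sum(xm**2) * np.sum(ym**2)))
        assert metric_correlations(rep).loc["crn", "rp"] == pytest.approx(expected)

    def test_zero_variance_column_is_missing(self):
        rep = self._report()
        rep["ts_mah"] = 0.5
        corr = metric_correlations(rep)
        assert np.isnan(corr.loc["ts_mah", "crn"])

    def test_spearman_option(self):
        corr = metric_correlations(self._report(), method="spearman")
        assert corr.loc["crn", "rp"] == pytest.approx(-1.0)  # perfectly anti-ranked

    def test_too_few_conditions(self):
        with pytest.raises(ValidationError):
            metric_correlations(self._report().iloc[:2])


class TestOverallRating:
    def test_unanimous_winner(self):
        rep = pd.DataFrame({
            "condition": ["a", "b", "c"],
            "crn": [2.0, 10.0, 20.0],  # lower better: a best
            "rp": [9.0, 3.0, 1.0],     # higher better: a best
            "ts_mah": [0.9, 0.5, 0.3],
        })
        rated = overall_rating(rep)
        assert rated.iloc[0]["condition"] == "a"
        assert rated.iloc[0]["rating"] == 3.0  # rank 1 on each of 3 metrics

    def test_tie_shares_mean_rank(self):
        rep = pd.DataFrame({"condition": ["a", "b"], "rp": [5.0, 5.0]})
        rated = overall_rating(rep)
        assert set(rated["rank_rp"]) == {1.5}

    def test_three_by_two_places_arithmetic(self):
        # places {A: (1, 2), B: (2, 1), C: (3, 3)} -> ratings {3, 3, 6}
        rep = pd.DataFrame({
            "condition": ["A", "B", "C"],
            "crn": [1.0, 2.0, 3.0],   # lower better: places 1, 2, 3
            "rp": [5.0, 9.0, 1.0],    # higher better: places 2, 1, 3
        })
        rated = overall_rating(rep).set_index("condition")
        assert rated.loc["A", "rating"] == 3.0
        assert rated.loc["B", "rating"] == 3.0
        assert rated.loc["C", "rating"] == 6.0
        assert rated.index[-1] == "C"

    def test_invariant_to_row_and_column_order(self):
        rep = pd.DataFrame({
            "condition": ["a", "b", "c"],
            "crn": [2.0, 10.0, 5.0],
            "rp": [9.0, 3.0, 7.0],
        })
        r1 = overall_rating(rep)
        r2 = overall_rating(rep.iloc[::-1][["rp", "condition", "crn"]])
        pd.testing.assert_series_equal(
            r1.set_index("condition")["rating"],
            r2.set_index("condition")["rating"],
        )

    def test_needs_two_conditions(self):
        with pytest.raises(ValidationError):
            overall_rating(pd.DataFrame({"condition": ["a"], "crn": [1.0]}))
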