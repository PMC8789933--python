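import numpy as np
import pytest
from scipy.stats import chi2
from sklearn.mixture import GaussianMixture

from heartsound import (
    ClassifierModel,
    DataError,
    GaussianComponent,
    ParameterError,
    chi2_inverse,
    classify,
    classify_batch,
    evaluate,
    evaluate_all,
    fit_gmm,
    mahalanobis_sq,
    select_beta,
)
from heartsound.classifier import DEFAULT_BETA_GRID, UNKNOWN

from ._oracles import mahalanobis_sq_literal


class TestChi2Inverse:
    def test_zero_confidence_gives_zero_threshold(self):
        assert chi2_inverse(0.0) == 0.0

    def test_inverse_of_cdf_on_the_sweep_grid(self):
        for beta in DEFAULT_BETA_GRID:
            assert chi2.cdf(chi2_inverse(beta), 3) == pytest.approx(beta, abs=1e-9)

    def test_strictly_increasing_in_confidence(self):
        thresholds = [chi2_inverse(b) for b in DEFAULT_BETA_GRID]
        assert (np.diff(thresholds) > 0).all()

    @pytest.mark.parametrize("beta", [-0.1, 1.0, 1.5])
    def test_out_of_range_rejected(self, beta):
        with pytest.raises(ParameterError):
            chi2_inverse(beta)


class TestMahalanobis:
    def test_zero_at_component_mean(self, bundled_model):
        for comp in bundled_model.components:
            assert mahalanobis_sq(comp.mu, comp) == pytest.approx(0.0, abs=1e-12)

    def test_identity_covariance_is_euclidean(self):
        comp = GaussianComponent(0.5, np.zeros(3), np.eye(3), "x")
        assert mahalanobis_sq([1.0, 2.0, 2.0], comp) == pytest.approx(9.0)

    def test_matches_explicit_three_by_three_inversion(self, bundled_model):
        comp = bundled_model.components[0]  # the MR component
        x = comp.mu + np.array([1.0, 0.0, 0.0])
        expected = mahalanobis_sq_literal(
            x.tolist(), comp.mu.tolist(), comp.sigma.tolist()
        )
        assert mahalanobis_sq(x, comp) == pytest.approx(expected, rel=1e-10)


class TestBundledModel:
    def test_mixing_weights_sum_to_one(self, bundled_model):
        assert round(sum(c.pi for c in bundled_model.components), 4) == 1.0

    def test_thresholds_recomputed_from_confidence_levels(self, bundled_model):
        np.testing.assert_array_equal(
            np.round(bundled_model.mdc, 4),
            [5.6489, 3.2831, 3.4297, 3.2831, 3.4297, 4.5258, 5.6489],
        )

    def test_covariances_symmetric_positive_definite(self, bundled_model):
        for comp in bundled_model.components:
            np.testing.assert_array_equal(comp.sigma, comp.sigma.T)
            assert np.linalg.eigvalsh(comp.sigma).min() > 0

    def test_each_component_mean_classified_as_its_label(self, bundled_model):
        for comp in bundled_model.components:
            assert classify(comp.mu, bundled_model) == comp.label

    def test_distant_point_is_unknown(self, bundled_model):
        assert classify([100.0, 100.0, 100.0], bundled_model) == UNKNOWN

    def test_class_roster(self, bundled_model):
        assert bundled_model.labels == ["MR", "MS", "ASD", "NM", "AS", "AR", "VSD"]

    def test_json_roundtrip_is_bit_exact(self, bundled_model, tmp_path):
        path = tmp_path / "model.json"
        bundled_model.save(path)
        back = ClassifierModel.load(path)
        for a, b in zip(bundled_model.components, back.components):
            assert a.label == b.label and a.pi == b.pi
            np.testing.assert_array_equal(a.mu, b.mu)
            np.testing.assert_array_equal(a.sigma, b.sigma)
        np.testing.assert_array_equal(bundled_model.beta, back.beta)
        np.testing.assert_array_equal(bundled_model.mdc, back.mdc)
        np.testing.assert_array_equal(bundled_model.pca.eigenvectors, back.pca.eigenvectors)


class TestCoverage:
    def test_ellipsoid_coverage_matches_confidence_level(self, bundled_model, rng):
        # chi2(3) calibration at reduced Monte-Carlo size; the acceptance
        # suite repeats this at 100k draws per component.
        for comp, beta, mdc in zip(
            bundled_model.components[:3], bundled_model.beta, bundled_model.mdc
        ):
            draws = rng.multivariate_normal(comp.mu, comp.sigma, size=20_000)
            diff = draws - comp.mu
            d2 = np.einsum("ij,jk,ik->i", diff, np.linalg.inv(comp.sigma), diff)
            assert np.mean(d2 <= mdc) == pytest.approx(beta, abs=0.012)


class TestFitGmm:
    def test_single_component_recovers_standard_normal(self, rng):
        x = rng.standard_normal((10_000, 3))
        (comp,) = fit_gmm(x, k=1, seed=0)
        np.testing.assert_allclose(comp.mu, 0, atol=0.05)
        np.testing.assert_allclose(comp.sigma, np.eye(3) + 0.01 * np.eye(3), atol=0.1)

    def test_two_separated_clusters_recovered_with_labels(self, rng):
        a = rng.multivariate_normal([0, 0, 0], np.eye(3) * 0.2, 300)
        b = rng.multivariate_normal([5, 5, 5], np.eye(3) * 0.2, 300)
        x = np.vstack([a, b])
        labels = np.array(["low"] * 300 + ["high"] * 300)
        comps = fit_gmm(x, k=2, seed=0, labels=labels)
        by_label = {c.label: c for c in comps}
        assert set(by_label) == {"low", "high"}
        np.testing.assert_allclose(by_label["low"].mu, [0, 0, 0], atol=0.2)
        np.testing.assert_allclose(by_label["high"].mu, [5, 5, 5], atol=0.2)

    def test_too_few_samples_rejected(self, rng):
        with pytest.raises(DataError):
            fit_gmm(rng.standard_normal((5, 3)), k=7)

    def test_non_finite_features_rejected(self, rng):
        x = rng.standard_normal((100, 3))
        x[3, 1] = np.nan
        with pytest.raises(DataError):
            fit_gmm(x, k=2)

    def test_em_log_likelihood_monotone(self, rng):
        x = np.vstack(
            [
                rng.multivariate_normal([0, 0, 0], np.eye(3), 400),
                rng.multivariate_normal([4, 0, 0], np.eye(3), 400),
            ]
        )
        gm = GaussianMixture(
            n_components=2, covariance_type="full", reg_covar=0.01,
            max_iter=1, warm_start=True, random_state=0, tol=0.0,
        )
        lls = []
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(60):
                gm.fit(x)
                lls.append(gm.lower_bound_)
        assert (np.diff(lls) >= -1e-8).all()


class TestClassify:
    def _toy_model(self):
        comps = [
            GaussianComponent(0.5, np.zeros(3), np.eye(3), "a"),
            GaussianComponent(0.5, np.array([4.0, 0, 0]), np.eye(3), "b"),
        ]
        beta = [0.9, 0.9]
        mdc = [chi2_inverse(b) for b in beta]
        return ClassifierModel(comps, beta, mdc)

    def test_overlap_resolved_by_normalized_distance(self):
        model = self._toy_model()
        assert classify([1.9, 0, 0], model) == "a"
        assert classify([2.1, 0, 0], model) == "b"

    def test_batch_matches_scalar(self, rng):
        model = self._toy_model()
        x = rng.standard_normal((20, 3))
        batch = classify_batch(x, model)
        assert list(batch) == [classify(row, model) for row in x]


class TestSelectBeta:
    def test_perfectly_separated_classes_choose_largest_ellipsoids(self, rng):
        comps = [
            GaussianComponent(0.5, np.zeros(3), np.eye(3) * 0.1, "a"),
            GaussianComponent(0.5, np.full(3, 50.0), np.eye(3) * 0.1, "b"),
        ]
        model = ClassifierModel(comps, [0.9, 0.9], [chi2_inverse(0.9)] * 2)
        x = np.vstack(
            [
                rng.multivariate_normal(c.mu, c.sigma, 200)
                for c in comps
            ]
        )
        labels = np.array(["a"] * 200 + ["b"] * 200)
        beta, table = select_beta(model, x, labels)
        np.testing.assert_array_equal(beta, [0.97, 0.97])
        assert table.shape == (18, 2)

    def test_selected_levels_come_from_the_grid(self, rng):
        comps = [
            GaussianComponent(0.5, np.zeros(3), np.eye(3), "a"),
            GaussianComponent(0.5, np.array([2.0, 0, 0]), np.eye(3), "b"),
        ]
        model = ClassifierModel(comps, [0.9, 0.9], [chi2_inverse(0.9)] * 2)
        x = np.vstack(
            [rng.multivariate_normal(c.mu, c.sigma, 300) for c in comps]
        )
        labels = np.array(["a"] * 300 + ["b"] * 300)
        beta, _ = select_beta(model, x, labels)
        assert all(any(np.isclose(b, g) for g in DEFAULT_BETA_GRID) for b in beta)

    def test_overlapping_clusters_pick_smaller_ellipsoids(self, rng):
        comps = [
            GaussianComponent(0.5, np.zeros(3), np.eye(3), "a"),
            GaussianComponent(0.5, np.array([1.5, 0, 0]), np.eye(3), "b"),
        ]
        model = ClassifierModel(comps, [0.9, 0.9], [chi2_inverse(0.9)] * 2)
        x = np.vstack(
            [rng.multivariate_normal(c.mu, c.sigma, 500) for c in comps]
        )
        labels = np.array(["a"] * 500 + ["b"] * 500)
        beta, _ = select_beta(model, x, labels)
        assert (beta < 0.97).all()

    def test_missing_class_rejected(self, rng, bundled_model):
        x = rng.standard_normal((30, 3))
        with pytest.raises(DataError):
            select_beta(bundled_model, x, np.array(["MR"] * 30))


class TestEvaluate:
    def test_hand_counted_confusion(self):
        predicted = ["p"] * 9 + ["n"] + ["n"] * 90
        true = ["p"] * 10 + ["n"] * 90
        m = evaluate(predicted, true, "p")
        assert (m.tp, m.fp, m.tn, m.fn) == (9, 0, 90, 1)
        assert m.se == pytest.approx(90.0)
        assert m.sp == pytest.approx(100.0)
        assert m.ca == pytest.approx(99.0)

    def test_perfect_predictions(self):
        labels = ["a", "b", "a", "c"]
        m = evaluate(labels, labels, "a")
        assert m.ca == m.se == m.sp == 100.0

    def test_matches_manual_count_on_random_labels(self, rng):
        classes = np.array(["x", "y", "z"])
        true = classes[rng.integers(0, 3, 200)]
        pred = classes[rng.integers(0, 3, 200)]
        m = evaluate(pred, true, "y")
        tp = sum(1 for p, t in zip(pred, true) if p == "y" and t == "y")
        fp = sum(1 for p, t in zip(pred, true) if p == "y" and t != "y")
        fn = sum(1 for p, t in zip(pred, true) if p != "y" and t == "y")
        tn = 200 - tp - fp - fn
        assert (m.tp, m.fp, m.fn, m.tn) == (tp, fp, fn, tn)
        assert m.ca == pytest.approx(100 * (tp + tn) / 200)

    def test_undefined_sensitivity_raises(self):
        with pytest.raises(DataError):
            evaluate(["a", "b"], ["b", "b"], "a")

    def test_undefined_specificity_raises(self):
        with pytest.raises(DataError):
            evaluate(["a", "a"], ["a", "a"], "a")

    def test_report_table_covers_all_classes(self, rng):
        classes = np.array(["x", "y"])
        true = classes[rng.integers(0, 2, 100)]
        pred = classes[rng.integers(0, 2, 100)]
        report = evaluate_all(pred, true)
        assert list(report.index) == ["x", "y"]
        assert {"TP", "FP", "TN", "FN", "CA", "Se", "Sp"} <= set(report.columns)
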