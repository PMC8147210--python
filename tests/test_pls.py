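"""NIPALS PLSR: oracles, invariants and the experiment report."""

import numpy as np
import pytest

import feedcube as fc
from feedcube.errors import DimensionError, DomainError, SplitError
from feedcube.pls import _nipals


def _random_table(n=24, k=12, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, (n, k))
    direction = rng.uniform(-1, 1, k)
    y = 5.0 + X @ direction + noise * rng.standard_normal(n)
    return X, y


class TestSplit:
    def test_paper_scale_split_sizes(self, spectra_table):
        cal, val = fc.split_cal_val(spectra_table, frac=0.7, seed=1)
        assert (cal.n, val.n) == (140, 60)

    def test_partition_property(self, spectra_table):
        table = spectra_table.take(np.arange(10))
        cal, val = fc.split_cal_val(table, frac=0.5, seed=3)
        assert (cal.n, val.n) == (5, 5)
        assert sorted(cal.sample_ids + val.sample_ids) == sorted(table.sample_ids)
        assert not set(cal.sample_ids) & set(val.sample_ids)

    def test_deterministic_given_seed(self, spectra_table):
        a = fc.split_cal_val(spectra_table, seed=5)[0]
        b = fc.split_cal_val(spectra_table, seed=5)[0]
        assert a.sample_ids == b.sample_ids

    @pytest.mark.parametrize("frac", [0.0, 1.0, 0.01])
    def test_empty_side_rejected(self, spectra_table, frac):
        table = spectra_table.take(np.arange(4))
        with pytest.raises(SplitError):
            fc.split_cal_val(table, frac=frac, seed=0)


class TestFitPLS:
    def test_single_factor_data_fit_exactly_with_one_lv(self):
        """y affine in one spectral direction needs exactly one component."""
        rng = np.random.default_rng(7)
        k = 15
        direction = rng.uniform(-1, 1, k)
        t = rng.uniform(-2, 2, 40)
        X = 0.5 + np.outer(t, direction)
        y = 30.0 + 4.0 * t
        model = fc.fit_pls(X, y, 1)
        np.testing.assert_allclose(fc.predict(model, X), y, atol=1e-8)

    def test_full_rank_beta_matches_least_squares(self):
        """At full latent rank PLS1 collapses to the OLS solution (12x5)."""
        X, y = _random_table(n=12, k=5, seed=11, noise=0.1)
        model = fc.fit_pls(X, y, 5)
        Xc = X - X.mean(axis=0)
        beta_ols = np.linalg.lstsq(Xc, y - y.mean(), rcond=None)[0]
        np.testing.assert_allclose(model.beta, beta_ols, atol=1e-6)

    def test_agrees_with_sklearn_reference(self):
        """Independent cross-check against scikit-learn's PLS at fixed LV."""
        sklearn_pls = pytest.importorskip("sklearn.cross_decomposition")
        X, y = _random_table(n=30, k=20, seed=2, noise=0.5)
        for n_lv in (1, 3, 5):
            model = fc.fit_pls(X, y, n_lv)
            ref = sklearn_pls.PLSRegression(n_components=n_lv, scale=False).fit(X, y)
            np.testing.assert_allclose(
                fc.predict(model, X), ref.predict(X).ravel(), atol=1e-8
            )

    def test_duplicating_rows_leaves_beta_unchanged(self):
        X, y = _random_table(seed=3, noise=0.2)
        m1 = fc.fit_pls(X, y, 4)
        m2 = fc.fit_pls(np.vstack([X, X]), np.concatenate([y, y]), 4)
        np.testing.assert_allclose(m1.beta, m2.beta, atol=1e-10)

    def test_scores_mutually_orthogonal(self):
        X, y = _random_table(seed=5, noise=0.3)
        model = fc.fit_pls(X, y, 6)
        gram = model.x_scores.T @ model.x_scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8 * np.diag(gram).max()

    def test_training_residual_non_increasing_in_lv(self):
        X, y = _random_table(seed=6, noise=0.5)
        errors = []
        for a in range(1, 8):
            model = fc.fit_pls(X, y, a)
            errors.append(np.sum((fc.predict(model, X) - y) ** 2))
        assert all(e1 >= e2 - 1e-10 for e1, e2 in zip(errors, errors[1:]))

    def test_beta_and_score_paths_agree(self):
        """Prediction via scores T q equals intercept + X beta."""
        X, y = _random_table(seed=8, noise=0.4)
        model = fc.fit_pls(X, y, 4)
        via_scores = model.y_mean + model.x_scores @ model.y_loadings
        np.testing.assert_allclose(via_scores, fc.predict(model, X), atol=1e-8)

    def test_nlv_exceeding_rank_bound_rejected(self):
        X, y = _random_table(n=6, k=4)
        with pytest.raises(DomainError):
            fc.fit_pls(X, y, 6)


class TestPredict:
    def test_mean_row_predicts_mean_response(self):
        X, y = _random_table(seed=9, noise=0.2)
        model = fc.fit_pls(X, y, 3)
        assert fc.predict(model, X.mean(axis=0)) == pytest.approx(y.mean(), abs=1e-8)

    def test_prediction_is_affine(self):
        X, y = _random_table(seed=10, noise=0.2)
        model = fc.fit_pls(X, y, 3)
        x1, x2 = X[0], X[1]
        mid = fc.predict(model, (x1 + x2) / 2)
        assert mid == pytest.approx((fc.predict(model, x1) + fc.predict(model, x2)) / 2, abs=1e-10)

    def test_dimension_mismatch_rejected(self):
        X, y = _random_table()
        model = fc.fit_pls(X, y, 2)
        with pytest.raises(DimensionError):
            fc.predict(model, np.zeros(X.shape[1] + 1))


class TestSelectLV:
    def test_single_factor_data_selects_one(self):
        rng = np.random.default_rng(12)
        direction = rng.uniform(-1, 1, 10)
        t = rng.uniform(-2, 2, 30)
        X = 0.5 + np.outer(t, direction)
        y = 30.0 + 4.0 * t
        n_lv, curve, _ = fc.select_lv(X, y, max_lv=5)
        assert n_lv == 1
        assert curve[0] == pytest.approx(0.0, abs=1e-6)

    def test_pure_noise_selects_few_components(self):
        """With no structure, extra components only add variance."""
        chosen = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.uniform(0, 1, (30, 15))
            y = rng.standard_normal(30)
            n_lv, curve, _ = fc.select_lv(X, y, max_lv=8)
            chosen.append(n_lv)
        assert np.mean(chosen) <= 4
        assert min(chosen) <= 2

    def test_loo_predictions_shape_and_curve_consistency(self):
        X, y = _random_table(seed=13, noise=0.3)
        n_lv, curve, preds = fc.select_lv(X, y, max_lv=4)
        assert preds.shape == (len(y), 4)
        np.testing.assert_allclose(
            curve, np.sqrt(np.mean((preds - y[:, None]) ** 2, axis=0)), atol=1e-12
        )
        assert curve[n_lv - 1] == curve.min()


class TestEvaluate:
    def test_perfect_fit(self):
        y = np.array([10.0, 20.0, 30.0])
        r = fc.evaluate(y, y)
        assert r.r2 == 1.0
        assert r.se == 0.0

    def test_null_model_scores_zero(self):
        y = np.array([10.0, 20.0, 30.0])
        r = fc.evaluate(y, np.full(3, y.mean()))
        assert r.r2 == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sums_of_squares(self):
        r = fc.evaluate(np.array([10.0, 20.0, 30.0]), np.array([12.0, 18.0, 32.0]))
        assert r.r2 == pytest.approx(1 - 12 / 200, abs=1e-12)
        assert r.se == pytest.approx(2.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            fc.evaluate(np.full(3, 5.0), np.array([1.0, 2.0, 3.0]))


class TestRunTable1:
    def test_report_structure_and_split(self, spectra_table):
        report, models = fc.run_table1(spectra_table, seed=1, max_lv=10)
        assert len(report) == 8
        assert set(report["method"]) == {"raw", "mean", "max", "range", "msc", "snv", "sg1", "sg2"}
        assert (report["n_cal"] == 140).all() and (report["n_val"] == 60).all()
        assert (report["n_lv"] <= 10).all()

    def test_single_method_single_row(self, spectra_table):
        report, models = fc.run_table1(
            spectra_table, [fc.PreprocessMethod(kind="raw")], seed=1, max_lv=5
        )
        assert list(report["method"]) == ["raw"]
        assert set(models) == {"raw"}

    def test_identical_seeds_identical_report(self, spectra_table):
        methods = [fc.PreprocessMethod(kind="range")]
        a, _ = fc.run_table1(spectra_table, methods, seed=4, max_lv=5)
        b, _ = fc.run_table1(spectra_table, methods, seed=4, max_lv=5)
        assert a.equals(b)

    def test_formatted_report_has_one_line_per_method(self, spectra_table):
        report, _ = fc.run_table1(
            spectra_table, [fc.PreprocessMethod(kind="raw")], seed=1, max_lv=3
        )
        text = fc.format_report(report)
        assert len(text.splitlines()) == 2  # header + one row


class TestModelPersistence:
    def test_json_round_trip_preserves_predictions(self, tmp_path, spectra_table):
        report, models = fc.run_table1(
            spectra_table, [fc.PreprocessMethod(kind="msc")], seed=1, max_lv=5
        )
        model = models["msc"]
        fc.model_to_json(model, tmp_path / "m.json")
        back = fc.model_from_json(tmp_path / "m.json")
        X = spectra_table.X[:5]
        np.testing.assert_allclose(
            fc.predict(back, back.method.apply(X)),
            fc.predict(model, model.method.apply(X)),
            atol=1e-12,
        )
        assert back.method.method.kind == "msc"
        np.testing.assert_allclose(back.method.reference, model.method.reference)


def test_nipals_stops_when_response_exhausted():
    """Exact single-factor data cannot support more than one component."""
    rng = np.random.default_rng(20)
    direction = rng.uniform(-1, 1, 8)
    t = rng.uniform(-2, 2, 20)
    X = 0.5 + np.outer(t, direction)
    y = 30.0 + 4.0 * t
    W, P, T, q, U, xm, ym = _nipals(X, y, 5)
    assert W.shape[1] <= 2  # residual response is numerically zero afterwards
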