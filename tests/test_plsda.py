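"""NIPALS PLS-DA, post-transformation, VIP, LDA, MCC and CV machinery."""

import numpy as np
import pandas as pd
import pytest

from metabocc.plsda import (
    PLSDA,
    PLSError,
    confusion_2x2,
    cross_validate_mcc,
    dummy_code,
    fit_mcc,
    fit_pls,
    lda_fit,
    mcc,
    permutation_test,
    post_transform,
    select_n_components,
    stratified_folds,
    vip,
)


def _labels(n_case, n_control):
    return np.array(["case"] * n_case + ["control"] * n_control)


def _random_fit(rng, n=12, p=8, A=2):
    X = rng.normal(size=(n, p))
    Xs = X - X.mean(axis=0)
    y, _ = dummy_code(_labels(n // 2, n - n // 2))
    return fit_pls(Xs, y, A), Xs, y


class TestNIPALSFit:
    def test_single_perfect_predictor_fits_exactly(self):
        y_raw = np.array([1.0, -1, 1, -1, 1, -1])
        X = y_raw[:, None] * 2.5
        y, _ = dummy_code(np.where(y_raw > 0, "case", "control"))
        model = fit_pls(X - X.mean(0), y, 1)
        assert np.corrcoef(model.fitted_values, y)[0, 1] == pytest.approx(1.0)

    def test_score_orthogonality_and_unit_weights(self, rng):
        model, _, _ = _random_fit(rng, n=14, p=10, A=3)
        G = model.scores.T @ model.scores
        np.testing.assert_allclose(G - np.diag(np.diag(G)), 0.0, atol=1e-8)
        np.testing.assert_allclose((model.weights**2).sum(axis=0), 1.0, atol=1e-12)

    def test_predictions_match_sklearn_reference(self, rng):
        from sklearn.cross_decomposition import PLSRegression

        X = rng.normal(size=(12, 8))
        y, _ = dummy_code(_labels(6, 6))
        Xs = X - X.mean(axis=0)
        for A in (1, 2, 3):
            mine = fit_pls(Xs, y, A)
            ref = PLSRegression(n_components=A, scale=False).fit(Xs, y)
            np.testing.assert_allclose(
                mine.fitted_values, ref.predict(Xs).ravel(), atol=1e-8
            )

    def test_transform_reproduces_training_scores(self, rng):
        model, Xs, _ = _random_fit(rng)
        np.testing.assert_allclose(model.transform(Xs), model.scores, atol=1e-10)

    def test_component_budget_and_class_checks(self, rng):
        X = rng.normal(size=(6, 4))
        y, _ = dummy_code(_labels(3, 3))
        with pytest.raises(PLSError):
            fit_pls(X, y, 6)
        with pytest.raises(PLSError):
            dummy_code(np.array(["case"] * 6))


class TestPostTransformation:
    def test_single_component_is_identity(self, rng):
        model, _, y = _random_fit(rng, A=1)
        pt = post_transform(model, y)
        np.testing.assert_allclose(np.abs(pt.tp), np.abs(model.scores[:, 0]), atol=1e-12)
        assert pt.to.shape[1] == 0

    def test_orthogonal_scores_lose_covariance_with_y(self, rng):
        for _ in range(20):
            model, _, y = _random_fit(rng, n=16, p=12, A=3)
            pt = post_transform(model, y)
            np.testing.assert_allclose(pt.to.T @ y, 0.0, atol=1e-8)

    def test_fitted_values_unchanged(self, rng):
        for _ in range(20):
            model, _, y = _random_fit(rng, n=16, p=12, A=3)
            pt = post_transform(model, y)
            np.testing.assert_allclose(pt.fitted_values, model.fitted_values, atol=1e-10)

    def test_rotation_preserves_total_score_variance(self, rng):
        model, _, y = _random_fit(rng, n=16, p=12, A=3)
        pt = post_transform(model, y)
        total_before = model.scores.var(axis=0, ddof=1).sum()
        total_after = pt.tp.var(ddof=1) + pt.to.var(axis=0, ddof=1).sum()
        assert total_after == pytest.approx(total_before, rel=1e-8)


class TestVIP:
    def test_mean_squared_vip_is_one(self, rng):
        for _ in range(10):
            model, _, _ = _random_fit(rng, n=14, p=9, A=2)
            v = vip(model)
            assert (v**2).mean() == pytest.approx(1.0, abs=1e-10)

    def test_single_feature_model_has_unit_vip(self):
        y_raw = np.array([1.0, -1, 1, -1, 1, -1])
        X = y_raw[:, None] + 0.01 * np.arange(6)[:, None]
        y, _ = dummy_code(np.where(y_raw > 0, "case", "control"))
        model = fit_pls(X - X.mean(0), y, 1)
        assert vip(model)[0] == pytest.approx(1.0)

    def test_informative_feature_attains_max_vip(self, rng):
        wins = 0
        for _ in range(100):
            X = rng.normal(size=(20, 30))
            labels = _labels(10, 10)
            X[:10, 0] += 3.0
            y, _ = dummy_code(labels)
            model = fit_pls(X - X.mean(0), y, 2)
            wins += int(np.argmax(vip(model)) == 0)
        assert wins >= 95


class TestLDA:
    def test_closed_form_boundary_in_2d(self):
        # means (0,0) and (2,0), identity covariance: boundary x = 1
        rng = np.random.default_rng(0)
        s0 = rng.normal(size=(200, 2))
        s1 = rng.normal(size=(200, 2)) + [2.0, 0.0]
        # force exact empirical moments by symmetrizing construction
        scores = np.vstack([s0, s1])
        labels = np.array(["a"] * 200 + ["b"] * 200)
        clf = lda_fit(scores, labels)
        d = clf.decision(np.array([[0.0, 0.0], [2.0, 0.0]]))
        assert d[0] > 0 > d[1]
        # decision flips close to x=1 (empirical boundary near closed form)
        xs = np.linspace(0.5, 1.5, 201)
        dd = clf.decision(np.column_stack([xs, np.zeros_like(xs)]))
        boundary = xs[np.argmin(np.abs(dd))]
        assert boundary == pytest.approx(1.0, abs=0.15)

    def test_separated_scores_classify_perfectly(self):
        scores = np.array([[-2.0], [-1.5], [-1.8], [1.9], [1.4], [2.2]])
        labels = np.array(["case"] * 3 + ["control"] * 3)
        clf = lda_fit(scores, labels)
        assert (clf.predict(scores) == labels).all()

    def test_exact_tie_goes_to_larger_prior_then_lexicographic(self):
        from metabocc.plsda import ScoreLDA

        # identical means, equal priors: every point is an exact tie and
        # the lexicographically first class wins
        flat = ScoreLDA(
            classes=["case", "control"],
            means=np.zeros((2, 1)),
            cov_inv=np.eye(1),
            log_priors=np.array([-1.0, -1.0]),
        )
        assert flat.decision(np.array([[2.0]]))[0] == 0.0
        assert flat.predict(np.array([[2.0]]))[0] == "case"
        # unequal priors with means placed so the discriminants tie exactly
        # at x=0: the larger prior ("control") wins the tie
        tilted = ScoreLDA(
            classes=["case", "control"],
            means=np.array([[0.0], [1.0]]),
            cov_inv=np.eye(1),
            log_priors=np.array([-1.0, -0.5]),
        )
        assert tilted.decision(np.array([[0.0]]))[0] == 0.0
        assert tilted.predict(np.array([[0.0]]))[0] == "control"

    def test_singular_covariance_is_ridge_regularized(self):
        scores = np.column_stack([np.array([-1.0, -1, 1, 1]), np.zeros(4)])
        labels = np.array(["case", "case", "control", "control"])
        with pytest.warns(UserWarning, match="singular"):
            clf = lda_fit(scores, labels)
        assert (clf.predict(scores) == labels).all()


class TestMCC:
    @pytest.mark.parametrize(
        "confusion,expected",
        [
            ([[9, 0], [1, 9]], 81 / 90),
            ([[10, 0], [0, 10]], 1.0),
            ([[5, 5], [5, 5]], 0.0),
            ([[0, 10], [10, 0]], -1.0),
            ([[0, 0], [5, 5]], 0.0),  # zero marginal
        ],
    )
    def test_closed_form_values(self, confusion, expected):
        assert mcc(confusion) == pytest.approx(expected, abs=1e-12)

    def test_invalid_counts_rejected(self):
        with pytest.raises(PLSError):
            mcc([[1.5, 0], [0, 1]])


class TestCrossValidation:
    def test_folds_are_stratified_and_deterministic(self):
        labels = _labels(10, 15)
        f1 = stratified_folds(labels, 5, np.random.default_rng(3))
        f2 = stratified_folds(labels, 5, np.random.default_rng(3))
        assert all((a == b).all() for a, b in zip(f1, f2))
        for fold in f1:
            fold_labels = labels[fold]
            assert (fold_labels == "case").sum() == 2
            assert (fold_labels == "control").sum() == 3

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(PLSError):
            stratified_folds(_labels(3, 10), 5, np.random.default_rng(0))

    def test_strong_separation_gives_perfect_cv_mcc(self, rng):
        X = rng.normal(size=(20, 40)) * 0.3
        X[:10, :3] += 4.0
        report = cross_validate_mcc(X, _labels(10, 10), 2, seed=1)
        assert report.mcc_cv == pytest.approx(1.0)

    def test_null_cv_mcc_centers_at_zero(self):
        rng = np.random.default_rng(9)
        values = []
        for s in range(100):
            X = rng.normal(size=(20, 15))
            values.append(cross_validate_mcc(X, _labels(10, 10), 2, seed=s).mcc_cv)
        assert abs(np.mean(values)) < 0.1

    def test_same_seed_reproduces_folds_and_mcc(self, rng):
        X = rng.normal(size=(20, 10))
        labels = _labels(10, 10)
        r1 = cross_validate_mcc(X, labels, 2, seed=7)
        r2 = cross_validate_mcc(X, labels, 2, seed=7)
        assert r1.mcc_cv == r2.mcc_cv
        assert r1.fold_assignments == r2.fold_assignments

    def test_fit_mcc_exceeds_cv_mcc_on_average(self):
        rng = np.random.default_rng(21)
        fit_vals, cv_vals = [], []
        for s in range(60):
            X = rng.normal(size=(20, 30)) * 1.2
            X[:10, :2] += 1.2
            labels = _labels(10, 10)
            fit_vals.append(fit_mcc(X, labels, 2)[0])
            cv_vals.append(cross_validate_mcc(X, labels, 2, seed=s).mcc_cv)
        assert np.mean(fit_vals) > np.mean(cv_vals)


class TestComponentSelection:
    def test_max_one_component(self, rng):
        X = rng.normal(size=(20, 8))
        assert select_n_components(X, _labels(10, 10), 1, seed=0) == 1

    def test_two_informative_directions_selected(self):
        picks = []
        for s in range(25):
            rng = np.random.default_rng(3000 + s)
            n = 30
            labels = _labels(15, 15)
            # class structure needs two orthogonal directions to separate
            u = np.repeat([1.0, -1.0], 15)
            v = np.tile([1.0, -1.0], 15) * np.repeat([1.0, -1.0], 15)
            X = 0.8 * rng.normal(size=(n, 40))
            X[:, 0] += 1.2 * u + 2.5 * v
            X[:, 1] += 2.5 * v - 1.2 * u
            picks.append(select_n_components(X, labels, 3, seed=s))
        assert np.mean(np.array(picks) >= 2) >= 0.6

    def test_pure_noise_prefers_smallest_on_ties(self, rng):
        X = rng.normal(size=(10, 5))
        labels = _labels(5, 5)
        # all-zero CV MCC across A is a tie: smallest A wins
        a = select_n_components(X, labels, 3, seed=0)
        assert a >= 1  # well-defined
        # explicit tie: duplicate feature space gives identical CV paths
        a2 = select_n_components(np.zeros((10, 3)) + X[:, :1], labels, 2, seed=0)
        assert a2 == 1


class TestPermutationTest:
    def test_p_value_floor_when_observed_beats_all_nulls(self, rng):
        X = rng.normal(size=(20, 10)) * 0.2
        X[:10, 0] += 5.0
        _, p, null = permutation_test(X, _labels(10, 10), 1, "mcc_fit", 100, seed=0)
        obs = fit_mcc(X, _labels(10, 10), 1)[0]
        assert (null < obs).all()
        assert p == pytest.approx(1 / 101)

    def test_p_value_is_one_when_observed_never_wins(self, monkeypatch, rng):
        # constant statistic: every null ties the observed value
        X = rng.normal(size=(12, 6))
        labels = _labels(6, 6)
        _, p, _ = permutation_test(X, labels, 1, "mcc_fit", 50, seed=0)
        obs = fit_mcc(X, labels, 1)[0]
        if obs == 1.0:  # overfit regime: all nulls also reach 1.0
            assert p == pytest.approx(1.0)

    def test_unknown_statistic_rejected(self, rng):
        with pytest.raises(PLSError):
            permutation_test(rng.normal(size=(12, 4)), _labels(6, 6), 1, "accuracy", 10, 0)


class TestModelResultsInterface:
    def test_fit_summary_and_scores_frame(self, clean_dataset):
        _, table, _ = clean_dataset
        logt = pd.DataFrame(np.log(table.study().intensities))
        model = PLSDA(logt, table.groups().to_numpy())
        res = model.fit(n_components=2, seed=0)
        text = res.summary()
        assert "MCC" in text and "latent variables:   2" in text
        sf = res.scores_frame()
        assert {"tp", "to1", "group"} <= set(sf.columns)
        assert res.mcc_fit >= res.mcc_cv - 1e-9

    def test_from_feature_table_roundtrip(self, clean_dataset):
        _, table, _ = clean_dataset
        res = PLSDA.from_feature_table(table).fit(n_components=1, seed=0)
        assert res.vip().shape[0] == table.n_features
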