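"""Calibration, PQN, imputation and scaling behavior."""

import numpy as np
import pandas as pd
import pytest

from metabocc.containers import FeatureTable
from metabocc.preprocess import (
    PreprocessError,
    apply_calibration_filter,
    fit_qc_calibration,
    impute_and_filter,
    pqn_normalize,
    scale,
)
from metabocc.simulate import SimConfig, generate_dataset, generate_qc_dilution_series


def _qc_table(base, dilutions=(1 / 3, 1 / 5, 1 / 7), reps=2, noise=0.0, seed=0):
    cfg = SimConfig(
        n_features=len(base), qc_dilutions=dilutions, n_qc_replicates=reps,
        qc_noise_sd=noise, seed=seed,
    )
    return generate_qc_dilution_series(cfg, np.asarray(base, dtype=float))


class TestQCCalibration:
    def test_noiseless_fit_is_exact(self):
        base = np.array([10.0, 200.0, 3000.0])
        qc = _qc_table(base)
        model = fit_qc_calibration(qc, 0.7)
        np.testing.assert_allclose(model.slope, base, rtol=1e-10)
        np.testing.assert_allclose(model.r_squared, 1.0, atol=1e-10)
        assert model.retained.all()

    def test_constant_feature_not_retained(self):
        base = np.array([10.0, 20.0])
        qc = _qc_table(base)
        qc.intensities.iloc[:, 1] = 5.0  # flat across dilutions
        model = fit_qc_calibration(qc, 0.7)
        assert model.r_squared.iloc[1] == pytest.approx(0.0, abs=1e-12)
        assert not model.retained.iloc[1]
        assert model.retained.iloc[0]

    def test_noisy_slopes_recover_base_profile(self):
        rng = np.random.default_rng(3)
        base = np.exp(rng.normal(8, 1, 200))
        qc = _qc_table(base, reps=5, noise=0.05, seed=3)
        model = fit_qc_calibration(qc, 0.7)
        rel = model.slope.to_numpy() / base - 1.0
        assert (np.abs(rel) < 0.10).mean() >= 0.95
        assert abs(np.median(rel)) < 0.02  # unbiased recovery

    def test_requires_qc_rows_and_two_dilutions(self, clean_dataset):
        _, table, _ = clean_dataset
        with pytest.raises(PreprocessError, match="no QC rows"):
            fit_qc_calibration(table.study())
        qc = _qc_table(np.ones(4), dilutions=(0.5,), reps=4)
        with pytest.raises(PreprocessError, match="single dilution"):
            fit_qc_calibration(qc)

    def test_filter_identity_when_slopes_are_one(self):
        qc = _qc_table(np.ones(3))
        model = fit_qc_calibration(qc, 0.7)
        out = apply_calibration_filter(qc, model)
        pd.testing.assert_frame_equal(out.intensities, qc.intensities)

    def test_corrected_qc_row_equals_dilution(self):
        base = np.array([10.0, 200.0, 3000.0, 7.0])
        qc = _qc_table(base, dilutions=(1 / 3, 1 / 5, 1 / 7), reps=1)
        model = fit_qc_calibration(qc, 0.7)
        out = apply_calibration_filter(qc, model)
        row = out.intensities.loc[out.sample_meta["nominal_dilution"] == 1 / 5].iloc[0]
        np.testing.assert_allclose(row, 0.2, rtol=1e-10)

    def test_zero_retained_features_is_an_error(self):
        qc = _qc_table(np.ones(2))
        qc.intensities.iloc[:, :] = 1.0  # flat: nothing calibrates
        model = fit_qc_calibration(qc, 0.7)
        with pytest.raises(PreprocessError, match="threshold"):
            apply_calibration_filter(qc, model)

    def test_feature_mismatch_rejected(self, clean_dataset):
        qc = _qc_table(np.ones(3))
        model = fit_qc_calibration(qc, 0.7)
        _, table, _ = clean_dataset
        with pytest.raises(PreprocessError, match="different feature set"):
            apply_calibration_filter(table, model)

    def test_retained_set_invariant_to_sample_order(self):
        rng = np.random.default_rng(4)
        base = np.exp(rng.normal(8, 1, 50))
        qc = _qc_table(base, reps=3, noise=0.3, seed=4)
        m1 = fit_qc_calibration(qc, 0.7)
        perm = rng.permutation(qc.intensities.index)
        m2 = fit_qc_calibration(qc.select_samples(perm), 0.7)
        pd.testing.assert_series_equal(m1.retained, m2.retained)


def _study_table(X, groups=None):
    n, p = X.shape
    sample_ids = [f"S{i}" for i in range(n)]
    fids = [f"F{j}" for j in range(p)]
    if groups is None:
        groups = ["case"] * (n // 2) + ["control"] * (n - n // 2)
    return FeatureTable(
        pd.DataFrame(X, index=pd.Index(sample_ids, name="sample_id"),
                     columns=pd.Index(fids, name="feature_id")),
        pd.DataFrame({"mz": np.linspace(100, 200, p), "rt": 1.0, "ion_mode": "NEG"},
                     index=pd.Index(fids, name="feature_id")),
        pd.DataFrame({"group": groups, "sample_type": "study", "nominal_dilution": np.nan},
                     index=pd.Index(sample_ids, name="sample_id")),
    )


class TestPQN:
    def test_exact_multiple_sample_is_rescaled_to_reference(self):
        ref = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.vstack([ref, ref, ref, 2.0 * ref])
        res = pqn_normalize(_study_table(X))
        assert res.quotient_median.iloc[3] == pytest.approx(2.0)
        np.testing.assert_allclose(res.table.intensities.iloc[3], ref, rtol=1e-12)

    def test_identical_samples_pass_through(self):
        X = np.tile([5.0, 6.0, 7.0], (4, 1))
        res = pqn_normalize(_study_table(X))
        np.testing.assert_allclose(res.quotient_median, 1.0)
        np.testing.assert_allclose(res.table.intensities, X)

    def test_idempotence_of_the_fixed_reference_map(self, rng):
        X = np.exp(rng.normal(0, 1, size=(8, 40)))
        once = pqn_normalize(_study_table(X))
        twice = pqn_normalize(once.table, reference=once.reference_profile)
        np.testing.assert_allclose(twice.quotient_median, 1.0, atol=1e-10)
        # re-estimating the reference perturbs quotients only slightly
        re_estimated = pqn_normalize(once.table)
        assert np.abs(re_estimated.quotient_median - 1.0).max() < 0.1

    def test_dilution_factor_recovery(self):
        errs = []
        for s in range(20):
            cfg = SimConfig(
                n_case=10, n_control=10, n_features=600, n_discriminant=0,
                dilution_sd=0.3, missing_rate=0.0, seed=50 + s,
            )
            table, truth = generate_dataset(cfg)
            res = pqn_normalize(table)
            for sid, true in truth.dilution_factors.items():
                errs.append(abs(res.quotient_median[sid] - true) / true)
        assert np.median(errs) < 0.05

    def test_sample_without_shared_features_is_named(self):
        X = np.exp(np.random.default_rng(1).normal(0, 1, size=(4, 5)))
        X[2, :] = np.nan
        with pytest.raises(PreprocessError, match="S2"):
            pqn_normalize(_study_table(X))

    def test_too_few_study_samples_rejected(self):
        with pytest.raises(PreprocessError, match=">= 3"):
            pqn_normalize(_study_table(np.ones((2, 3))))


class TestImputeAndFilter:
    def test_no_missing_is_identity(self):
        X = np.arange(12, dtype=float).reshape(3, 4) + 1.0
        t = _study_table(X)
        out = impute_and_filter(t, 0.5)
        pd.testing.assert_frame_equal(out.intensities, t.intensities)

    def test_fully_missing_feature_removed(self):
        X = np.ones((4, 3))
        X[:, 1] = np.nan
        out = impute_and_filter(_study_table(X), 0.5)
        assert list(out.intensities.columns) == ["F0", "F2"]

    def test_half_minimum_imputation(self):
        X = np.array([[10.0, 1.0], [20.0, 1.0], [np.nan, 1.0], [40.0, 1.0]])
        out = impute_and_filter(_study_table(X), 0.5)
        assert out.intensities.iloc[2, 0] == pytest.approx(5.0)


class TestScaling:
    def test_mean_center_example(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        Xs, _ = scale(X, "mean_center")
        np.testing.assert_allclose(Xs["a"], [-1.0, 0.0, 1.0])

    def test_autoscale_example_uses_ddof1(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        Xs, scaler = scale(X, "autoscale")
        np.testing.assert_allclose(Xs["a"], [-1.0, 0.0, 1.0])
        assert scaler.scale["a"] == pytest.approx(1.0)

    def test_constant_column_flagged_not_divided(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        Xs, scaler = scale(X, "autoscale")
        assert scaler.zero_variance["b"]
        np.testing.assert_allclose(Xs["b"], 0.0)

    def test_round_trip(self, rng):
        X = pd.DataFrame(rng.normal(size=(6, 5)))
        for mode in ("mean_center", "autoscale"):
            Xs, scaler = scale(X, mode)
            np.testing.assert_allclose(scaler.inverse_transform(Xs), X, atol=1e-10)

    def test_unknown_mode_rejected(self):
        with pytest.raises(PreprocessError):
            scale(pd.DataFrame({"a": [1.0, 2.0]}), "pareto")
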