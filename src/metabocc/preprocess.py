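"""Normalization and scaling of feature tables.

Two-stage normalization: (1) per-feature ordinary-least-squares calibration
of QC intensity against nominal dilution fraction — features whose response
is not linear in dilution (low R^2) are discarded, the rest are divided by
their slope (response-factor correction); (2) probabilistic quotient
normalization (PQN) against the median study-sample profile, removing
per-sample multiplicative dilution.  Plus half-minimum imputation with a
missingness filter, and the mean-centering / autoscaling conventions used
by the downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import FeatureTable


class PreprocessError(ValueError):
    pass


# -- QC dilution calibration -------------------------------------------

@dataclass
class CalibrationModel:
    """Per-feature OLS of QC intensity on nominal dilution fraction."""

    slope: pd.Series
    intercept: pd.Series
    r_squared: pd.Series
    retained: pd.Series
    r2_threshold: float

    @property
    def n_retained(self) -> int:
        return int(self.retained.sum())


def fit_qc_calibration(table: FeatureTable, r2_threshold: float = 0.7) -> CalibrationModel:
    """Fit the per-feature dilution calibration on the table's QC rows.

    A feature is retained when it has >= 3 non-missing QC observations and
    the OLS fit of intensity on nominal dilution achieves R^2 >=
    ``r2_threshold``.  Requires QC rows at >= 2 distinct dilutions.
    """
    qc = table.sample_meta["sample_type"] == "QC"
    if not qc.any():
        raise PreprocessError("no QC rows in table: cannot fit calibration")
    d = table.sample_meta.loc[qc, "nominal_dilution"].to_numpy(dtype=float)
    if np.unique(d[np.isfinite(d)]).size < 2:
        raise PreprocessError("QC rows at a single dilution: slope unidentifiable")
    Y = table.intensities.loc[qc.index[qc]].to_numpy(dtype=float)

    n_feat = Y.shape[1]
    slope = np.full(n_feat, np.nan)
    intercept = np.full(n_feat, np.nan)
    r2 = np.full(n_feat, np.nan)
    n_obs = np.isfinite(Y).sum(axis=0)
    for j in range(n_feat):
        ok = np.isfinite(Y[:, j])
        if ok.sum() < 3 or np.unique(d[ok]).size < 2:
            continue
        x, y = d[ok], Y[ok, j]
        xc, yc = x - x.mean(), y - y.mean()
        sxx = xc @ xc
        b = (xc @ yc) / sxx
        a = y.mean() - b * x.mean()
        resid = y - (a + b * x)
        sst = yc @ yc
        slope[j], intercept[j] = b, a
        r2[j] = 1.0 - (resid @ resid) / sst if sst > 0 else 0.0
    idx = table.feature_meta.index
    retained = pd.Series(
        (n_obs >= 3)
        & (np.nan_to_num(r2, nan=-1.0) >= r2_threshold)
        & (np.nan_to_num(slope) > 0),
        index=idx,
    )
    return CalibrationModel(
        slope=pd.Series(slope, index=idx),
        intercept=pd.Series(intercept, index=idx),
        r_squared=pd.Series(r2, index=idx),
        retained=retained,
        r2_threshold=r2_threshold,
    )


def apply_calibration_filter(
    table: FeatureTable, model: CalibrationModel, correct: bool = True
) -> FeatureTable:
    """Restrict to retained features; optionally divide by the slope.

    With ``correct=True`` intensities are divided by the per-feature slope,
    so a corrected QC intensity at dilution d has expectation d.  With
    ``correct=False`` the calibration only filters features.
    """
    if not model.retained.index.equals(table.feature_meta.index):
        raise PreprocessError("calibration model fitted on a different feature set")
    kept = model.retained.index[model.retained]
    if len(kept) == 0:
        raise PreprocessError(
            "calibration retained 0 features: review the R^2 threshold "
            f"({model.r2_threshold}) or the QC design"
        )
    out = table.select_features(kept)
    if correct:
        out = FeatureTable(
            out.intensities / model.slope[kept],
            out.feature_meta,
            out.sample_meta,
        )
    return out


# -- probabilistic quotient normalization ------------------------------

@dataclass
class PQNResult:
    """PQN output: reference profile, per-sample quotient medians, table."""

    table: FeatureTable
    reference_profile: pd.Series
    quotient_median: pd.Series  # the estimated per-sample dilution factor


def pqn_normalize(table: FeatureTable, reference: pd.Series | None = None) -> PQNResult:
    """Divide each sample by the median of its ratios to the reference.

    The reference profile defaults to the feature-wise median over *study*
    samples; passing ``reference`` reuses a previously fitted profile, in
    which case the normalization map is exactly idempotent.  QC and blank
    rows are passed through using the study-sample reference.  Missing
    values and zero-reference features are ignored in the quotient.
    """
    study = table.study_mask
    if int(study.sum()) < 3:
        raise PreprocessError("PQN needs >= 3 study samples")
    X = table.intensities
    if reference is not None:
        ref = reference.reindex(X.columns)
        if ref.isna().any():
            raise PreprocessError("reference profile does not cover all features")
    else:
        ref = X.loc[study[study].index].median(axis=0, skipna=True)
    usable = ref > 0
    if not usable.any():
        raise PreprocessError("reference profile has no positive entries")

    quotients = X.loc[:, usable].div(ref[usable], axis=1)
    qmed = quotients.median(axis=1, skipna=True)
    bad = qmed.index[~(qmed > 0)]
    if len(bad):
        raise PreprocessError(
            f"samples share no non-missing features with the reference: {list(bad)}"
        )
    normalized = X.div(qmed, axis=0)
    out = FeatureTable(normalized, table.feature_meta.copy(), table.sample_meta.copy())
    return PQNResult(table=out, reference_profile=ref, quotient_median=qmed)


# -- missingness filter and imputation ---------------------------------

def impute_and_filter(
    table: FeatureTable, max_missing_fraction: float = 0.5
) -> FeatureTable:
    """Drop features too often missing; half-minimum impute the rest.

    A feature is dropped when missing in more than ``max_missing_fraction``
    of the *study* samples; remaining missing cells (all rows) are set to
    half the feature's minimum observed value.
    """
    if not 0 <= max_missing_fraction < 1:
        raise PreprocessError("max_missing_fraction must lie in [0, 1)")
    study_ids = table.study_mask[table.study_mask].index
    miss_frac = table.intensities.loc[study_ids].isna().mean(axis=0)
    kept = miss_frac.index[miss_frac <= max_missing_fraction]
    if len(kept) == 0:
        warnings.warn("all features removed by the missingness filter")
    out = table.select_features(kept)
    X = out.intensities
    if X.isna().to_numpy().any():
        fill = X.min(axis=0, skipna=True) / 2.0
        X = X.fillna(fill)
    return FeatureTable(X, out.feature_meta, out.sample_meta)


# -- scaling ------------------------------------------------------------

@dataclass
class Scaler:
    """Stored centers/scales so a scaled matrix can be round-tripped."""

    mode: str
    center: pd.Series
    scale: pd.Series
    zero_variance: pd.Series

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X - self.center) / self.scale

    def inverse_transform(self, Xs: pd.DataFrame) -> pd.DataFrame:
        return Xs * self.scale + self.center


def scale(X: pd.DataFrame, mode: str = "mean_center") -> tuple[pd.DataFrame, Scaler]:
    """Mean-center or autoscale columns (sd uses the n-1 denominator).

    Zero-variance columns are left centered (scale 1) and flagged instead
    of dividing by zero.
    """
    if mode not in ("mean_center", "autoscale"):
        raise PreprocessError(f"unknown scaling mode {mode!r}")
    if X.shape[0] < 2:
        raise PreprocessError("scaling needs >= 2 samples")
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    zero_var = sd == 0
    if mode == "mean_center":
        scl = pd.Series(1.0, index=X.columns)
    else:
        scl = sd.where(~zero_var, 1.0)
    scaler = Scaler(mode=mode, center=center, scale=scl, zero_variance=zero_var)
    return scaler.transform(X), scaler
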