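"""PCA-based multivariate sample outlier screening.

Samples are scored against a principal-component model with the two
classical chemometric diagnostics: Hotelling's T^2 (distance within the
model plane, F-distributed control limit) and Q / squared prediction error
(distance off the plane, Jackson-Mudholkar control limit).  A sample is
flagged when either statistic exceeds its limit at confidence gamma.
Outliers are only reported, never removed silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import FeatureTable
from .preprocess import scale as scale_matrix


class OutlierModelError(ValueError):
    pass


@dataclass
class PCAModel:
    loadings: np.ndarray       # features x A, orthonormal columns
    scores: np.ndarray         # samples x A
    eigenvalues: np.ndarray    # retained score variances (n-1 denominator)
    residual_eigenvalues: np.ndarray  # variances beyond the model
    explained_variance_ratio: np.ndarray
    center: np.ndarray
    residual_ss: np.ndarray    # per-sample squared residual norm (Q)
    sample_ids: list

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    @property
    def n_samples(self) -> int:
        return self.scores.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Model-plane reconstruction of the training data."""
        return self.scores @ self.loadings.T + self.center


def fit_pca(matrix: pd.DataFrame | np.ndarray, n_components: int) -> PCAModel:
    """Principal components by SVD of the column-centered matrix.

    Components are ordered by decreasing explained variance with a
    deterministic sign convention: the largest-magnitude loading entry of
    each component is positive.
    """
    X = np.asarray(matrix, dtype=float)
    n, p = X.shape
    max_a = min(n - 1, p)
    if not 1 <= n_components <= max_a:
        raise OutlierModelError(
            f"n_components={n_components} outside [1, min(n-1, p)={max_a}]"
        )
    center = X.mean(axis=0)
    Xc = X - center
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    V = Vt.T
    # deterministic sign: largest |loading| entry positive per component
    flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V = V * flip
    T = Xc @ V
    eig = s**2 / (n - 1)
    total_var = eig.sum()
    A = n_components
    resid = Xc - T[:, :A] @ V[:, :A].T
    sample_ids = list(matrix.index) if isinstance(matrix, pd.DataFrame) else list(range(n))
    return PCAModel(
        loadings=V[:, :A],
        scores=T[:, :A],
        eigenvalues=eig[:A],
        residual_eigenvalues=eig[A:],
        explained_variance_ratio=(eig[:A] / total_var if total_var > 0 else eig[:A]),
        center=center,
        residual_ss=(resid**2).sum(axis=1),
        sample_ids=sample_ids,
    )


def components_for_variance(matrix, min_explained: float = 0.8) -> int:
    """Smallest component count whose cumulative explained variance
    reaches ``min_explained`` (the default model-size rule)."""
    X = np.asarray(matrix, dtype=float)
    Xc = X - X.mean(axis=0)
    s = np.linalg.svd(Xc, compute_uv=False)
    eig = s**2
    frac = np.cumsum(eig) / eig.sum()
    A = int(np.searchsorted(frac, min_explained) + 1)
    return min(A, min(X.shape[0] - 1, X.shape[1]))


def hotelling_t2(model: PCAModel, gamma: float = 0.95) -> tuple[np.ndarray, float]:
    """Per-sample T^2 and its F-based control limit.

    T^2_i = sum_a t_ia^2 / lambda_a;
    limit = A (n-1)(n+1) / (n (n-A)) * F_gamma(A, n-A).
    """
    n, A = model.n_samples, model.n_components
    if n <= A:
        raise OutlierModelError("need n > A for the T2 limit")
    if np.any(model.eigenvalues <= 0):
        raise OutlierModelError("zero eigenvalue among retained components")
    t2 = ((model.scores**2) / model.eigenvalues).sum(axis=1)
    limit = A * (n - 1) * (n + 1) / (n * (n - A)) * stats.f.ppf(gamma, A, n - A)
    return t2, float(limit)


def spe_q(model: PCAModel, gamma: float = 0.95) -> tuple[np.ndarray, float]:
    """Per-sample squared prediction error and Jackson-Mudholkar limit.

    The limit is computed from the spectral moments theta_k of the
    residual eigenvalues; errors out when the model is full rank (no
    residual subspace, all Q identically 0).
    """
    resid_eig = model.residual_eigenvalues[model.residual_eigenvalues > 1e-12]
    if resid_eig.size == 0:
        raise OutlierModelError("model is full rank: Q limit undefined")
    theta1 = resid_eig.sum()
    theta2 = (resid_eig**2).sum()
    theta3 = (resid_eig**3).sum()
    h0 = 1.0 - 2.0 * theta1 * theta3 / (3.0 * theta2**2)
    if h0 <= 0:
        h0 = 1e-4
    z = stats.norm.ppf(gamma)
    limit = theta1 * (
        z * np.sqrt(2.0 * theta2 * h0**2) / theta1
        + 1.0
        + theta2 * h0 * (h0 - 1.0) / theta1**2
    ) ** (1.0 / h0)
    return model.residual_ss.copy(), float(limit)


@dataclass
class OutlierReport:
    t2: pd.Series
    q: pd.Series
    t2_limit: float
    q_limit: float
    gamma: float
    n_components: int
    flagged: list

    def to_json_dict(self) -> dict:
        return {
            "gamma": self.gamma,
            "n_components": self.n_components,
            "t2_limit": self.t2_limit,
            "q_limit": self.q_limit,
            "t2": self.t2.round(6).to_dict(),
            "q": self.q.round(6).to_dict(),
            "flagged": list(self.flagged),
        }


def detect_outliers(
    table: FeatureTable | pd.DataFrame,
    n_components: int | None = None,
    gamma: float = 0.95,
    scale_mode: str = "mean_center",
) -> OutlierReport:
    """Run both T^2 and Q screens on the (study samples of a) table.

    ``n_components=None`` uses the smallest model covering >= 80% of the
    variance (capped so a residual subspace remains for Q).
    """
    if isinstance(table, FeatureTable):
        X = table.study().intensities
    else:
        X = table
    n = X.shape[0]
    Xs, _ = scale_matrix(X, scale_mode)
    cap = min(n - 2, X.shape[1] - 1)  # keep a residual subspace so Q is defined
    if n_components is None:
        n_components = min(components_for_variance(Xs), cap)
        if n_components < 1:
            raise OutlierModelError("too few samples for outlier screening")
    elif not 1 <= n_components <= cap:
        raise OutlierModelError(
            f"n_components={n_components} leaves no residual subspace "
            f"(needs 1 <= A <= {cap} for n={n})"
        )
    model = fit_pca(Xs, n_components)
    t2, t2_lim = hotelling_t2(model, gamma)
    q, q_lim = spe_q(model, gamma)
    t2_s = pd.Series(t2, index=X.index)
    q_s = pd.Series(q, index=X.index)
    flagged = list(X.index[(t2 > t2_lim) | (q > q_lim)])
    return OutlierReport(
        t2=t2_s,
        q=q_s,
        t2_limit=t2_lim,
        q_limit=q_lim,
        gamma=gamma,
        n_components=n_components,
        flagged=flagged,
    )
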