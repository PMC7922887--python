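"""PLS discriminant analysis with post-transformation and MCC diagnostics.

The discriminant engine: NIPALS partial least squares against an
autoscaled +1/-1 dummy response, class assignment by linear discriminant
analysis on the latent scores, variable influence on projection (VIP) for
predictor ranking, the Matthews correlation coefficient (MCC) in fit and
under stratified 5-fold cross-validation, and permutation tests on the
class response for both statistics.

A fitted model can be *post-transformed*: the score space is rotated so a
single direction (tp) carries all covariance with the response and the
remaining directions (to) carry none, without changing the fitted
predictions — the standard way to display a PLS-DA model with one
predictive and one orthogonal axis.

The module follows the Model/Results convention: build :class:`PLSDA`
from data, call :meth:`PLSDA.fit`, inspect the returned
:class:`PLSDAResults` (``summary()``, ``vip()``, ``post_transformed()``,
``permutation_pvalues()``).  The underlying routines are plain functions
reused by the stability-selection stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import scale as scale_matrix

NIPALS_TOL = 1e-10
NIPALS_MAX_ITER = 500
LDA_RIDGE = 1e-8


class PLSError(ValueError):
    pass


# -- response coding ----------------------------------------------------

def dummy_code(labels) -> tuple[np.ndarray, list]:
    """Two-class labels -> autoscaled +1/-1 dummy column.

    The lexicographically first class gets +1.  Autoscaling (mean 0,
    sd 1 with the n-1 denominator) matches building the model on
    autoscaled dummy variables.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise PLSError(f"need exactly two classes, got {classes}")
    y = np.where(labels == classes[0], 1.0, -1.0)
    y = (y - y.mean()) / y.std(ddof=1)
    return y, classes


# -- NIPALS fit ---------------------------------------------------------

@dataclass
class PLSModel:
    """Fitted PLS model on scaled X and autoscaled dummy y."""

    weights: np.ndarray    # W, features x A, unit-norm columns
    loadings: np.ndarray   # P, features x A
    scores: np.ndarray     # T, samples x A, mutually orthogonal columns
    y_loadings: np.ndarray # q, length A
    ssy: np.ndarray        # per-component explained SS of y

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def fitted_values(self) -> np.ndarray:
        return self.scores @ self.y_loadings

    def transform(self, X_scaled: np.ndarray) -> np.ndarray:
        """Latent scores of new (already scaled) samples."""
        Xd = np.array(X_scaled, dtype=float, copy=True)
        T = np.empty((Xd.shape[0], self.n_components))
        for a in range(self.n_components):
            t = Xd @ self.weights[:, a]
            T[:, a] = t
            Xd -= np.outer(t, self.loadings[:, a])
        return T

    def predict(self, X_scaled: np.ndarray) -> np.ndarray:
        return self.transform(X_scaled) @ self.y_loadings


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSModel:
    """Sequential NIPALS extraction with deflation of X.

    ``X`` must be scaled (mean-centered or autoscaled) and ``y`` an
    autoscaled dummy column.  Deterministic; errors out when
    ``n_components`` exceeds min(n-1, p) or the residual covariance with
    y vanishes (rank exhausted).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise PLSError("X and y sample counts differ")
    A = int(n_components)
    if not 1 <= A <= min(n - 1, p):
        raise PLSError(f"n_components={A} outside [1, min(n-1, p)={min(n - 1, p)}]")
    if np.unique(y).size < 2:
        raise PLSError("single-class response")
    Xd = X.copy()
    W = np.empty((p, A))
    P = np.empty((p, A))
    T = np.empty((n, A))
    q = np.empty(A)
    ssy = np.empty(A)
    for a in range(A):
        # with a single response column NIPALS converges in one pass,
        # but iterate for generality
        u = y.copy()
        w_old = None
        for _ in range(NIPALS_MAX_ITER):
            w = Xd.T @ u
            norm = np.linalg.norm(w)
            if norm < 1e-12:
                raise PLSError(
                    f"no residual covariance with y at component {a + 1}: rank exhausted"
                )
            w /= norm
            t = Xd @ w
            tt = t @ t
            if tt < 1e-24:
                raise PLSError(f"degenerate score at component {a + 1}")
            qa = (y @ t) / tt
            u_new = y * qa  # single-column y: u proportional to y
            if w_old is not None and np.linalg.norm(w - w_old) < NIPALS_TOL:
                break
            w_old = w
            u = u_new
        p_a = (Xd.T @ t) / tt
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, qa
        ssy[a] = qa**2 * tt
        Xd -= np.outer(t, p_a)
    return PLSModel(weights=W, loadings=P, scores=T, y_loadings=q, ssy=ssy)


# -- post-transformation ------------------------------------------------

@dataclass
class PostTransformedPLS:
    """Rotation of the score space into predictive tp + orthogonal to."""

    tp: np.ndarray          # samples
    to: np.ndarray          # samples x (A-1)
    rotation: np.ndarray    # A x A orthogonal, first column spans tp
    y_loadings_rotated: np.ndarray

    @property
    def fitted_values(self) -> np.ndarray:
        scores = np.column_stack([self.tp, self.to]) if self.to.size else self.tp[:, None]
        return scores @ self.y_loadings_rotated


def post_transform(model: PLSModel, y: np.ndarray) -> PostTransformedPLS:
    """Rotate scores so one direction carries all covariance with y.

    The first rotated direction is the (normalized) vector of score-y
    covariances; the orthogonal complement completes an orthogonal
    rotation, so each remaining direction has exactly zero sample
    covariance with y and the fitted predictions are unchanged.
    """
    A = model.n_components
    if A < 1:
        raise PLSError("post-transformation needs at least one component")
    y = np.asarray(y, dtype=float).ravel()
    c = model.scores.T @ y
    norm = np.linalg.norm(c)
    if norm < 1e-12:
        raise PLSError("scores carry no covariance with y")
    if A == 1:
        G = np.array([[1.0]]) if c[0] >= 0 else np.array([[-1.0]])
    else:
        basis = np.column_stack([c / norm, np.eye(A)])
        Q, _ = np.linalg.qr(basis)
        G = Q[:, :A]
        if G[:, 0] @ c < 0:
            G = -G
    T_rot = model.scores @ G
    return PostTransformedPLS(
        tp=T_rot[:, 0],
        to=T_rot[:, 1:],
        rotation=G,
        y_loadings_rotated=G.T @ model.y_loadings,
    )


# -- VIP ----------------------------------------------------------------

def vip(model: PLSModel) -> np.ndarray:
    """Variable influence on projection.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a );
    by construction the mean of VIP^2 over features is exactly 1.
    """
    ssy_total = model.ssy.sum()
    if ssy_total <= 0:
        raise PLSError("explained response sum of squares is zero")
    W = model.weights
    wnorm2 = (W**2).sum(axis=0)
    contrib = (W**2 / wnorm2) @ model.ssy
    p = W.shape[0]
    return np.sqrt(p * contrib / ssy_total)


# -- LDA on scores ------------------------------------------------------

@dataclass
class ScoreLDA:
    """Two-class LDA with pooled covariance, fitted on latent scores."""

    classes: list
    means: np.ndarray       # 2 x A
    cov_inv: np.ndarray
    log_priors: np.ndarray

    def decision(self, scores: np.ndarray) -> np.ndarray:
        """delta(class0) - delta(class1) for each sample."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        deltas = []
        for g in range(2):
            mu = self.means[g]
            deltas.append(
                scores @ self.cov_inv @ mu - 0.5 * mu @ self.cov_inv @ mu + self.log_priors[g]
            )
        return deltas[0] - deltas[1]

    def predict(self, scores: np.ndarray) -> np.ndarray:
        d = self.decision(scores)
        # ties toward the class with the larger prior, then lexicographic
        # (classes are stored sorted, so index 0 wins the final tie)
        tie_winner = int(np.argmax(self.log_priors))  # argmax is first on ties
        out = np.where(d > 0, self.classes[0], self.classes[1])
        out = np.asarray(out, dtype=object)
        out[d == 0] = self.classes[tie_winner]
        return out


def lda_fit(scores: np.ndarray, labels) -> ScoreLDA:
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.ndim == 2 and scores.shape[0] == 1:
        scores = scores.T if scores.shape[1] > 1 else scores
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise PLSError(f"LDA needs two classes, got {classes}")
    n, A = scores.shape
    means = np.vstack([scores[labels == c].mean(axis=0) for c in classes])
    pooled = np.zeros((A, A))
    for c, mu in zip(classes, means):
        R = scores[labels == c] - mu
        pooled += R.T @ R
    pooled /= max(n - 2, 1)
    try:
        cov_inv = np.linalg.inv(pooled)
    except np.linalg.LinAlgError:
        warnings.warn("singular pooled covariance; ridge-regularizing")
        pooled = pooled + LDA_RIDGE * np.eye(A)
        cov_inv = np.linalg.inv(pooled)
    priors = np.array([(labels == c).mean() for c in classes])
    return ScoreLDA(
        classes=classes,
        means=means,
        cov_inv=cov_inv,
        log_priors=np.log(priors),
    )


# -- MCC ----------------------------------------------------------------

def confusion_2x2(y_true, y_pred, classes) -> np.ndarray:
    """Rows = true class (classes[0] first), columns = predicted."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    m = np.zeros((2, 2), dtype=int)
    for i, ct in enumerate(classes):
        for j, cp in enumerate(classes):
            m[i, j] = int(np.sum((y_true == ct) & (y_pred == cp)))
    return m


def mcc(confusion) -> float:
    """Matthews correlation coefficient of a 2x2 confusion matrix.

    (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)); defined as 0
    when any marginal is zero.
    """
    m = np.asarray(confusion)
    if m.shape != (2, 2) or (m < 0).any() or not np.issubdtype(m.dtype, np.integer):
        m = m.astype(float)
        if m.shape != (2, 2) or (m < 0).any() or np.any(m != np.round(m)):
            raise PLSError("confusion matrix must be 2x2 nonnegative integer counts")
    tp, fn = float(m[0, 0]), float(m[0, 1])
    fp, tn = float(m[1, 0]), float(m[1, 1])
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(denom)


# -- cross-validation ---------------------------------------------------

def stratified_folds(labels, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deterministic stratified k-fold assignment (round-robin after a
    within-class shuffle); returns test-index arrays."""
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(k)]
    for c in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == c)
        if idx.size < k:
            raise PLSError(f"class {c!r} has {idx.size} < k={k} members")
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


@dataclass
class MCCReport:
    mcc_fit: float | None = None
    mcc_cv: float | None = None
    p_fit: float | None = None
    p_cv: float | None = None
    confusion_fit: np.ndarray | None = None
    confusion_cv: np.ndarray | None = None
    n_permutations: int = 0
    fold_assignments: list | None = None
    seed: int | None = None


def _fit_predict_mcc(X: np.ndarray, labels, n_components: int, scale_mode: str):
    """Scale, fit PLS + LDA, predict the training samples; returns
    (model, lda, confusion, mcc)."""
    Xs, _ = scale_matrix(pd.DataFrame(X), scale_mode)
    Xs = Xs.to_numpy()
    y, classes = dummy_code(labels)
    model = fit_pls(Xs, y, n_components)
    clf = lda_fit(model.scores, labels)
    pred = clf.predict(model.scores)
    conf = confusion_2x2(labels, pred, classes)
    return model, clf, conf, mcc(conf)


def fit_mcc(X, labels, n_components: int, scale_mode: str = "mean_center") -> tuple[float, np.ndarray]:
    """In-fit (calculation) MCC of the full-data model."""
    _, _, conf, value = _fit_predict_mcc(np.asarray(X, dtype=float), labels, n_components, scale_mode)
    return value, conf


def cross_validate_mcc(
    X,
    labels,
    n_components: int,
    k: int = 5,
    seed: int = 0,
    scale_mode: str = "mean_center",
) -> MCCReport:
    """Stratified k-fold CV MCC with the whole fit redone per fold.

    Scaling, PLS and LDA are re-estimated on each training split; test
    predictions are pooled into a single confusion matrix and one MCC.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = stratified_folds(labels, k, rng)
    classes = sorted(set(labels.tolist()))
    pred = np.empty(labels.shape, dtype=object)
    for test_idx in folds:
        train_idx = np.setdiff1d(np.arange(X.shape[0]), test_idx)
        Xtr = X[train_idx]
        center = Xtr.mean(axis=0)
        if scale_mode == "autoscale":
            sd = Xtr.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
        else:
            sd = 1.0
        Xtr_s = (Xtr - center) / sd
        Xte_s = (X[test_idx] - center) / sd
        y_tr, _ = dummy_code(labels[train_idx])
        a = min(n_components, min(len(train_idx) - 1, X.shape[1]))
        model = fit_pls(Xtr_s, y_tr, a)
        clf = lda_fit(model.scores, labels[train_idx])
        pred[test_idx] = clf.predict(model.transform(Xte_s))
    conf = confusion_2x2(labels, pred, classes)
    return MCCReport(
        mcc_cv=mcc(conf),
        confusion_cv=conf,
        fold_assignments=[f.tolist() for f in folds],
        seed=seed,
    )


def select_n_components(
    X,
    labels,
    max_components: int = 5,
    k: int = 5,
    seed: int = 0,
    scale_mode: str = "mean_center",
) -> int:
    """Component count maximizing the CV MCC; ties go to the smallest."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if max_components < 1:
        raise PLSError("max_components must be >= 1")
    n_tr_min = X.shape[0] - max(len(f) for f in stratified_folds(labels, k, np.random.default_rng(seed)))
    cap = min(max_components, n_tr_min - 1, X.shape[1])
    if cap < max_components:
        warnings.warn(f"max_components capped at {cap} by the data rank")
    best_a, best_mcc = 1, -np.inf
    for a in range(1, cap + 1):
        try:
            value = cross_validate_mcc(
                X, labels, a, k=k, seed=seed, scale_mode=scale_mode
            ).mcc_cv
        except PLSError:  # rank exhausted before a components
            break
        if value > best_mcc + 1e-12:
            best_a, best_mcc = a, value
    return best_a


# -- permutation test ---------------------------------------------------

def permutation_test(
    X,
    labels,
    n_components: int,
    statistic: str = "mcc_cv",
    n_permutations: int = 1000,
    seed: int = 0,
    k: int = 5,
    scale_mode: str = "mean_center",
) -> tuple[float, float, np.ndarray]:
    """Permutation p-value of the in-fit or CV MCC.

    The class response is permuted and the *entire* statistic (scaling,
    PLS, LDA, and the CV loop for ``mcc_cv``) recomputed per permutation;
    p = (1 + #{null >= observed}) / (n_permutations + 1).
    Returns (observed, p, null distribution).
    """
    if statistic not in ("mcc_fit", "mcc_cv"):
        raise PLSError(f"unknown statistic {statistic!r}")
    if n_permutations < 1:
        raise PLSError("need at least one permutation")
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)

    def stat(lab, fold_seed):
        if statistic == "mcc_fit":
            return fit_mcc(X, lab, n_components, scale_mode)[0]
        return cross_validate_mcc(
            X, lab, n_components, k=k, seed=fold_seed, scale_mode=scale_mode
        ).mcc_cv

    obs_seed = int(rng.integers(2**31))
    observed = stat(labels, obs_seed)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        perm = rng.permutation(labels)
        null[b] = stat(perm, int(rng.integers(2**31)))
    p = (1.0 + np.sum(null >= observed)) / (n_permutations + 1.0)
    return observed, float(p), null


# -- Model / Results interface ------------------------------------------

class PLSDA:
    """PLS discriminant analysis model bound to a dataset.

    Parameters
    ----------
    X : DataFrame or array, samples x features (unscaled)
    labels : sequence of two class labels, aligned with X rows
    scale_mode : "mean_center" (untargeted convention) or "autoscale"
        (targeted convention)
    """

    def __init__(self, X, labels, scale_mode: str = "mean_center"):
        self.X = pd.DataFrame(X)
        self.labels = np.asarray(labels)
        if self.labels.shape[0] != self.X.shape[0]:
            raise PLSError("labels and X sample counts differ")
        self.scale_mode = scale_mode
        _, self.classes = dummy_code(self.labels)

    @classmethod
    def from_feature_table(cls, table, scale_mode: str = "mean_center") -> "PLSDA":
        study = table.study()
        return cls(study.intensities, study.sample_meta["group"].to_numpy(), scale_mode)

    def fit(
        self,
        n_components: int | None = None,
        max_components: int = 5,
        cv_folds: int = 5,
        seed: int = 0,
    ) -> "PLSDAResults":
        """Fit, selecting the component count by CV MCC when not given."""
        if n_components is None:
            n_components = select_n_components(
                self.X.to_numpy(), self.labels, max_components, k=cv_folds,
                seed=seed, scale_mode=self.scale_mode,
            )
        Xs, scaler = scale_matrix(self.X, self.scale_mode)
        y, _ = dummy_code(self.labels)
        model = fit_pls(Xs.to_numpy(), y, n_components)
        clf = lda_fit(model.scores, self.labels)
        pred = clf.predict(model.scores)
        conf = confusion_2x2(self.labels, pred, self.classes)
        report = cross_validate_mcc(
            self.X.to_numpy(), self.labels, n_components, k=cv_folds,
            seed=seed, scale_mode=self.scale_mode,
        )
        report.mcc_fit = mcc(conf)
        report.confusion_fit = conf
        return PLSDAResults(
            model_spec=self,
            pls=model,
            scaler=scaler,
            lda=clf,
            y_dummy=y,
            n_components=n_components,
            cv_folds=cv_folds,
            seed=seed,
            report=report,
        )


@dataclass
class PLSDAResults:
    """Results of a fitted PLS-DA model."""

    model_spec: PLSDA
    pls: PLSModel
    scaler: object
    lda: ScoreLDA
    y_dummy: np.ndarray
    n_components: int
    cv_folds: int
    seed: int
    report: MCCReport
    _post: PostTransformedPLS | None = field(default=None, repr=False)

    @property
    def mcc_fit(self) -> float:
        return self.report.mcc_fit

    @property
    def mcc_cv(self) -> float:
        return self.report.mcc_cv

    def vip(self) -> pd.Series:
        return pd.Series(vip(self.pls), index=self.model_spec.X.columns, name="VIP")

    def post_transformed(self) -> PostTransformedPLS:
        if self._post is None:
            self._post = post_transform(self.pls, self.y_dummy)
        return self._post

    def scores_frame(self) -> pd.DataFrame:
        """tp / to score coordinates with group labels (plot data)."""
        pt = self.post_transformed()
        data = {"tp": pt.tp}
        for j in range(pt.to.shape[1]):
            data[f"to{j + 1}"] = pt.to[:, j]
        data["group"] = self.model_spec.labels
        return pd.DataFrame(data, index=self.model_spec.X.index)

    def permutation_pvalues(
        self, n_permutations: int = 1000, seed: int | None = None
    ) -> tuple[float, float]:
        """(p of in-fit MCC, p of CV MCC) by response permutation."""
        seed = self.seed if seed is None else seed
        X, labels = self.model_spec.X.to_numpy(), self.model_spec.labels
        _, p_fit, _ = permutation_test(
            X, labels, self.n_components, "mcc_fit", n_permutations, seed,
            k=self.cv_folds, scale_mode=self.model_spec.scale_mode,
        )
        _, p_cv, _ = permutation_test(
            X, labels, self.n_components, "mcc_cv", n_permutations, seed,
            k=self.cv_folds, scale_mode=self.model_spec.scale_mode,
        )
        self.report.p_fit, self.report.p_cv = p_fit, p_cv
        self.report.n_permutations = n_permutations
        return p_fit, p_cv

    def summary(self) -> str:
        r = self.report
        lines = [
            "PLS-DA (NIPALS, LDA class assignment)",
            "=" * 46,
            f"samples:            {self.model_spec.X.shape[0]}"
            f"  ({' vs '.join(str(c) for c in self.model_spec.classes)})",
            f"features:           {self.model_spec.X.shape[1]}",
            f"scaling:            {self.model_spec.scale_mode}",
            f"latent variables:   {self.n_components}",
            f"MCC (in fit):       {r.mcc_fit:.3f}",
            f"MCC ({self.cv_folds}-fold CV):   {r.mcc_cv:.3f}",
        ]
        if r.p_fit is not None:
            lines.append(f"p(MCC):             {r.p_fit:.4g}  ({r.n_permutations} permutations)")
            lines.append(f"p(MCC CV):          {r.p_cv:.4g}")
        lines.append(f"explained SSY/comp: {np.round(self.pls.ssy / self.pls.ssy.sum(), 3)}")
        return "\n".join(lines)
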