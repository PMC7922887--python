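"""Bootstrap stability selection of discriminant features.

Relevance of a feature is judged by how consistently its VIP score stays
high when the PLS-DA model is refitted on stratified bootstrap resamples.
The VIP cutoff that defines "high" is calibrated against a permutation
null at significance level alpha: the cutoff is the empirical (1-alpha)
quantile of the maximum VIP over features across refits with a permuted
class response, which controls the family-wise chance of declaring any
feature relevant on null data.  A feature is relevant when its VIP
exceeds the calibrated cutoff in more than ``freq_threshold`` (default a
majority) of the bootstrap refits.

A fixed, uncalibrated cutoff (e.g. VIP >= 1, the classical rule of thumb)
plus thresholding of the selection frequency against the permutation null
of the maximum frequency is available via ``vip_cutoff=...`` and
``threshold_mode="max_frequency"``; at the dimensions this pipeline
targets (tens of samples, hundreds-to-thousands of features) that
frequency statistic saturates under the null and the calibrated-VIP mode
is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .plsda import PLSError, dummy_code, fit_pls, vip


class StabilityError(ValueError):
    pass


@dataclass
class StabilityConfig:
    """Stability-selection settings.

    ``n_boot`` bootstrap subsets (500 emulates the study); ``alpha`` is
    the significance level of the permutation calibration; ``n_null`` the
    number of permuted-response refits used for it.  ``vip_cutoff=None``
    means "calibrate from the permutation null"; a number fixes the
    per-subset cutoff.  ``seed`` is mandatory for reproducibility.
    """

    n_boot: int = 500
    alpha: float = 0.05
    vip_cutoff: float | None = None
    freq_threshold: float = 0.5
    n_null: int = 100
    threshold_mode: str = "calibrated_vip"  # or "max_frequency"
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise StabilityError("alpha must lie in (0, 1)")
        if self.n_boot < 1:
            raise StabilityError("n_boot must be >= 1")
        if not 0 <= self.freq_threshold < 1:
            raise StabilityError("freq_threshold must lie in [0, 1)")
        if self.threshold_mode not in ("calibrated_vip", "max_frequency"):
            raise StabilityError(f"unknown threshold_mode {self.threshold_mode!r}")

    def require_seed(self) -> int:
        if self.seed is None:
            raise StabilityError("seed is required")
        return self.seed


@dataclass
class SelectionResult:
    """Per-feature bootstrap selection frequencies and the relevant set."""

    frequencies: pd.Series
    frequency_threshold: float
    vip_cutoff: float
    relevant: list
    null_summary: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"frequency": self.frequencies})
        out["relevant"] = out.index.isin(self.relevant)
        return out


def _scale_center(X: np.ndarray, mode: str) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    if mode == "autoscale":
        sd = X.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    return Xc


def _vip_of(X: np.ndarray, labels: np.ndarray, n_components: int, scale_mode: str) -> np.ndarray:
    y, _ = dummy_code(labels)
    a = min(n_components, min(X.shape[0] - 1, X.shape[1]))
    return vip(fit_pls(_scale_center(X, scale_mode), y, a))


def bootstrap_vip_frequencies(
    X,
    labels,
    n_components: int,
    vip_cutoff: float,
    n_boot: int,
    rng: np.random.Generator,
    scale_mode: str = "mean_center",
    max_retries: int = 10,
) -> np.ndarray:
    """Fraction of stratified bootstrap refits with VIP >= cutoff, per feature.

    Resampling is stratified with replacement at the original group sizes,
    so both classes appear in every subset by construction; degenerate
    refits (rank exhausted on a pathological resample) are redrawn a
    bounded number of times.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise StabilityError(f"need two classes, got {classes}")
    idx_by_class = [np.flatnonzero(labels == c) for c in classes]
    counts = np.zeros(X.shape[1])
    for _ in range(n_boot):
        for attempt in range(max_retries):
            idx = np.concatenate(
                [rng.choice(ix, size=ix.size, replace=True) for ix in idx_by_class]
            )
            try:
                v = _vip_of(X[idx], labels[idx], n_components, scale_mode)
                break
            except PLSError:
                if attempt == max_retries - 1:
                    raise StabilityError("bootstrap refit failed repeatedly")
        counts += v >= vip_cutoff
    return counts / n_boot


def null_max_vip(
    X,
    labels,
    n_components: int,
    n_null: int,
    rng: np.random.Generator,
    scale_mode: str = "mean_center",
) -> np.ndarray:
    """Null distribution of the maximum VIP under a permuted response."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    out = np.empty(n_null)
    for r in range(n_null):
        perm = rng.permutation(labels)
        out[r] = _vip_of(X, perm, n_components, scale_mode).max()
    return out


def null_max_frequency(
    X,
    labels,
    n_components: int,
    vip_cutoff: float,
    n_null: int,
    n_boot: int,
    rng: np.random.Generator,
    scale_mode: str = "mean_center",
) -> np.ndarray:
    """Null distribution of the max per-feature selection frequency.

    Each null round permutes the response once and repeats the full
    bootstrap frequency pass.  Kept for the fixed-cutoff mode.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if n_null < 20:
        raise StabilityError("n_null must be >= 20 for a usable quantile")
    out = np.empty(n_null)
    for r in range(n_null):
        perm = rng.permutation(labels)
        freqs = bootstrap_vip_frequencies(
            X, perm, n_components, vip_cutoff, n_boot, rng, scale_mode
        )
        out[r] = freqs.max()
    return out


def select_relevant(
    X,
    labels,
    n_components: int,
    cfg: StabilityConfig,
    scale_mode: str = "mean_center",
) -> SelectionResult:
    """Full stability selection: calibrate, bootstrap, threshold.

    Reproducible under ``cfg.seed``; see the module docstring for the two
    threshold modes.
    """
    X = pd.DataFrame(X)
    labels = np.asarray(labels)
    rng = np.random.default_rng(cfg.require_seed())
    Xv = X.to_numpy(dtype=float)

    if cfg.threshold_mode == "calibrated_vip":
        if cfg.vip_cutoff is not None:
            cutoff = float(cfg.vip_cutoff)
            null_summary = {"mode": "fixed_cutoff"}
        else:
            null = null_max_vip(Xv, labels, n_components, cfg.n_null, rng, scale_mode)
            cutoff = float(np.quantile(null, 1.0 - cfg.alpha, method="higher"))
            null_summary = {
                "mode": "calibrated_vip",
                "n_null": cfg.n_null,
                "null_max_vip_mean": float(null.mean()),
                "null_max_vip_quantile": cutoff,
            }
        freqs = bootstrap_vip_frequencies(
            Xv, labels, n_components, cutoff, cfg.n_boot, rng, scale_mode
        )
        freq_threshold = cfg.freq_threshold
    else:  # max_frequency: fixed VIP cutoff, frequency thresholded on its null
        cutoff = 1.0 if cfg.vip_cutoff is None else float(cfg.vip_cutoff)
        null = null_max_frequency(
            Xv, labels, n_components, cutoff, cfg.n_null,
            max(cfg.n_boot // 5, 20), rng, scale_mode,
        )
        freq_threshold = float(np.quantile(null, 1.0 - cfg.alpha, method="higher"))
        null_summary = {
            "mode": "max_frequency",
            "n_null": cfg.n_null,
            "null_max_frequency_quantile": freq_threshold,
        }
        freqs = bootstrap_vip_frequencies(
            Xv, labels, n_components, cutoff, cfg.n_boot, rng, scale_mode
        )

    frequencies = pd.Series(freqs, index=X.columns, name="selection_frequency")
    relevant = list(frequencies.index[frequencies > freq_threshold])
    return SelectionResult(
        frequencies=frequencies,
        frequency_threshold=freq_threshold,
        vip_cutoff=cutoff,
        relevant=relevant,
        null_summary=null_summary,
    )
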