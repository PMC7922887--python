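"""Synthetic study generator.

Emulates the design of a small untargeted LC-MS case-control study:
two groups of ~9-15 neonates, a few thousand RT_mass features per
ionization mode, log-normal intensities with per-sample multiplicative
dilution, a small set of planted group-discriminant features, pooled-QC
samples injected at nominal dilutions (1:3, 1:5, 1:7), and completely-at-
random missing values.

The intensity model is multiplicative: for study sample i and feature j,

    log I_ij = b_j + s_j * e * 1[i in case] * 1[j planted] + log d_i + eps_ij

with feature baseline b_j, planted log-fold-change effect e with random
sign s_j, per-sample dilution factor d_i (log-normal), and iid Gaussian
noise eps_ij.  This makes the probabilistic-quotient normalization
assumption (pure multiplicative dilution) literally true, and the planted
effects additive on the log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .chemdb import PROTON_MASS, load_bundled_metabolite_db
from .containers import FeatureTable


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-design and noise parameters of the generator.

    Defaults are the emulated study's conditions: 9 cases vs 10 controls
    (the urine cohort), 2394 features (the NEG-mode table), pooled QCs at
    1:3 / 1:5 / 1:7.  ``effect_size`` is a natural-log fold change;
    ``dilution_sd``/``noise_sd`` are standard deviations on the log scale.
    """

    n_case: int = 9
    n_control: int = 10
    n_features: int = 2394
    #: None -> min(40, n_features), the study-scale default
    n_discriminant: int | None = None
    effect_size: float = 2.0
    dilution_sd: float = 0.3
    noise_sd: float = 0.5
    missing_rate: float = 0.1
    qc_dilutions: tuple[float, ...] = (1 / 3, 1 / 5, 1 / 7)
    n_qc_replicates: int = 3
    #: technical repeatability of pooled-QC injections (log-scale sd);
    #: much smaller than the biological noise_sd
    qc_noise_sd: float = 0.1
    ion_mode: str = "NEG"
    mz_jitter_ppm: float = 2.0
    #: metabolite names (or HMDB ids) whose adduct masses the planted
    #: features receive, cycled in order; None cycles the whole bundled DB
    planted_metabolites: tuple[str, ...] | None = None
    baseline_log_mean: float = 11.5  # ~1e5 ion counts
    baseline_log_sd: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_discriminant is None:
            self.n_discriminant = min(40, self.n_features)
        if self.n_discriminant > self.n_features:
            raise SimConfigError(
                f"n_discriminant ({self.n_discriminant}) exceeds n_features ({self.n_features})"
            )
        if not 0 <= self.missing_rate < 1:
            raise SimConfigError("missing_rate must lie in [0, 1)")
        if any(d <= 0 or d > 1 for d in self.qc_dilutions):
            raise SimConfigError("qc_dilutions must be in (0, 1]")
        if min(self.n_case, self.n_control, self.n_features) < 1:
            raise SimConfigError("counts must be positive")
        if self.ion_mode not in ("POS", "NEG"):
            raise SimConfigError(f"unknown ion_mode {self.ion_mode!r}")

    def require_seed(self) -> int:
        if self.seed is None:
            raise SimConfigError("seed is required: generation must be reproducible")
        return self.seed


@dataclass
class GroundTruth:
    """What the generator planted, for oracle comparisons downstream."""

    discriminant_ids: list[str]
    #: +1 = elevated in cases, -1 = elevated in controls, per planted feature
    directions: dict[str, int]
    #: true per-sample multiplicative dilution factor (study samples)
    dilution_factors: dict[str, float]
    #: undiluted pooled profile used for QC rows (per feature)
    base_profile: dict[str, float]
    #: HMDB accession whose adduct mass was given to each planted feature
    planted_metabolites: dict[str, str]

    def to_json_dict(self) -> dict:
        return asdict(self)


def _feature_meta(cfg: SimConfig, rng: np.random.Generator, planted: np.ndarray):
    """Assign m/z, RT and ion mode; planted features get database adduct masses."""
    from .chemdb import hmdb_equal

    records, _ = load_bundled_metabolite_db()
    if cfg.planted_metabolites is not None:
        chosen = []
        for name in cfg.planted_metabolites:
            match = [
                r for r in records
                if r.matches_name(name)
                or (name.upper().startswith("HMDB") and hmdb_equal(r.hmdb_id, name))
            ]
            if not match:
                raise SimConfigError(f"unknown planted metabolite {name!r}")
            chosen.append(match[0])
        records = chosen
    shift = PROTON_MASS if cfg.ion_mode == "POS" else -PROTON_MASS
    mz = rng.uniform(50.0, 1200.0, size=cfg.n_features)
    planted_metabolites: dict[str, str] = {}
    ids = [f"{cfg.ion_mode}_{j:05d}" for j in range(cfg.n_features)]
    for k, j in enumerate(planted):
        rec = records[k % len(records)]
        ppm = rng.normal(0.0, cfg.mz_jitter_ppm)
        mz[j] = (rec.monoisotopic_mass + shift) * (1.0 + ppm * 1e-6)
        planted_metabolites[ids[j]] = rec.hmdb_id
    meta = pd.DataFrame(
        {
            "mz": mz,
            "rt": rng.uniform(0.5, 12.0, size=cfg.n_features),
            "ion_mode": cfg.ion_mode,
        },
        index=pd.Index(ids, name="feature_id"),
    )
    return meta, planted_metabolites


def generate_feature_table(cfg: SimConfig) -> tuple[FeatureTable, GroundTruth]:
    """Generate the study samples of one ionization mode.

    Returns the feature table (study rows only; see
    :func:`generate_qc_dilution_series` for QC rows) and the ground truth
    needed by recovery oracles.  Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.require_seed())
    n = cfg.n_case + cfg.n_control
    baselines = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_features)
    planted = rng.choice(cfg.n_features, size=cfg.n_discriminant, replace=False)
    signs = rng.choice([-1, 1], size=cfg.n_discriminant)
    log_dilution = rng.normal(0.0, cfg.dilution_sd, size=n)

    sample_ids = [f"CASE{i + 1:02d}" for i in range(cfg.n_case)] + [
        f"CTRL{i + 1:02d}" for i in range(cfg.n_control)
    ]
    group = np.array(["case"] * cfg.n_case + ["control"] * cfg.n_control)

    log_int = np.tile(baselines, (n, 1))
    # planted effect: cases shifted by sign*effect relative to controls
    for s, j in zip(signs, planted):
        log_int[group == "case", j] += s * cfg.effect_size
    log_int += log_dilution[:, None]
    log_int += rng.normal(0.0, cfg.noise_sd, size=(n, cfg.n_features))
    intensities = np.exp(log_int)

    if cfg.missing_rate > 0:
        mask = rng.random(size=intensities.shape) < cfg.missing_rate
        intensities[mask] = np.nan

    feature_meta, planted_metabolites = _feature_meta(cfg, rng, planted)
    sample_meta = pd.DataFrame(
        {
            "group": group,
            "sample_type": "study",
            "nominal_dilution": np.nan,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    table = FeatureTable(
        pd.DataFrame(intensities, index=sample_meta.index, columns=feature_meta.index),
        feature_meta,
        sample_meta,
    )
    ids = feature_meta.index
    truth = GroundTruth(
        discriminant_ids=[ids[j] for j in planted],
        directions={ids[j]: int(s) for s, j in zip(signs, planted)},
        dilution_factors=dict(zip(sample_ids, np.exp(log_dilution))),
        base_profile=dict(zip(ids, np.exp(baselines))),
        planted_metabolites=planted_metabolites,
    )
    return table, truth


def generate_qc_dilution_series(
    cfg: SimConfig,
    base_profile: Sequence[float],
    feature_meta: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> FeatureTable:
    """QC rows: the pooled profile injected at each nominal dilution.

    The expected intensity of a QC row at dilution ``d`` is
    ``d * base_profile`` with multiplicative log-normal technical noise of
    ``qc_noise_sd`` around it; the nominal dilution is recorded in the
    sample metadata.
    """
    if len(cfg.qc_dilutions) == 0:
        raise SimConfigError("qc_dilutions is empty")
    base = np.asarray(base_profile, dtype=float)
    if base.shape[0] != cfg.n_features:
        raise SimConfigError(
            f"base_profile length {base.shape[0]} != n_features {cfg.n_features}"
        )
    if rng is None:
        rng = np.random.default_rng(cfg.require_seed() + 1)
    rows, ids, dils = [], [], []
    for d in cfg.qc_dilutions:
        for r in range(cfg.n_qc_replicates):
            noise = rng.normal(0.0, cfg.qc_noise_sd, size=cfg.n_features)
            rows.append(d * base * np.exp(noise))
            ids.append(f"QC_d{round(1 / d)}_r{r + 1}")
            dils.append(d)
    if feature_meta is None:
        feature_meta = pd.DataFrame(
            {"mz": np.nan, "rt": np.nan, "ion_mode": cfg.ion_mode},
            index=pd.Index([f"{cfg.ion_mode}_{j:05d}" for j in range(cfg.n_features)], name="feature_id"),
        )
    sample_meta = pd.DataFrame(
        {"group": "none", "sample_type": "QC", "nominal_dilution": dils},
        index=pd.Index(ids, name="sample_id"),
    )
    return FeatureTable(
        pd.DataFrame(np.asarray(rows), index=sample_meta.index, columns=feature_meta.index),
        feature_meta.copy(),
        sample_meta,
    )


def generate_dataset(cfg: SimConfig) -> tuple[FeatureTable, GroundTruth]:
    """Study samples plus QC dilution series in one table."""
    study, truth = generate_feature_table(cfg)
    base = np.array([truth.base_profile[f] for f in study.feature_meta.index])
    qc = generate_qc_dilution_series(cfg, base, study.feature_meta)
    table = FeatureTable(
        pd.concat([study.intensities, qc.intensities]),
        study.feature_meta,
        pd.concat([study.sample_meta, qc.sample_meta]),
    )
    return table, truth


# -- clinical covariate fixture ---------------------------------------

#: (name, kind, case parameter, control parameter): binary covariates carry
#: exact per-group counts; numeric covariates carry (mean, sd).
DEFAULT_CLINICAL_SPECS = [
    ("gestational_age_days", "numeric", (207.0, 17.0), (213.0, 16.0)),
    ("birth_weight_g", "numeric", (1269.0, 358.0), (1300.0, 354.0)),
    ("male_sex", "binary", 7, 5),
    ("cesarean_section", "binary", 14, 15),
    ("prenatal_steroids", "binary", 13, 13),
    ("small_for_gestational_age", "binary", 2, 6),
    ("positive_maternal_vaginal_swab", "binary", 3, 0),
    ("prom_gt_18h", "binary", 4, 2),
    ("inotropes", "binary", 0, 1),
    ("crp_lt_2.9_at_birth", "binary", 12, 15),
]


def generate_clinical_table(
    seed: int,
    n_case: int = 15,
    n_control: int = 15,
    specs: list[tuple] | None = None,
) -> pd.DataFrame:
    """Per-subject covariate table reproducing stated margins exactly.

    Binary covariates reproduce the requested per-group counts exactly
    (rows are shuffled within group); numeric covariates are drawn
    Normal(mean, sd) per group.
    """
    if specs is None:
        specs = DEFAULT_CLINICAL_SPECS
    rng = np.random.default_rng(seed)
    n = {"case": n_case, "control": n_control}
    frames = {}
    for g in ("case", "control"):
        cols = {}
        for name, kind, case_par, ctrl_par in specs:
            par = case_par if g == "case" else ctrl_par
            if kind == "binary":
                if not 0 <= par <= n[g]:
                    raise ValueError(
                        f"{name}: count {par} infeasible for group of {n[g]}"
                    )
                values = np.zeros(n[g], dtype=int)
                values[:par] = 1
                rng.shuffle(values)
                cols[name] = values
            elif kind == "numeric":
                mean, sd = par
                cols[name] = rng.normal(mean, sd, size=n[g])
            else:
                raise ValueError(f"unknown covariate kind {kind!r}")
        idx = [f"{'EOS' if g == 'case' else 'CTRL'}{i + 1:02d}" for i in range(n[g])]
        frame = pd.DataFrame(cols, index=pd.Index(idx, name="subject_id"))
        frame.insert(0, "group", g)
        frames[g] = frame
    return pd.concat([frames["case"], frames["control"]])
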