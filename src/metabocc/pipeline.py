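"""End-to-end two-step analysis orchestration.

``run_untargeted`` executes the discovery arm on an untargeted feature
table: QC calibration -> PQN -> missingness filter / imputation -> log
transform -> PCA outlier report -> univariate testing (BH, delta=0.10)
-> PLS-DA (components by 5-fold CV, MCC + permutation p-values) ->
bootstrap stability selection -> union of the univariate and multivariate
relevant sets (with provenance) -> annotation -> pathway ORA
(delta=0.15).  ``run_targeted`` runs the confirmation arm on a named-
metabolite concentration table (autoscaling, no annotation step, ORA at
delta=0.10).

Every artifact written to disk embeds the configuration hash and a
content digest of the input table, so reports can be traced to their
exact inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import chemdb
from .containers import FeatureTable, config_hash
from .outliers import detect_outliers
from .pathways import run_ora
from .plsda import PLSDA
from .preprocess import (
    apply_calibration_filter,
    fit_qc_calibration,
    impute_and_filter,
    pqn_normalize,
)
from .stability import StabilityConfig, select_relevant
from .univariate import relevant_features

log = logging.getLogger("metabocc")


class PipelineError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Knobs of the two-step analysis (defaults emulate the study)."""

    delta_univariate: float = 0.10
    delta_ora_untargeted: float = 0.15
    delta_ora_targeted: float = 0.10
    qc_r2_threshold: float = 0.7
    qc_correct_intensities: bool = True
    max_missing_fraction: float = 0.5
    log_transform: bool = True
    outlier_gamma: float = 0.95
    max_components: int = 5
    cv_folds: int = 5
    n_permutations: int = 1000
    n_boot: int = 500
    stability_alpha: float = 0.05
    stability_n_null: int = 100
    annotation_tolerance_ppm: float = 10.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for d in (self.delta_univariate, self.delta_ora_untargeted, self.delta_ora_targeted):
            if not 0 < d < 1:
                raise PipelineError("all delta levels must lie in (0, 1)")

    def require_seed(self) -> int:
        if self.seed is None:
            raise PipelineError("seed is mandatory")
        return self.seed

    def hash(self) -> str:
        return config_hash(dataclasses.asdict(self))


def _merge_relevant(uni: pd.DataFrame, multi: list) -> pd.DataFrame:
    """Set union of univariate and multivariate relevant features with a
    provenance column (univariate / multivariate / both)."""
    uni_set = set(uni.index[uni["relevant"]])
    multi_set = set(multi)
    merged = sorted(uni_set | multi_set)
    provenance = [
        "both" if f in uni_set and f in multi_set
        else ("univariate" if f in uni_set else "multivariate")
        for f in merged
    ]
    return pd.DataFrame({"provenance": provenance}, index=pd.Index(merged, name="feature_id"))


def _write(outdir: Path | None, name: str, payload) -> None:
    if outdir is None:
        return
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / name
    if isinstance(payload, pd.DataFrame):
        payload.to_csv(path, sep="\t" if path.suffix == ".tsv" else ",")
    else:
        path.write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def preprocess_untargeted(
    table: FeatureTable, config: PipelineConfig
) -> tuple[FeatureTable, dict]:
    """Calibration (if QC rows exist) + PQN + imputation + log transform."""
    report: dict = {}
    work = table
    if work.qc_mask.any():
        cal = fit_qc_calibration(work, config.qc_r2_threshold)
        work = apply_calibration_filter(work, cal, correct=config.qc_correct_intensities)
        report["qc_calibration"] = {
            "n_features_in": table.n_features,
            "n_retained": cal.n_retained,
            "r2_threshold": config.qc_r2_threshold,
            "corrected": config.qc_correct_intensities,
        }
        log.info("QC calibration: %d -> %d features", table.n_features, cal.n_retained)
    pqn = pqn_normalize(work)
    work = pqn.table
    report["pqn"] = {
        "quotient_median": pqn.quotient_median.round(5).to_dict(),
    }
    work = impute_and_filter(work, config.max_missing_fraction)
    report["missingness_filter"] = {"n_features_out": work.n_features}
    log.info("missingness filter: %d features remain", work.n_features)
    if config.log_transform:
        work = FeatureTable(
            np.log(work.intensities.clip(lower=1e-12)),
            work.feature_meta,
            work.sample_meta,
            log_scale=True,
        )
        report["log_transform"] = True
    return work, report


def run_untargeted(
    config: PipelineConfig,
    table: FeatureTable,
    outdir: str | Path | None = None,
    db=None,
    pathway_db=None,
) -> dict:
    """Discovery arm on one untargeted feature table; returns all stage
    results keyed by stage name (and writes artifacts when ``outdir``)."""
    seed = config.require_seed()
    outdir = Path(outdir) if outdir is not None else None
    groups = table.groups()
    if set(groups) != {"case", "control"}:
        raise PipelineError(f"study groups must be case/control, got {sorted(set(groups))}")
    provenance = {"config_hash": config.hash(), "input_digest": table.content_digest(), "seed": seed}

    work, prep_report = preprocess_untargeted(table, config)
    study = work.study()

    outliers = detect_outliers(work, gamma=config.outlier_gamma)
    log.info("outlier screen: %d flagged of %d samples", len(outliers.flagged), study.n_samples)

    uni = relevant_features(work, config.delta_univariate)
    n_uni = int(uni["relevant"].sum())
    log.info("univariate: %d relevant features (delta=%.2f)", n_uni, config.delta_univariate)

    model = PLSDA.from_feature_table(work, scale_mode="mean_center")
    results = model.fit(max_components=config.max_components, cv_folds=config.cv_folds, seed=seed)
    if config.n_permutations > 0:
        results.permutation_pvalues(config.n_permutations, seed)
    log.info(
        "PLS-DA: A=%d, MCC=%.2f, MCC_cv=%.2f",
        results.n_components, results.mcc_fit, results.mcc_cv,
    )

    stab_cfg = StabilityConfig(
        n_boot=config.n_boot,
        alpha=config.stability_alpha,
        n_null=config.stability_n_null,
        seed=seed,
    )
    selection = select_relevant(
        study.intensities, groups.to_numpy(), results.n_components, stab_cfg,
        scale_mode="mean_center",
    )
    log.info("stability selection: %d relevant features", len(selection.relevant))

    merged = _merge_relevant(uni, selection.relevant)

    if db is None:
        db, bundled_pathways = chemdb.load_bundled_metabolite_db()
        pathway_db = pathway_db or bundled_pathways
    annotated = ann.annotate_features(
        work.feature_meta.loc[merged.index],
        db,
        config.annotation_tolerance_ppm,
        directions=uni["direction"],
    )
    hit_ids = sorted(set(annotated.loc[annotated["hmdb_id"] != "", "hmdb_id"]))
    log.info("annotation: %d of %d relevant features annotated", len(hit_ids), len(merged))

    ora = (
        run_ora(hit_ids, pathway_db, config.delta_ora_untargeted) if hit_ids else None
    )
    if ora is not None:
        log.info("ORA: %d flagged pathways (delta=%.2f)", int(ora["flagged"].sum()),
                 config.delta_ora_untargeted)

    summary = {
        "provenance": provenance,
        "preprocess": prep_report,
        "outliers": outliers.to_json_dict(),
        "n_univariate_relevant": n_uni,
        "plsda": {
            "n_components": results.n_components,
            "mcc_fit": results.mcc_fit,
            "mcc_cv": results.mcc_cv,
            "p_fit": results.report.p_fit,
            "p_cv": results.report.p_cv,
        },
        "n_stability_relevant": len(selection.relevant),
        "n_merged_relevant": len(merged),
        "n_annotated": len(hit_ids),
        "n_flagged_pathways": int(ora["flagged"].sum()) if ora is not None else 0,
    }
    if outdir is not None:
        _write(outdir, "summary.json", summary)
        _write(outdir, "univariate.tsv", uni)
        _write(outdir, "selection.tsv", selection.to_frame())
        _write(outdir, "merged_relevant.tsv", merged)
        _write(outdir, "annotation.tsv", annotated)
        _write(outdir, "scores.csv", results.scores_frame())
        if ora is not None:
            _write(outdir, "ora.tsv", ora)
    return {
        "summary": summary,
        "preprocessed": work,
        "outliers": outliers,
        "univariate": uni,
        "plsda": results,
        "selection": selection,
        "merged": merged,
        "annotation": annotated,
        "ora": ora,
    }


def run_targeted(
    config: PipelineConfig,
    concentrations: pd.DataFrame,
    groups: pd.Series,
    outdir: str | Path | None = None,
    db=None,
    pathway_db=None,
) -> dict:
    """Confirmation arm on a samples x named-metabolites table.

    Metabolite identities are known, so annotation is skipped; columns are
    mapped to HMDB accessions through the bundled database for the ORA
    step (unmatched names are reported, not errors).
    """
    seed = config.require_seed()
    outdir = Path(outdir) if outdir is not None else None
    groups = groups.loc[concentrations.index]
    if db is None:
        db, bundled_pathways = chemdb.load_bundled_metabolite_db()
        pathway_db = pathway_db or bundled_pathways

    work = concentrations
    if config.log_transform:
        work = np.log(work.clip(lower=1e-12))
    uni = relevant_features(work, config.delta_univariate, groups=groups)
    n_uni = int(uni["relevant"].sum())
    log.info("targeted univariate: %d relevant metabolites", n_uni)

    model = PLSDA(work, groups.to_numpy(), scale_mode="autoscale")
    results = model.fit(max_components=config.max_components, cv_folds=config.cv_folds, seed=seed)
    if config.n_permutations > 0:
        results.permutation_pvalues(config.n_permutations, seed)

    stab_cfg = StabilityConfig(
        n_boot=config.n_boot, alpha=config.stability_alpha,
        n_null=config.stability_n_null, seed=seed,
    )
    selection = select_relevant(
        work, groups.to_numpy(), results.n_components, stab_cfg, scale_mode="autoscale"
    )
    merged = _merge_relevant(uni, selection.relevant)

    name_to_hmdb = {}
    for name in merged.index:
        recs = chemdb.lookup(db, str(name))
        if recs:
            name_to_hmdb[name] = recs[0].hmdb_id
    unmatched = sorted(set(merged.index) - set(name_to_hmdb))
    ora = (
        run_ora(sorted(set(name_to_hmdb.values())), pathway_db, config.delta_ora_targeted)
        if name_to_hmdb
        else None
    )

    summary = {
        "provenance": {"config_hash": config.hash(), "seed": seed},
        "n_metabolites": concentrations.shape[1],
        "n_univariate_relevant": n_uni,
        "plsda": {
            "n_components": results.n_components,
            "mcc_fit": results.mcc_fit,
            "mcc_cv": results.mcc_cv,
            "p_fit": results.report.p_fit,
            "p_cv": results.report.p_cv,
        },
        "n_stability_relevant": len(selection.relevant),
        "n_merged_relevant": len(merged),
        "unmatched_names": unmatched,
        "n_flagged_pathways": int(ora["flagged"].sum()) if ora is not None else 0,
    }
    if outdir is not None:
        _write(outdir, "summary.json", summary)
        _write(outdir, "univariate.tsv", uni)
        _write(outdir, "selection.tsv", selection.to_frame())
        _write(outdir, "merged_relevant.tsv", merged)
        _write(outdir, "scores.csv", results.scores_frame())
        if ora is not None:
            _write(outdir, "ora.tsv", ora)
    return {
        "summary": summary,
        "univariate": uni,
        "plsda": results,
        "selection": selection,
        "merged": merged,
        "ora": ora,
    }
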