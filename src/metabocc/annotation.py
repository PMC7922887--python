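"""Adduct-aware exact-mass annotation of RT_mass features.

Relevant features are matched to candidate metabolites by comparing the
observed m/z with the expected adduct mass ([M+H]+ in positive mode,
[M-H]- in negative mode by default) within a ppm tolerance.  Annotation
confidence levels (1 identified / 2 putatively annotated / 3 class only)
are recorded metadata, not inferred — confident identification requires
MS/MS evidence, outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chemdb import PROTON_MASS, MetaboliteRecord

#: adduct name -> (mass shift in Da, ionization mode it appears in)
ADDUCTS: dict[str, tuple[float, str]] = {
    "[M+H]+": (+PROTON_MASS, "POS"),
    "[M-H]-": (-PROTON_MASS, "NEG"),
    # extensible: common cation adducts
    "[M+Na]+": (+22.98922070, "POS"),
    "[M+K]+": (+38.96315810, "POS"),
    "[M+NH4]+": (+18.03382555, "POS"),
}

DEFAULT_ADDUCTS = ("[M+H]+", "[M-H]-")
DEFAULT_TOLERANCE_PPM = 10.0


class AnnotationError(ValueError):
    pass


def adduct_mass(monoisotopic_mass: float, adduct: str) -> float:
    """Expected m/z of an adduct ion of a neutral monoisotopic mass."""
    if adduct not in ADDUCTS:
        raise AnnotationError(f"unsupported adduct {adduct!r}")
    if monoisotopic_mass <= 0:
        raise AnnotationError("monoisotopic mass must be positive")
    return monoisotopic_mass + ADDUCTS[adduct][0]


@dataclass(frozen=True)
class AnnotationHit:
    feature_id: str | None
    observed_mz: float
    ion_mode: str
    adduct: str
    record: MetaboliteRecord
    ppm_error: float
    level: int


def mass_match(
    mz: float,
    ion_mode: str,
    db: list[MetaboliteRecord],
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    adducts=DEFAULT_ADDUCTS,
    feature_id: str | None = None,
) -> list[AnnotationHit]:
    """All ion-mode-consistent database hits within tolerance, best first."""
    if tolerance_ppm <= 0:
        raise AnnotationError("tolerance_ppm must be positive")
    hits = []
    for adduct in adducts:
        shift, mode = ADDUCTS[adduct]
        if mode != ion_mode:
            continue
        for rec in db:
            expected = rec.monoisotopic_mass + shift
            ppm = (mz - expected) / expected * 1e6
            if abs(ppm) <= tolerance_ppm:
                hits.append(
                    AnnotationHit(feature_id, mz, ion_mode, adduct, rec, ppm, rec.level)
                )
    return sorted(hits, key=lambda h: abs(h.ppm_error))


def annotate_features(
    feature_meta: pd.DataFrame,
    db: list[MetaboliteRecord],
    tolerance_ppm: float = DEFAULT_TOLERANCE_PPM,
    directions: pd.Series | None = None,
    adducts=DEFAULT_ADDUCTS,
) -> pd.DataFrame:
    """One row per feature with its best hit (or an unannotated marker).

    ``feature_meta`` must carry ``mz`` and ``ion_mode``; ``directions``
    (feature -> "SEPSIS > CTRL" / "CTRL > SEPSIS") is copied through from
    the univariate stage when given.  Output columns mirror an annotated-
    variables table: mz, direction, hmdb_id, level, annotation, adduct,
    ppm_error.
    """
    missing = [c for c in ("mz", "ion_mode") if c not in feature_meta.columns]
    if missing:
        raise AnnotationError(f"feature metadata lacks {missing}")
    bad = feature_meta.index[~np.isfinite(feature_meta["mz"].astype(float))]
    if len(bad):
        raise AnnotationError(f"features without m/z: {list(bad[:5])}")
    rows = []
    for fid, row in feature_meta.iterrows():
        hits = mass_match(
            float(row["mz"]), str(row["ion_mode"]), db, tolerance_ppm, adducts, fid
        )
        direction = directions.get(fid, "") if directions is not None else ""
        if hits:
            h = hits[0]
            rows.append(
                (fid, row["mz"], direction, h.record.hmdb_id, h.level,
                 h.record.name, h.adduct, h.ppm_error)
            )
        else:
            rows.append((fid, row["mz"], direction, "", 3, "", "", np.nan))
    return pd.DataFrame(
        rows,
        columns=["feature_id", "mz", "direction", "hmdb_id", "level",
                 "annotation", "adduct", "ppm_error"],
    ).set_index("feature_id")
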