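"""Feature-table container shared by every pipeline stage.

A :class:`FeatureTable` couples a samples x features intensity matrix with
per-feature metadata (m/z, retention time, ionization mode) and per-sample
metadata (group, sample type, nominal dilution).  Missing intensities are
NaN.  All stages consume and return this object (or plain DataFrames once
feature identities are fixed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GROUPS = ("case", "control", "none")
SAMPLE_TYPES = ("study", "QC", "blank")
ION_MODES = ("POS", "NEG")


class FeatureTableError(ValueError):
    """Raised when a feature table violates its structural invariants."""


@dataclass
class FeatureTable:
    """Samples x features intensity matrix plus metadata.

    Parameters
    ----------
    intensities : DataFrame
        Non-negative intensities, index = sample_id, columns = feature_id.
        NaN marks a missing (undetected) value.
    feature_meta : DataFrame
        Index = feature_id; columns ``mz`` (Da), ``rt`` (minutes),
        ``ion_mode`` ("POS"/"NEG").
    sample_meta : DataFrame
        Index = sample_id; columns ``group`` ("case"/"control"/"none"),
        ``sample_type`` ("study"/"QC"/"blank"), ``nominal_dilution``
        (fraction, NaN when not applicable).
    log_scale : bool
        True once intensities have been log-transformed (lifts the
        non-negativity invariant).
    """

    intensities: pd.DataFrame
    feature_meta: pd.DataFrame
    sample_meta: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        ints, fmeta, smeta = self.intensities, self.feature_meta, self.sample_meta
        if ints.shape[0] != smeta.shape[0]:
            raise FeatureTableError(
                f"{ints.shape[0]} intensity rows but {smeta.shape[0]} sample records"
            )
        if ints.shape[1] != fmeta.shape[0]:
            raise FeatureTableError(
                f"{ints.shape[1]} intensity columns but {fmeta.shape[0]} feature records"
            )
        if not ints.index.equals(smeta.index):
            raise FeatureTableError("intensity index does not match sample_meta index")
        if not ints.columns.equals(fmeta.index):
            raise FeatureTableError("intensity columns do not match feature_meta index")
        if ints.index.has_duplicates:
            raise FeatureTableError("duplicate sample_ids")
        if ints.columns.has_duplicates:
            raise FeatureTableError("duplicate feature_ids")
        if "mz" in fmeta.columns and (fmeta["mz"] <= 0).any():
            bad = fmeta.index[fmeta["mz"] <= 0].tolist()
            raise FeatureTableError(f"non-positive m/z for features {bad[:5]}")
        if not self.log_scale:
            with np.errstate(invalid="ignore"):
                if (ints.to_numpy(dtype=float) < 0).any():
                    raise FeatureTableError("negative intensities")

    # -- convenience selectors -----------------------------------------
    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def study_mask(self) -> pd.Series:
        return self.sample_meta["sample_type"] == "study"

    @property
    def qc_mask(self) -> pd.Series:
        return self.sample_meta["sample_type"] == "QC"

    def study(self) -> "FeatureTable":
        """Restrict to study samples."""
        return self.select_samples(self.study_mask[self.study_mask].index)

    def groups(self) -> pd.Series:
        """Group labels of study samples."""
        return self.sample_meta.loc[self.study_mask, "group"]

    def select_samples(self, sample_ids) -> "FeatureTable":
        return FeatureTable(
            self.intensities.loc[sample_ids],
            self.feature_meta.copy(),
            self.sample_meta.loc[sample_ids],
            self.log_scale,
        )

    def select_features(self, feature_ids) -> "FeatureTable":
        return FeatureTable(
            self.intensities.loc[:, feature_ids],
            self.feature_meta.loc[feature_ids],
            self.sample_meta.copy(),
            self.log_scale,
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(),
            self.feature_meta.copy(),
            self.sample_meta.copy(),
            self.log_scale,
        )

    # -- IO ------------------------------------------------------------
    def to_csv(self, prefix: str | Path) -> dict[str, Path]:
        """Write the CSV trio ``<prefix>_intensities/_features/_samples.csv``."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "intensities": prefix.with_name(prefix.name + "_intensities.csv"),
            "features": prefix.with_name(prefix.name + "_features.csv"),
            "samples": prefix.with_name(prefix.name + "_samples.csv"),
            "meta": prefix.with_name(prefix.name + "_table.json"),
        }
        self.intensities.to_csv(paths["intensities"], index_label="sample_id")
        self.feature_meta.to_csv(paths["features"], index_label="feature_id")
        self.sample_meta.to_csv(paths["samples"], index_label="sample_id")
        paths["meta"].write_text(json.dumps({"log_scale": self.log_scale}))
        return paths

    @classmethod
    def from_csv(cls, prefix: str | Path) -> "FeatureTable":
        prefix = Path(prefix)
        # round_trip parsing keeps re-saved tables byte-identical (provenance)
        ints = pd.read_csv(
            prefix.with_name(prefix.name + "_intensities.csv"),
            index_col="sample_id", float_precision="round_trip",
        )
        fmeta = pd.read_csv(
            prefix.with_name(prefix.name + "_features.csv"),
            index_col="feature_id", float_precision="round_trip",
        )
        smeta = pd.read_csv(
            prefix.with_name(prefix.name + "_samples.csv"),
            index_col="sample_id", float_precision="round_trip",
        )
        meta_path = prefix.with_name(prefix.name + "_table.json")
        log_scale = False
        if meta_path.exists():
            log_scale = bool(json.loads(meta_path.read_text()).get("log_scale", False))
        ints.columns.name = fmeta.index.name
        return cls(ints, fmeta, smeta.loc[ints.index], log_scale)

    def content_digest(self) -> str:
        """Stable sha256 digest of the table contents (provenance)."""
        h = hashlib.sha256()
        for df in (self.intensities, self.feature_meta, self.sample_meta):
            h.update(df.to_csv().encode())
        return h.hexdigest()[:16]


def config_hash(obj) -> str:
    """Short sha256 of a JSON-serializable configuration object."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
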