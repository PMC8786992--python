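"""Long-format feature tables: validation, I/O and per-feature matrices.

The canonical on-disk layout is tidy CSV: one row per
``(patient_id, setting, feature)`` value, plus a one-row-per-patient metadata
CSV. Missing cells are tolerated at I/O time and resolved per analysis by
complete-case selection within the requested setting subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .design import (
    FeatureDescriptor,
    PatientRecord,
    ReconstructionDesign,
    VOLUME_LIKE_NAMES,
    parse_feature_name,
)

__all__ = ["FeatureTable", "read_feature_table", "write_feature_table"]

VALUE_COLUMNS = ("patient_id", "setting", "feature", "value")
METADATA_BASE_COLUMNS = ("patient_id", "scanner", "tube_voltage", "tumour_volume_cm3")


@dataclass
class FeatureTable:
    """Patients x settings x features value store with patient metadata.

    Attributes
    ----------
    design : ReconstructionDesign
    values : pandas.DataFrame
        Long-format values with columns ``patient_id, setting, feature, value``.
    metadata : pandas.DataFrame
        One row per patient, indexed by ``patient_id``.
    features : list of FeatureDescriptor
    """

    design: ReconstructionDesign
    values: pd.DataFrame
    metadata: pd.DataFrame
    features: list[FeatureDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()
        # wide cube: rows = patients, columns = (feature, setting)
        self._cube = self.values.pivot(
            index="patient_id", columns=["feature", "setting"], values="value"
        ).sort_index()

    # ------------------------------------------------------------------ #
    def _validate(self) -> None:
        vals = self.values
        missing_cols = [c for c in VALUE_COLUMNS if c not in vals.columns]
        if missing_cols:
            raise ValueError(f"values table lacks columns {missing_cols}")
        unknown = sorted(set(vals["setting"]) - set(self.design.setting_labels))
        if unknown:
            raise ValueError(
                f"unknown setting label(s) {unknown}; design has "
                f"{list(self.design.setting_labels)}"
            )
        dup = vals.duplicated(subset=["patient_id", "setting", "feature"])
        if dup.any():
            first = vals.loc[dup, ["patient_id", "setting", "feature"]].iloc[0]
            raise ValueError(
                "duplicated (patient, setting, feature) key: "
                f"{tuple(first)} (and {int(dup.sum()) - 1} more)"
            )
        bad = ~np.isfinite(pd.to_numeric(vals["value"], errors="coerce"))
        if bad.any():
            idx = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"non-numeric feature value at row {idx}")
        unknown_pat = sorted(set(vals["patient_id"]) - set(self.metadata.index))
        if unknown_pat:
            raise ValueError(f"values reference unknown patient(s) {unknown_pat[:5]}")
        if not self.features:
            self.features = [
                parse_feature_name(n) for n in sorted(vals["feature"].unique())
            ]
        declared = {f.name for f in self.features}
        undeclared = sorted(set(vals["feature"]) - declared)
        if undeclared:
            raise ValueError(f"values reference undeclared feature(s) {undeclared[:5]}")

    # ------------------------------------------------------------------ #
    @property
    def patient_ids(self) -> list[str]:
        return list(self.metadata.index)

    @property
    def feature_names(self) -> list[str]:
        return [f.name for f in self.features]

    @property
    def patients(self) -> list[PatientRecord]:
        recs = []
        extra_cols = [c for c in self.metadata.columns if c not in METADATA_BASE_COLUMNS]
        for pid, row in self.metadata.iterrows():
            recs.append(
                PatientRecord(
                    patient_id=str(pid),
                    scanner=str(row["scanner"]),
                    tube_voltage=str(row["tube_voltage"]),
                    tumour_volume_cm3=float(row["tumour_volume_cm3"]),
                    extra_covariates={c: row[c] for c in extra_cols},
                )
            )
        return recs

    def descriptor(self, feature: str) -> FeatureDescriptor:
        for f in self.features:
            if f.name == feature:
                return f
        raise KeyError(feature)

    @property
    def n_missing(self) -> int:
        """Count of absent (patient, setting, feature) cells vs the full grid."""
        full = (
            len(self.metadata) * len(self.design.setting_labels) * len(self.features)
        )
        return full - len(self.values)

    # ------------------------------------------------------------------ #
    def feature_matrix(
        self, feature: str, settings: Sequence[str] | None = None
    ) -> tuple[np.ndarray, list[str]]:
        """Patients x settings value matrix for one feature.

        Rows are the patients having *all* requested settings (complete-case
        within the subset); column order follows ``settings``.

        Returns
        -------
        (matrix, patient_ids)
        """
        if settings is None:
            settings = self.design.setting_labels
        settings = list(settings)
        unknown = [s for s in settings if s not in self.design.setting_labels]
        if unknown:
            raise ValueError(f"settings {unknown} not in design")
        if feature not in self._cube.columns.get_level_values(0):
            raise KeyError(f"feature {feature!r} not in table")
        sub = self._cube[feature]
        missing_cols = [s for s in settings if s not in sub.columns]
        if missing_cols:
            raise ValueError(
                f"feature {feature!r} has no values for settings {missing_cols}"
            )
        sub = sub[settings].dropna(axis=0, how="any")
        if sub.empty:
            raise ValueError(
                f"feature {feature!r}: no patient has all of {settings}"
            )
        return sub.to_numpy(dtype=float), [str(p) for p in sub.index]

    def long_values(self) -> pd.DataFrame:
        return self.values.copy()

    def with_values(self, new_values: pd.DataFrame) -> "FeatureTable":
        """A new table sharing this table's design/metadata/features."""
        return FeatureTable(
            design=self.design,
            values=new_values.reset_index(drop=True),
            metadata=self.metadata,
            features=list(self.features),
        )


# ---------------------------------------------------------------------- #
def read_feature_table(
    values_path: str | Path,
    metadata_path: str | Path,
    design: ReconstructionDesign,
    volume_like: Iterable[str] = VOLUME_LIKE_NAMES,
) -> FeatureTable:
    """Read and validate a long-format values CSV plus a patient metadata CSV."""
    values = pd.read_csv(
        values_path,
        dtype={"patient_id": str, "setting": str, "feature": str},
        float_precision="round_trip",
    )
    metadata = pd.read_csv(
        metadata_path, dtype={"patient_id": str}, float_precision="round_trip"
    )
    missing_cols = [c for c in METADATA_BASE_COLUMNS if c not in metadata.columns]
    if missing_cols:
        raise ValueError(f"metadata lacks columns {missing_cols}")
    if metadata["patient_id"].duplicated().any():
        raise ValueError("duplicated patient_id in metadata")
    metadata = metadata.set_index("patient_id")
    vol_like = frozenset(volume_like)
    features = [
        parse_feature_name(n, volume_like=vol_like)
        for n in sorted(values["feature"].unique())
    ]
    return FeatureTable(design=design, values=values, metadata=metadata, features=features)


def write_feature_table(
    table: FeatureTable, values_path: str | Path, metadata_path: str | Path
) -> None:
    """Write the long values CSV and metadata CSV (round-trip safe).

    Floats are serialised with :func:`repr` precision so that a write/read
    cycle reproduces values bit-exactly.
    """
    out = table.values.copy()
    out["value"] = [repr(float(v)) for v in out["value"]]
    out.to_csv(values_path, index=False)
    meta = table.metadata.reset_index()
    meta.to_csv(metadata_path, index=False)
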