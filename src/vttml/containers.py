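"""In-memory containers shared by the pipeline stages.

The central object is :class:`FeatureTable`: a patients x features matrix
(pandas DataFrame, NaN marks a missing measurement) together with per-feature
provenance — which marker was measured, from which sample source (blood or
tissue), at which study week, and whether the value is a raw level or a
fold change relative to the patient's own baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

META_COLUMNS = ["marker", "source", "timepoint", "kind"]


@dataclass
class FeatureTable:
    """Patients x features matrix with missingness and per-feature provenance.

    Parameters
    ----------
    values
        DataFrame indexed by patient id, one column per feature. ``NaN``
        encodes a missing measurement.
    meta
        DataFrame indexed by feature name with columns ``marker``,
        ``source`` ("blood"/"tissue"/"clinical"), ``timepoint`` ("week1",
        "week3", ...) and ``kind`` ("level" or "fold_change"). Built
        automatically (kind="level") when omitted.
    """

    values: pd.DataFrame
    meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate patient ids: {dupes}")
        if not self.values.columns.is_unique:
            dupes = self.values.columns[self.values.columns.duplicated()].tolist()
            raise ValidationError(f"duplicate feature names: {dupes}")
        if self.meta is None:
            self.meta = default_meta(self.values.columns)
        missing = self.values.columns.difference(self.meta.index)
        if len(missing):
            raise ValidationError(f"features without metadata: {list(missing)}")
        self.meta = self.meta.loc[self.values.columns, META_COLUMNS]

    # -- basic introspection -------------------------------------------------
    @property
    def patient_ids(self) -> pd.Index:
        return self.values.index

    @property
    def feature_names(self) -> pd.Index:
        return self.values.columns

    @property
    def n_patients(self) -> int:
        return len(self.values)

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missingness indicator (True = missing)."""
        return self.values.isna()

    @property
    def is_complete(self) -> bool:
        return not bool(self.values.isna().to_numpy().any())

    # -- manipulation --------------------------------------------------------
    def copy(self) -> "FeatureTable":
        return FeatureTable(self.values.copy(), self.meta.copy())

    def select_features(self, names) -> "FeatureTable":
        names = list(names)
        return FeatureTable(self.values[names], self.meta.loc[names])

    def select_patients(self, ids) -> "FeatureTable":
        ids = list(ids)
        return FeatureTable(self.values.loc[ids], self.meta)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def default_meta(features, source: str = "blood", timepoint: str = "week1",
                 kind: str = "level") -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker": list(features),
            "source": source,
            "timepoint": timepoint,
            "kind": kind,
        },
        index=pd.Index(features, name="feature"),
    )


def concat_tables(left: FeatureTable, right: FeatureTable) -> FeatureTable:
    """Column-concatenate two tables over identical patient sets."""
    if set(left.patient_ids) != set(right.patient_ids):
        only_l = set(left.patient_ids) - set(right.patient_ids)
        only_r = set(right.patient_ids) - set(left.patient_ids)
        raise ValidationError(
            f"patient id mismatch between tables (left-only={sorted(only_l)}, "
            f"right-only={sorted(only_r)})"
        )
    overlap = left.feature_names.intersection(right.feature_names)
    if len(overlap):
        raise ValidationError(f"duplicate feature names across tables: {list(overlap)}")
    right_vals = right.values.loc[left.patient_ids]
    return FeatureTable(
        pd.concat([left.values, right_vals], axis=1),
        pd.concat([left.meta, right.meta], axis=0),
    )
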