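"""The shared in-memory container for eNose sensor panels.

A :class:`SensorPanel` is a tidy table with one row per fecal sample: a fixed
block of metadata columns (group, disease activity, diet, surgical history,
measurement day, matching covariates) followed by one numeric column per
sensor holding the dimensionless response ΔR/R₀.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import SchemaError, DayVocabularyError

#: canonical metadata column order (metadata first, sensors after)
METADATA_COLUMNS = (
    "sample_id",
    "group",
    "activity",
    "diet",
    "surgery",
    "day",
    "age",
    "sex",
    "smoking",
    "hospital",
)

GROUPS = ("control", "CD", "UC")


def sensor_names(n_sensors: int) -> tuple[str, ...]:
    """Default sensor column names S1..Sn (1-based, instrument convention)."""
    return tuple(f"S{i}" for i in range(1, n_sensors + 1))


@dataclass(frozen=True)
class SensorPanel:
    """Samples × sensors response matrix plus per-sample metadata.

    Parameters
    ----------
    data:
        DataFrame containing all columns in :data:`METADATA_COLUMNS` plus the
        sensor columns. Row order is meaningful and preserved.
    sensor_columns:
        Ordered sensor column names.
    day_vocabulary:
        Ordered measurement-day labels. Defaults to first-appearance order.
    """

    data: pd.DataFrame
    sensor_columns: tuple[str, ...]
    day_vocabulary: tuple[str, ...] = field(default=())

    def __post_init__(self):
        missing = [c for c in METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(f"missing metadata column(s): {missing}")
        missing_s = [c for c in self.sensor_columns if c not in self.data.columns]
        if missing_s:
            raise SchemaError(f"missing sensor column(s): {missing_s}")
        if len(self.sensor_columns) == 0:
            raise SchemaError("panel must declare at least one sensor column")
        resp = self.data[list(self.sensor_columns)]
        if resp.isna().any().any():
            bad = resp.columns[resp.isna().any()].tolist()
            raise SchemaError(f"missing sensor response(s) in column(s): {bad}")
        if not self.data["sample_id"].is_unique:
            raise SchemaError("sample_id values must be unique")
        bad_groups = set(self.data["group"].unique()) - set(GROUPS)
        if bad_groups:
            raise SchemaError(f"unknown group label(s): {sorted(bad_groups)}")
        if not self.day_vocabulary:
            vocab = tuple(pd.unique(self.data["day"].astype(str)))
            object.__setattr__(self, "day_vocabulary", vocab)
        unknown = set(self.data["day"].astype(str)) - set(self.day_vocabulary)
        if unknown:
            raise DayVocabularyError(f"day label(s) outside vocabulary: {sorted(unknown)}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_sensors(self) -> int:
        return len(self.sensor_columns)

    @property
    def responses(self) -> np.ndarray:
        """Response matrix as float ndarray of shape (n_samples, n_sensors)."""
        return self.data[list(self.sensor_columns)].to_numpy(dtype=float)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.data["sample_id"].to_numpy()

    @property
    def days(self) -> np.ndarray:
        return self.data["day"].astype(str).to_numpy()

    @property
    def groups(self) -> np.ndarray:
        return self.data["group"].to_numpy()

    @property
    def is_control(self) -> np.ndarray:
        return self.data["group"].to_numpy() == "control"

    @property
    def case_labels(self) -> np.ndarray:
        """Binary disease labels: 1 for IBD (CD or UC), 0 for control."""
        return (~self.is_control).astype(int)

    # -- functional updates ----------------------------------------------
    def with_responses(self, values: np.ndarray) -> "SensorPanel":
        """Return a copy of the panel with the response matrix replaced."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_samples, self.n_sensors):
            raise SchemaError(
                f"response matrix shape {values.shape} does not match panel "
                f"({self.n_samples}, {self.n_sensors})"
            )
        data = self.data.copy()
        data[list(self.sensor_columns)] = values
        return replace(self, data=data)

    def subset(self, mask: np.ndarray) -> "SensorPanel":
        """Row subset preserving order; `mask` is boolean or positional."""
        data = self.data.loc[np.asarray(mask)] if np.asarray(mask).dtype == bool else self.data.iloc[mask]
        return replace(self, data=data.reset_index(drop=True))

    def metadata(self) -> pd.DataFrame:
        return self.data[list(METADATA_COLUMNS)].copy()

    def to_frame(self) -> pd.DataFrame:
        """Canonical column order: metadata then sensors."""
        return self.data[list(METADATA_COLUMNS) + list(self.sensor_columns)].copy()
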