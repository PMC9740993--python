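"""Panel and artifact I/O.

Canonical panel dialect: comma-separated UTF-8 with period decimals, LF line
endings, metadata columns first then sensor columns. On read the delimiter is
sniffed among comma, semicolon and tab so deposited tables in other dialects
load unchanged. Day labels are opaque ordered categories, never parsed dates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import DayVocabularyError, PanelParseError, SchemaError
from .panel import METADATA_COLUMNS, SensorPanel, sensor_names

log = logging.getLogger("enose_driftlab")


@dataclass(frozen=True)
class PanelSchema:
    """Expected table layout for a sensor panel file."""

    sensor_columns: tuple[str, ...]
    metadata_columns: tuple[str, ...] = METADATA_COLUMNS
    day_labels: tuple[str, ...] | None = None  # None: first-appearance order

    def __post_init__(self):
        if len(self.sensor_columns) == 0:
            raise SchemaError("schema must declare at least one sensor column")
        if len(set(self.sensor_columns)) != len(self.sensor_columns):
            raise SchemaError("sensor column names must be unique")
        if self.day_labels is not None and len(self.day_labels) == 0:
            raise SchemaError("day vocabulary must be non-empty when given")


def default_schema(n_sensors: int = 32, day_labels: tuple[str, ...] | None = None) -> PanelSchema:
    return PanelSchema(sensor_columns=sensor_names(n_sensors), day_labels=day_labels)


def _sniff_delimiter(first_line: str) -> str:
    counts = {d: first_line.count(d) for d in (",", ";", "\t")}
    return max(counts, key=counts.get) if max(counts.values()) > 0 else ","


def read_panel(path, schema: PanelSchema | None = None) -> SensorPanel:
    """Read and validate a delimited sensor-panel table.

    Raises
    ------
    SchemaError
        Missing metadata or sensor columns.
    PanelParseError
        Non-numeric sensor (or age) cell; names the offending row and column.
    DayVocabularyError
        A day label outside the schema's declared vocabulary.
    """
    path = Path(path)
    if schema is None:
        schema = default_schema()
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    delim = _sniff_delimiter(first)
    raw = pd.read_csv(path, sep=delim, dtype=str, keep_default_na=False, encoding="utf-8")

    missing = [c for c in schema.metadata_columns if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing metadata column(s): {missing}")
    missing = [c for c in schema.sensor_columns if c not in raw.columns]
    if missing:
        raise SchemaError(f"missing sensor column(s): {missing}")

    def numeric(col: str) -> np.ndarray:
        # numpy's strtod is decimal-faithful (pandas' fast parser can be 1 ulp off)
        values = raw[col].to_numpy()
        try:
            return values.astype(float)
        except ValueError:
            for row, v in enumerate(values):
                try:
                    float(v)
                except ValueError:
                    raise PanelParseError(row=row, column=col, value=v) from None
            raise

    data = raw[list(schema.metadata_columns)].copy()
    for col in schema.sensor_columns:
        data[col] = numeric(col)
    data["age"] = numeric("age")

    if schema.day_labels is not None:
        unknown = set(data["day"]) - set(schema.day_labels)
        if unknown:
            raise DayVocabularyError(f"unknown day label(s): {sorted(unknown)}")
        vocab = tuple(schema.day_labels)
    else:
        vocab = tuple(pd.unique(data["day"]))
    log.info("read panel: %d samples, %d sensors from %s", len(data), len(schema.sensor_columns), path)
    return SensorPanel(data=data, sensor_columns=tuple(schema.sensor_columns), day_vocabulary=vocab)


def write_panel(panel: SensorPanel, path) -> Path:
    """Write a panel in the canonical dialect; identical panels yield
    identical bytes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = panel.to_frame()
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# generic artifact helpers (deterministic byte output)
# ---------------------------------------------------------------------------

def write_json(obj, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return path


def read_json(path):
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", encoding="utf-8")
    return path


def read_yaml(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        out = yaml.safe_load(fh)
    return out or {}


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
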