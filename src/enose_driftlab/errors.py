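"""Exception hierarchy for the drift-lab pipeline.

Every guarded failure mode raises a dedicated subclass of
:class:`DriftLabError` so callers (and the CLI) can map failures to stages.
"""

from __future__ import annotations


class DriftLabError(Exception):
    """Base class for all package errors."""


class ConfigError(DriftLabError):
    """Inconsistent or invalid configuration (e.g. vector length mismatch)."""


class InvalidBaselineError(DriftLabError):
    """Baseline resistance R0 must be strictly positive."""


class UnmatchableCaseError(DriftLabError):
    """A case has no remaining control with identical categorical covariates."""

    def __init__(self, case_id: str, message: str | None = None):
        self.case_id = case_id
        super().__init__(message or f"no exact categorical match available for case {case_id!r}")


class SchemaError(DriftLabError):
    """Input table does not conform to the declared panel schema."""


class PanelParseError(DriftLabError):
    """A cell failed to parse; carries row index and column name."""

    def __init__(self, row: int, column: str, value: object):
        self.row = row
        self.column = column
        self.value = value
        super().__init__(f"non-numeric value {value!r} in column {column!r}, row {row}")


class DayVocabularyError(DriftLabError):
    """A day label is outside the declared day vocabulary."""


class DegenerateSensorError(DriftLabError):
    """A sensor column is constant where variation is required."""

    def __init__(self, sensors, message: str | None = None):
        self.sensors = list(sensors)
        super().__init__(message or f"degenerate (zero-variance) sensor column(s): {self.sensors}")


class UndefinedCorrelationError(DegenerateSensorError):
    """Correlation undefined because at least one sensor is constant."""


class InsufficientDayError(DriftLabError):
    """A measurement day has too few samples for the requested diagnostic."""


class ParameterError(DriftLabError):
    """An operation parameter is out of range (e.g. invalid component count)."""


class UncoveredDayError(DriftLabError):
    """A day label has no control samples / is not covered by the drift model."""

    def __init__(self, days, message: str | None = None):
        self.days = list(days)
        super().__init__(message or f"day(s) without control coverage: {self.days}")


class NearZeroMeanError(DriftLabError):
    """Relative drift correction undefined: per-sensor control mean near zero."""

    def __init__(self, sensors, message: str | None = None):
        self.sensors = list(sensors)
        super().__init__(
            message or f"near-zero control mean for sensor(s) {self.sensors}; relative mode undefined"
        )


class SingularCorrectionError(DriftLabError):
    """A relative correction factor 1 + d is (numerically) zero."""


class GroupingError(DriftLabError):
    """A two-group comparison received an empty or invalid group."""


class DegenerateVarianceError(DriftLabError):
    """Welch t statistic undefined: both groups have zero variance but differ."""


class LabelError(DriftLabError):
    """Classification labels invalid (e.g. a class entirely absent)."""


class FoldError(DriftLabError):
    """A cross-validation training fold lost one of the classes."""


class DegenerateCutoffError(DriftLabError):
    """All predicted probabilities identical; no cut-off can be optimized."""


class IncompatibleRunsError(DriftLabError):
    """Two pipeline runs cannot be compared (different input panels)."""


class PipelineStageError(DriftLabError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
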