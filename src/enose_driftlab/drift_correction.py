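"""Control-based per-sensor per-day drift estimation and correction.

The correction assumes control samples (endoscopically normal subjects) have
no systematic day-to-day difference in fecal VOC composition, so any day
structure in their sensor responses is instrument drift. For sensor j and
measurement day d the model records the mean relative deviation of the
control day-mean from the overall control mean,

    mu_j  = mean over all control samples of sensor j
    d_jd  = (mean over controls on day d of sensor j - mu_j) / mu_j

and every sample measured on day d is corrected by

    relative mode (default):  x'_ij = x_ij / (1 + d_j,day(i))
    additive mode:            x'_ij = x_ij - mu_j * d_j,day(i)

After correction the per-day control means are exactly equal for every
sensor, in either mode — the method's defining algebraic property. The
common-drift-direction assumption (rank-1 drift, d = a g^T) is used only by
the simulator and by an optional diagnostic; the estimator itself is a free
per-sensor per-day table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import (
    NearZeroMeanError,
    ParameterError,
    SingularCorrectionError,
    UncoveredDayError,
)
from .panel import SensorPanel

#: scale-aware guard on |mu_j| in relative mode: eps = MEAN_EPS_FACTOR * control sd_j
MEAN_EPS_FACTOR = 1e-8
#: guard on |1 + d| in relative mode
SINGULAR_EPS = 1e-6


@dataclass(frozen=True)
class DriftModel:
    """Fitted per-sensor control means and per-day relative deviations."""

    mu: np.ndarray                      # (n_sensors,)
    dev: np.ndarray                     # (n_sensors, n_days), relative deviations
    delta: np.ndarray                   # (n_sensors, n_days), absolute deviations mu*dev
    mode: str                           # "relative" | "additive"
    day_vocabulary: tuple[str, ...]
    control_counts: np.ndarray          # (n_days,) controls per day
    sensors: tuple[str, ...]
    pooled_days: tuple[str, ...] = ()   # days whose deviation was borrowed

    @property
    def n_sensors(self) -> int:
        return len(self.mu)

    @property
    def n_days(self) -> int:
        return len(self.day_vocabulary)

    def day_column(self, day: str) -> np.ndarray:
        try:
            idx = self.day_vocabulary.index(day)
        except ValueError:
            raise UncoveredDayError([day]) from None
        return self.dev[:, idx]

    def rank1_share(self) -> float:
        """Fraction of the deviation table's energy on its first singular
        direction; near 1 under common-direction (rank-1) drift."""
        s = np.linalg.svd(self.dev, compute_uv=False)
        total = float(np.sum(s**2))
        return float(s[0] ** 2 / total) if total > 0 else 1.0

    def to_jsonable(self) -> dict:
        return {
            "mu": self.mu.tolist(),
            "dev": self.dev.tolist(),
            "delta": self.delta.tolist(),
            "mode": self.mode,
            "day_vocabulary": list(self.day_vocabulary),
            "control_counts": self.control_counts.tolist(),
            "sensors": list(self.sensors),
            "pooled_days": list(self.pooled_days),
        }


class DriftCorrector(BaseEstimator, TransformerMixin):
    """Scikit-learn style transformer for control-based day correction.

    Parameters
    ----------
    mode:
        "relative" (divide by 1 + d) or "additive" (subtract mu * d).
    pool_adjacent:
        If True, a day without controls borrows the nearest covered day's
        deviations (vocabulary order, earlier day on ties) instead of
        raising. Off by default: silently extrapolating drift is the exact
        failure mode the correction exists to prevent.

    Fit requires per-sample day labels and a control mask; both are passed
    as keyword arguments so the transformer stays usable on bare matrices::

        corr = DriftCorrector().fit(X, day=days, control=is_control)
        X_corrected = corr.transform(X, day=days)

    Fitted attributes: ``mu_``, ``dev_``, ``day_vocabulary_``,
    ``control_counts_``, ``model_``.
    """

    def __init__(self, mode: str = "relative", pool_adjacent: bool = False):
        self.mode = mode
        self.pool_adjacent = pool_adjacent

    # -- estimation ------------------------------------------------------
    def fit(self, X, y=None, *, day, control, day_vocabulary=None, sensors=None):
        if self.mode not in ("relative", "additive"):
            raise ParameterError(f"unknown correction mode {self.mode!r}")
        X = np.asarray(X, dtype=float)
        day = np.asarray(day).astype(str)
        control = np.asarray(control, dtype=bool)
        if X.ndim != 2 or len(day) != len(X) or len(control) != len(X):
            raise ParameterError("X, day and control must agree on n_samples")
        vocab = tuple(day_vocabulary) if day_vocabulary is not None else tuple(pd.unique(day))
        n_sensors = X.shape[1]
        sensors = tuple(sensors) if sensors is not None else tuple(f"S{i+1}" for i in range(n_sensors))

        ctrl = X[control]
        ctrl_day = day[control]
        counts = np.array([(ctrl_day == d).sum() for d in vocab])
        uncovered = [d for d, c in zip(vocab, counts) if c == 0]
        if uncovered and not self.pool_adjacent:
            raise UncoveredDayError(uncovered)
        if ctrl.shape[0] == 0:
            raise UncoveredDayError(list(vocab), "no control samples in panel")

        mu = ctrl.mean(axis=0)
        sd = ctrl.std(axis=0, ddof=1) if ctrl.shape[0] > 1 else np.zeros(n_sensors)
        if self.mode == "relative":
            eps = MEAN_EPS_FACTOR * sd
            bad = np.flatnonzero(np.abs(mu) <= eps)
            if bad.size:
                raise NearZeroMeanError([sensors[i] for i in bad])

        delta = np.zeros((n_sensors, len(vocab)))
        for k, d in enumerate(vocab):
            if counts[k] > 0:
                delta[:, k] = ctrl[ctrl_day == d].mean(axis=0) - mu
        pooled = []
        if uncovered:
            covered = [k for k in range(len(vocab)) if counts[k] > 0]
            for k, d in enumerate(vocab):
                if counts[k] == 0:
                    nearest = min(covered, key=lambda c: (abs(c - k), c))
                    delta[:, k] = delta[:, nearest]
                    pooled.append(d)
        # relative deviations; left at 0 where mu ~ 0 (additive mode only,
        # where only delta = mu*dev enters the correction)
        safe = np.abs(mu) > 0
        dev = np.divide(delta, mu[:, None], out=np.zeros_like(delta), where=safe[:, None])

        self.mu_ = mu
        self.dev_ = dev
        self.day_vocabulary_ = vocab
        self.control_counts_ = counts
        self.model_ = DriftModel(
            mu=mu,
            dev=dev,
            delta=delta,
            mode=self.mode,
            day_vocabulary=vocab,
            control_counts=counts,
            sensors=sensors,
            pooled_days=tuple(pooled),
        )
        return self

    # -- correction ------------------------------------------------------
    def transform(self, X, *, day):
        if not hasattr(self, "model_"):
            raise ParameterError("DriftCorrector is not fitted")
        return _apply_model(np.asarray(X, dtype=float), np.asarray(day).astype(str), self.model_)


def _apply_model(X: np.ndarray, day: np.ndarray, model: DriftModel) -> np.ndarray:
    if X.shape[1] != model.n_sensors:
        raise ParameterError(
            f"panel has {X.shape[1]} sensors but model was fitted on {model.n_sensors}"
        )
    unseen = sorted(set(day) - set(model.day_vocabulary))
    if unseen:
        raise UncoveredDayError(unseen)
    idx = np.array([model.day_vocabulary.index(d) for d in day])
    if model.mode == "relative":
        dev = model.dev[:, idx].T  # (n_samples, n_sensors)
        denom = 1.0 + dev
        if np.any(np.abs(denom) <= SINGULAR_EPS):
            raise SingularCorrectionError("correction factor 1 + d is numerically zero")
        return X / denom
    return X - model.delta[:, idx].T


# ---------------------------------------------------------------------------
# panel-level functional surface
# ---------------------------------------------------------------------------

def fit_drift(
    panel: SensorPanel,
    control_selector: str | Callable[[pd.DataFrame], np.ndarray] = "control",
    mode: str = "relative",
    pool_adjacent: bool = False,
) -> DriftModel:
    """Fit the drift model on the panel's control samples.

    ``control_selector`` is a group label (default ``"control"``) or a
    predicate mapping the metadata frame to a boolean mask. Only control
    samples enter the fit; case samples never influence it.
    """
    if callable(control_selector):
        mask = np.asarray(control_selector(panel.data), dtype=bool)
    else:
        mask = panel.groups == control_selector
    corr = DriftCorrector(mode=mode, pool_adjacent=pool_adjacent)
    corr.fit(
        panel.responses,
        day=panel.days,
        control=mask,
        day_vocabulary=panel.day_vocabulary,
        sensors=panel.sensor_columns,
    )
    return corr.model_


def apply_correction(
    panel: SensorPanel, model: DriftModel, restrict_to_cases: bool = False
) -> SensorPanel:
    """Return a corrected copy of the panel; metadata unchanged.

    By default both cases and controls are corrected (a joint classifier
    needs all samples on the same footing); ``restrict_to_cases`` leaves
    control responses untouched.
    """
    corrected = _apply_model(panel.responses, panel.days, model)
    if restrict_to_cases:
        corrected = np.where(panel.is_control[:, None], panel.responses, corrected)
    return panel.with_responses(corrected)


def correction_report(model: DriftModel) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summaries of the fitted deviations.

    Returns (per_sensor, per_day): per sensor the range of d across days and
    the day of maximum |d|; per day the mean |d| across sensors.
    """
    rng = model.dev.max(axis=1) - model.dev.min(axis=1)
    argmax = np.abs(model.dev).argmax(axis=1)
    per_sensor = pd.DataFrame(
        {
            "sensor": list(model.sensors),
            "dev_range": rng,
            "day_of_max_abs_dev": [model.day_vocabulary[i] for i in argmax],
        }
    )
    per_day = pd.DataFrame(
        {
            "day": list(model.day_vocabulary),
            "mean_abs_dev": np.abs(model.dev).mean(axis=0),
            "n_controls": model.control_counts,
        }
    )
    return per_sensor, per_day
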