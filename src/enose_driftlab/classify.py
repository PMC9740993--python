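"""Logistic classification of IBD vs control with leave-one-out
cross-validation, cut-off optimization and diagnostic metrics.

The positive class is IBD (probability orientation P(IBD)); a sample is
called positive when its out-of-fold probability is at or above the cut-off.
The default ``fixed`` selection policy uses one sensor subset, selected on
the full data, in every fold — the small-cohort practice this pipeline
mirrors, which carries an optimistic selection bias. The ``nested`` policy
re-selects sensors inside every training fold and is the leakage-free
alternative; their gap on null data is itself a useful diagnostic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .errors import (
    DegenerateCutoffError,
    FoldError,
    LabelError,
    ParameterError,
)
from .group_stats import select_sensors, test_sensors
from .panel import SensorPanel

log = logging.getLogger("enose_driftlab")

_ETA_SEPARATION = 30.0  # |linear predictor| beyond which fits are saturated


class IRLSLogisticRegression(BaseEstimator, ClassifierMixin):
    """Maximum-likelihood logistic regression by iteratively reweighted
    least squares.

    Converges when the maximum absolute coefficient change drops below
    ``tol`` (default 1e-8) or after ``max_iter`` (default 100) iterations.
    Complete or quasi-complete separation is detected (diverging linear
    predictor with a perfectly classified training set) and flagged via
    ``separation_``; coefficients and probabilities from the last iterate
    are still returned.

    Fitted attributes: ``intercept_``, ``coef_``, ``converged_``,
    ``separation_``, ``llf_`` (log-likelihood, <= 0), ``n_iter_``.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 100):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y).astype(float)
        classes = np.unique(y)
        if not np.array_equal(classes, [0.0, 1.0]):
            raise LabelError(f"need both classes 0 and 1, got {classes.tolist()}")
        n, p = X.shape
        design = np.column_stack([np.ones(n), X])
        b = np.zeros(p + 1)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            eta = design @ b
            prob = expit(eta)
            w = np.clip(prob * (1.0 - prob), 1e-10, None)
            z = eta + (y - prob) / w
            wd = design * w[:, None]
            try:
                b_new = np.linalg.solve(design.T @ wd, wd.T @ z)
            except np.linalg.LinAlgError:
                b_new = np.linalg.lstsq(design.T @ wd, wd.T @ z, rcond=None)[0]
            delta = np.max(np.abs(b_new - b))
            b = b_new
            if delta < self.tol:
                converged = True
                break
        eta = design @ b
        prob = expit(eta)
        train_acc = np.mean((prob >= 0.5) == (y == 1.0))
        self.separation_ = bool(not converged and np.max(np.abs(eta)) > _ETA_SEPARATION and train_acc == 1.0)
        if self.separation_:
            log.warning("perfect separation detected; coefficients from last IRLS iterate")
        self.converged_ = converged
        self.n_iter_ = it
        self.intercept_ = float(b[0])
        self.coef_ = b[1:].copy()
        pc = np.clip(prob, 1e-300, 1 - 1e-16)
        self.llf_ = float(np.sum(y * np.log(pc) + (1.0 - y) * np.log1p(-pc)))
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p1 = expit(self.decision_function(X))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass(frozen=True)
class LogisticModel:
    """Fitted logistic model on a sensor subset."""

    intercept: float
    coefficients: dict[str, float]
    converged: bool
    separation: bool
    log_likelihood: float


@dataclass(frozen=True)
class CVPrediction:
    sample_id: str
    label: int                  # IBD=1, control=0
    probability: float          # out-of-fold P(IBD)


def fit_logistic(panel: SensorPanel, sensor_subset: list[str], labels=None) -> LogisticModel:
    """Fit the logistic model P(IBD | selected sensors) on the full panel.

    An empty subset yields the intercept-only model.
    """
    y = np.asarray(labels if labels is not None else panel.case_labels).astype(int)
    unknown = [s for s in sensor_subset if s not in panel.sensor_columns]
    if unknown:
        raise ParameterError(f"unknown sensor(s): {unknown}")
    X = panel.data[list(sensor_subset)].to_numpy(dtype=float) if sensor_subset else np.empty((panel.n_samples, 0))
    est = IRLSLogisticRegression().fit(X, y)
    return LogisticModel(
        intercept=est.intercept_,
        coefficients=dict(zip(sensor_subset, est.coef_)),
        converged=est.converged_,
        separation=est.separation_,
        log_likelihood=est.llf_,
    )


def loocv_predict(
    panel: SensorPanel,
    sensor_subset: list[str] | None,
    labels=None,
    selection_policy: str = "fixed",
    method: str = "mann_whitney",
    alpha: float = 0.05,
    adjust: str = "none",
) -> list[CVPrediction]:
    """Leave-one-out out-of-fold probabilities of IBD.

    ``fixed`` uses ``sensor_subset`` in every fold (selection done once,
    outside the folds; optimistic when the subset was chosen on the full
    data). ``nested`` re-runs testing + selection inside each training fold;
    folds whose selection is empty fall back to the intercept-only model.
    """
    if selection_policy not in ("fixed", "nested"):
        raise ParameterError(f"unknown selection policy {selection_policy!r}")
    y = np.asarray(labels if labels is not None else panel.case_labels).astype(int)
    n = panel.n_samples
    if n < 10:
        raise ParameterError("leave-one-out needs at least 10 samples")
    if y.sum() == 0 or y.sum() == n:
        raise LabelError("both classes must be present")
    if selection_policy == "fixed":
        if sensor_subset is None:
            raise ParameterError("fixed policy requires a sensor subset")
        log.warning(
            "fixed selection policy: sensor subset chosen outside the folds; "
            "out-of-fold metrics carry selection bias (use nested to avoid)"
        )
    ids = panel.sample_ids
    preds: list[CVPrediction] = []
    for i in range(n):
        train = np.ones(n, dtype=bool)
        train[i] = False
        if y[train].sum() in (0, train.sum()):
            raise FoldError(f"training fold without both classes when holding out {ids[i]!r}")
        sub_panel = panel.subset(train)
        if selection_policy == "nested":
            results = test_sensors(sub_panel, labels=y[train], method=method)
            subset_i = select_sensors(results, alpha=alpha, adjust=adjust)
        else:
            subset_i = list(sensor_subset)
        Xtr = (
            sub_panel.data[list(subset_i)].to_numpy(dtype=float)
            if subset_i
            else np.empty((int(train.sum()), 0))
        )
        est = IRLSLogisticRegression().fit(Xtr, y[train])
        if subset_i:
            xte = panel.data.iloc[[i]][list(subset_i)].to_numpy(dtype=float)
        else:
            xte = np.empty((1, 0))
        p1 = float(est.predict_proba(xte)[0, 1])
        preds.append(CVPrediction(sample_id=str(ids[i]), label=int(y[i]), probability=p1))
    return preds


def optimal_cutoff(predictions: list[CVPrediction], criterion: str = "youden") -> float:
    """Probability cut-off maximizing Youden's J (default) or accuracy.

    Candidates are the midpoints between adjacent sorted unique
    probabilities plus 0.5; ties are broken toward the candidate nearest
    0.5 (then the smaller value).
    """
    if criterion not in ("youden", "accuracy"):
        raise ParameterError(f"unknown criterion {criterion!r}")
    y = np.array([p.label for p in predictions])
    prob = np.array([p.probability for p in predictions])
    if y.sum() == 0 or y.sum() == len(y):
        raise LabelError("both classes must be present")
    uniq = np.unique(prob)
    if len(uniq) == 1:
        raise DegenerateCutoffError("all predicted probabilities identical")
    candidates = set((uniq[:-1] + uniq[1:]) / 2.0)
    candidates.add(0.5)
    best = None
    for c in sorted(candidates):
        if not (0.0 < c < 1.0):
            continue
        pred = prob >= c
        tp = int(np.sum(pred & (y == 1)))
        tn = int(np.sum(~pred & (y == 0)))
        if criterion == "youden":
            value = tp / y.sum() + tn / (len(y) - y.sum()) - 1.0
        else:
            value = (tp + tn) / len(y)
        key = (-value, abs(c - 0.5), c)
        if best is None or key < best[0]:
            best = (key, c)
    return float(best[1])


@dataclass(frozen=True)
class ClassificationReport:
    """Confusion counts at a cut-off plus threshold-free calibration."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    brier: float
    squared_errors: tuple[float, ...] = field(default=(), repr=False)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def rounded(self) -> dict:
        """Headline metrics at the 2-decimal reporting convention."""
        return {
            k: round(getattr(self, k), 2)
            for k in ("accuracy", "sensitivity", "specificity", "ppv", "npv", "brier")
        }

    def to_jsonable(self) -> dict:
        return {
            "cutoff": self.cutoff,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "brier": self.brier,
            "rounded": self.rounded(),
        }

    @classmethod
    def from_counts(cls, tp: int, fp: int, tn: int, fn: int, cutoff: float = 0.5) -> "ClassificationReport":
        """Metrics from a confusion matrix alone (Brier undefined: NaN)."""
        n = tp + fp + tn + fn
        return cls(
            cutoff=cutoff,
            tp=tp,
            fp=fp,
            tn=tn,
            fn=fn,
            accuracy=(tp + tn) / n,
            sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
            specificity=tn / (tn + fp) if tn + fp else float("nan"),
            ppv=tp / (tp + fp) if tp + fp else float("nan"),
            npv=tn / (tn + fn) if tn + fn else float("nan"),
            brier=float("nan"),
        )


def evaluate(predictions: list[CVPrediction], cutoff: float) -> ClassificationReport:
    """Confusion counts, accuracy/sensitivity/specificity/PPV/NPV and Brier
    score at the given cut-off (positive call: probability >= cutoff).

    The Brier score, mean (p - y)^2, does not depend on the cut-off.
    """
    if not predictions:
        raise ParameterError("predictions must be non-empty")
    if not (0.0 < cutoff < 1.0):
        raise ParameterError(f"cutoff must be in (0, 1), got {cutoff}")
    y = np.array([p.label for p in predictions])
    prob = np.array([p.probability for p in predictions])
    if np.any((prob < 0) | (prob > 1)):
        raise ParameterError("probabilities must lie in [0, 1]")
    pred = prob >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sq = (prob - y) ** 2
    rep = ClassificationReport.from_counts(tp=tp, fp=fp, tn=tn, fn=fn, cutoff=cutoff)
    return ClassificationReport(
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=rep.accuracy,
        sensitivity=rep.sensitivity,
        specificity=rep.specificity,
        ppv=rep.ppv,
        npv=rep.npv,
        brier=float(sq.mean()),
        squared_errors=tuple(float(v) for v in sq),
    )
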