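"""Per-sensor two-group comparisons and discriminating-sensor selection.

Default test is the two-sided Mann-Whitney U (exact null enumeration for
small groups, normal approximation with tie and continuity correction
otherwise); Welch's t is available as a parametric alternative. Selection
keeps sensors with (optionally Benjamini-Hochberg adjusted) p below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateVarianceError, GroupingError, ParameterError
from .panel import SensorPanel

EXACT_MAX_N = 8  # exact enumeration when both groups are at most this size


@dataclass(frozen=True)
class GroupTestResult:
    sensor: str
    method: str
    statistic: float
    p_value: float
    mean_case: float
    mean_control: float
    median_case: float
    median_control: float
    n_case: int
    n_control: int


def _mw_exact_enumeration(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney p by enumerating all group assignments.

    Used for small groups with ties, where the distribution-free tables do
    not apply; p is the null fraction of assignments whose U deviates from
    n1*n2/2 at least as much as the observed U.
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    center = n1 * len(y) / 2
    dev_obs = abs(u_obs - center)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        count += abs(u - center) >= dev_obs - 1e-12
        total += 1
    return float(u_obs), count / total


def _mann_whitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0.0:  # all values tied across both groups
        return float(len(x) * len(y) / 2), 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N:
        if has_ties:
            return _mw_exact_enumeration(x, y)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(x) < 2 or len(y) < 2:
        raise GroupingError("Welch t requires at least 2 samples per group")
    if np.ptp(np.concatenate([x, y])) == 0.0:
        return 0.0, 1.0
    if x.std(ddof=1) == 0.0 and y.std(ddof=1) == 0.0:
        raise DegenerateVarianceError(
            "both groups have zero variance with different means; t statistic infinite"
        )
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def test_sensors(
    panel: SensorPanel,
    labels: np.ndarray | None = None,
    method: str = "mann_whitney",
) -> list[GroupTestResult]:
    """Two-sided per-sensor comparison of cases vs controls.

    ``labels`` defaults to the panel's disease labels (IBD=1, control=0).
    """
    if method not in ("mann_whitney", "welch_t"):
        raise ParameterError(f"unknown test method {method!r}")
    y = np.asarray(labels if labels is not None else panel.case_labels).astype(int)
    if len(y) != panel.n_samples:
        raise GroupingError("labels length does not match panel")
    if y.sum() == 0 or y.sum() == len(y):
        raise GroupingError("both groups must be non-empty")
    x = panel.responses
    stat_fn = _mann_whitney if method == "mann_whitney" else _welch
    out = []
    for j, sensor in enumerate(panel.sensor_columns):
        xc, x0 = x[y == 1, j], x[y == 0, j]
        statistic, p = stat_fn(xc, x0)
        out.append(
            GroupTestResult(
                sensor=sensor,
                method=method,
                statistic=statistic,
                p_value=p,
                mean_case=float(xc.mean()),
                mean_control=float(x0.mean()),
                median_case=float(np.median(xc)),
                median_control=float(np.median(x0)),
                n_case=len(xc),
                n_control=len(x0),
            )
        )
    return out


def select_sensors(
    results: list[GroupTestResult],
    alpha: float = 0.05,
    adjust: str = "none",
) -> list[str]:
    """Sensors with (adjusted) p < alpha, ascending p, ties by sensor order.

    ``adjust``: "none" (raw p, mirroring small-panel practice) or
    "benjamini_hochberg" (step-up FDR).
    """
    if not results:
        raise ParameterError("results must be non-empty")
    if adjust not in ("none", "benjamini_hochberg"):
        raise ParameterError(f"unknown adjustment {adjust!r}")
    p = np.array([r.p_value for r in results])
    if adjust == "benjamini_hochberg":
        p_eff = multipletests(p, method="fdr_bh")[1]
    else:
        p_eff = p
    order = sorted(range(len(results)), key=lambda i: (p_eff[i], p[i], i))
    return [results[i].sensor for i in order if p_eff[i] < alpha]


class UnivariateSensorSelector(BaseEstimator):
    """Feature selector over sensor columns for sklearn composition.

    fit(X, y) runs the per-sensor two-group test on the columns of X;
    transform keeps the selected columns. Fitted attributes: ``pvalues_``,
    ``support_``, ``selected_``.
    """

    def __init__(self, method: str = "mann_whitney", alpha: float = 0.05, adjust: str = "none"):
        self.method = method
        self.alpha = alpha
        self.adjust = adjust

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            raise GroupingError("both groups must be non-empty")
        stat_fn = _mann_whitney if self.method == "mann_whitney" else _welch
        if self.method not in ("mann_whitney", "welch_t"):
            raise ParameterError(f"unknown test method {self.method!r}")
        p = np.array([stat_fn(X[y == 1, j], X[y == 0, j])[1] for j in range(X.shape[1])])
        if self.adjust == "benjamini_hochberg":
            p_eff = multipletests(p, method="fdr_bh")[1]
        elif self.adjust == "none":
            p_eff = p
        else:
            raise ParameterError(f"unknown adjustment {self.adjust!r}")
        self.pvalues_ = p
        self.adjusted_pvalues_ = p_eff
        self.support_ = p_eff < self.alpha
        self.selected_ = np.flatnonzero(self.support_)
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_]
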