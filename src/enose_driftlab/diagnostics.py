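"""Drift diagnostics: per-sensor scaling, rank correlation, PCA and a
day-separation score.

The drift signature of a short-term eNose study is a shared shift of most
sensors with the measurement day. These diagnostics quantify it: z-scored
heatmap matrices show the day blocks, the Spearman matrix shows the common
response direction, and the day-separation score condenses the PCA chart
("do samples cluster by measurement day?") into one number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import silhouette_score

from .errors import (
    DegenerateSensorError,
    InsufficientDayError,
    ParameterError,
    UndefinedCorrelationError,
)
from .panel import SensorPanel

_TOL = 1e-10


@dataclass(frozen=True)
class ScaledPanel:
    """A panel with each sensor column z-scored (sample sd, n-1 denominator)."""

    panel: SensorPanel
    mean_: np.ndarray
    sd_: np.ndarray

    @property
    def responses(self) -> np.ndarray:
        return self.panel.responses


@dataclass(frozen=True)
class CorrelationMatrix:
    values: np.ndarray
    sensors: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sensors), columns=list(self.sensors))


@dataclass(frozen=True)
class PCAResult:
    scores: np.ndarray                     # (n_samples, k)
    explained_variance_ratio: np.ndarray   # (k,)
    loadings: np.ndarray                   # (k, n_sensors)


def scale_panel(panel: SensorPanel) -> ScaledPanel:
    """z-score each sensor across all samples: z = (x - mean) / sd.

    Raises
    ------
    DegenerateSensorError
        If a sensor column is constant (sd = 0); no silent NaN columns.
    """
    if panel.n_samples < 2:
        raise ParameterError("scaling requires at least 2 samples")
    x = panel.responses
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    degenerate = np.flatnonzero(sd == 0.0)
    if degenerate.size:
        raise DegenerateSensorError([panel.sensor_columns[i] for i in degenerate])
    z = (x - mean) / sd
    return ScaledPanel(panel=panel.with_responses(z), mean_=mean, sd_=sd)


def spearman_matrix(panel: SensorPanel | ScaledPanel) -> CorrelationMatrix:
    """Pairwise Spearman correlation between sensors (average ranks for ties).

    Monotone per-sensor transforms leave the result unchanged.
    """
    base = panel.panel if isinstance(panel, ScaledPanel) else panel
    x = base.responses
    if x.shape[0] < 3:
        raise ParameterError("Spearman matrix requires at least 3 samples")
    constant = np.flatnonzero(np.ptp(x, axis=0) == 0.0)
    if constant.size:
        raise UndefinedCorrelationError([base.sensor_columns[i] for i in constant])
    rho = stats.spearmanr(x).statistic
    if np.ndim(rho) == 0:  # scipy collapses the 2-sensor case to a scalar
        r = float(rho)
        rho = np.array([[1.0, r], [r, 1.0]])
    return CorrelationMatrix(values=rho, sensors=base.sensor_columns)


def pca_scores(scaled: ScaledPanel, k: int) -> PCAResult:
    """Top-k principal-component scores of the column-centered scaled matrix.

    Component sign convention: the largest-|loading| entry of each component
    is made positive, so scores are reproducible across SVD backends.
    """
    x = scaled.responses
    n, p = x.shape
    if not (1 <= k <= min(n - 1, p)):
        raise ParameterError(f"k must be in [1, {min(n - 1, p)}], got {k}")
    xc = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    for i in range(len(s)):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1.0
            u[:, i] *= -1.0
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else np.zeros_like(var)
    scores = u[:, :k] * s[:k]
    return PCAResult(scores=scores, explained_variance_ratio=evr[:k], loadings=vt[:k])


def day_separation_score(scaled: ScaledPanel, method: str = "changepoint") -> float:
    """How strongly do measurement days cluster the samples in PC1/PC2 space?

    ``changepoint`` (default): the maximum, over contiguous temporal
    bipartitions of the ordered day vocabulary, of the mean silhouette
    coefficient of the two blocks. Shared day drift manifests as a temporal
    changepoint (e.g. below-average early days vs above-average late days);
    scoring bipartitions keeps the score high when adjacent days drift
    identically, where a per-day-label silhouette would wash out. For two
    days the two methods coincide.

    ``day``: plain mean silhouette with each day label as its own cluster.

    Returns a score in [-1, 1]; higher = stronger drift signature.
    """
    base = scaled.panel
    days = base.days
    vocab = [d for d in base.day_vocabulary if (days == d).sum() > 0]
    if len(vocab) < 2:
        raise InsufficientDayError("need at least 2 distinct day labels")
    small = [d for d in vocab if (days == d).sum() < 2]
    if small:
        raise InsufficientDayError(f"day(s) with fewer than 2 samples: {small}")

    k = min(2, base.n_sensors, base.n_samples - 1)
    pts = pca_scores(scaled, k=k).scores
    if method == "day":
        return float(silhouette_score(pts, days))
    if method != "changepoint":
        raise ParameterError(f"unknown method {method!r}")
    day_index = np.array([vocab.index(d) for d in days])
    best = -1.0
    for cut in range(1, len(vocab)):
        labels = (day_index < cut).astype(int)
        best = max(best, float(silhouette_score(pts, labels)))
    return best


def build_heatmap_matrix(
    scaled: ScaledPanel,
    annotations: list[str],
    cluster: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Row-ordered z-score matrix plus annotation tracks for heatmap rendering.

    Rows are ordered by (group, day, sample_id) — groups contiguous, days in
    vocabulary order — or by average-linkage hierarchical clustering when
    ``cluster`` is set. Values are passed through unchanged (no re-scaling).
    """
    base = scaled.panel
    unknown = [c for c in annotations if c not in base.data.columns]
    if unknown:
        raise ParameterError(f"unknown annotation column(s): {unknown}")
    df = base.data.copy()
    group_rank = {g: i for i, g in enumerate(("control", "CD", "UC"))}
    day_rank = {d: i for i, d in enumerate(base.day_vocabulary)}
    if cluster:
        from scipy.cluster import hierarchy

        link = hierarchy.linkage(base.responses, method="average")
        order = hierarchy.leaves_list(link)
        df = df.iloc[order]
    else:
        key = df.assign(
            _g=df["group"].map(group_rank),
            _d=df["day"].map(day_rank),
        )
        df = df.loc[key.sort_values(["_g", "_d", "sample_id"], kind="stable").index]
    matrix = df.set_index("sample_id")[list(base.sensor_columns)]
    ann = df.set_index("sample_id")[annotations]
    return matrix, ann


def render_heatmap(matrix: pd.DataFrame, path) -> None:
    """Optional PNG rendering of a heatmap matrix (decoration, not contract)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, max(3, matrix.shape[0] * 0.05)))
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-3, vmax=3)
    ax.set_xlabel("sensor")
    ax.set_ylabel("sample")
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
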