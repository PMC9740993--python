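"""Synthetic matched case-control eNose panels with day-level drift.

The generator emulates the structure of a short-term clinical eNose study:
63 IBD cases and 63 matched controls measured on four subsequent days with a
32-sensor conducting-polymer array. Each sample's response vector is

    x_ij = mu_j * (1 + a_j * g_d(i)) + beta_j * 1[i is case] + lambda_j * f_i + eps_ij

where ``mu_j`` is the baseline response of sensor j, ``g_d`` a shared
(dimensionless) day drift factor, ``a_j`` a per-sensor drift loading (the
common-drift-direction assumption: most sensors drift together, a few barely
at all), ``beta_j`` the disease effect (nonzero on a small discriminating
subset), ``f_i`` a standard-normal per-sample factor whose loadings
``lambda_j`` induce the strong inter-sensor correlation seen in polymer
arrays, and ``eps_ij`` independent Gaussian noise.

Ground truth (drift matrix, subject factors, day assignment) is returned
alongside the panel so that estimator-recovery tests can score the fitted
correction against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidBaselineError, UnmatchableCaseError
from .panel import METADATA_COLUMNS, SensorPanel, sensor_names

# Sensors (1-based) that barely follow the common drift direction and sit
# outside the high-correlation block; mirrors the three "specific" sensors
# of a Cyranose-type array.
WEAK_SENSORS_1BASED = (6, 19, 24)
# Discriminating sensors (1-based) carrying the disease effect by default.
EFFECT_SENSORS_1BASED = (3, 8, 13, 18, 23, 28)
# Confounded allocation: fraction of cases measured on the early half of days.
CONFOUND_EARLY_FRACTION = 2.0 / 3.0


@dataclass(frozen=True)
class ResistanceReading:
    """One sensor reading: maximum resistance change over a positive baseline."""

    delta_r: float
    r0: float

    @property
    def response(self) -> float:
        return compute_response(self.delta_r, self.r0)


def compute_response(delta_r: float, r0: float) -> float:
    """Dimensionless sensor response ΔR/R₀.

    Raises
    ------
    InvalidBaselineError
        If the baseline resistance is not strictly positive.
    """
    if not np.isfinite(r0) or r0 <= 0:
        raise InvalidBaselineError(f"baseline resistance must be > 0, got {r0!r}")
    return float(delta_r) / float(r0)


def _default_mu(n_sensors: int) -> np.ndarray:
    # spread of baseline response levels across the array
    return np.linspace(0.5, 2.0, n_sensors)


def _indicator(n: int, ones_1based: Sequence[int], on: float, off: float) -> np.ndarray:
    out = np.full(n, on, dtype=float)
    for i in ones_1based:
        if 1 <= i <= n:
            out[i - 1] = off
    return out


@dataclass
class SimulationConfig:
    """Generative parameters; defaults are the documented study conditions.

    Vector parameters left as ``None`` are resolved against ``n_sensors`` /
    ``n_days`` by :meth:`resolved`:

    - ``sensor_means``: mu_j, evenly spread over [0.5, 2.0] response units.
    - ``effect_sizes``: beta_j = 0.12 * mu_j on the six discriminating sensors,
      calibrated so the corrected per-sensor tests at 63+63 samples land in
      the reported-significance range of such studies (p ~ 0.001).
    - ``drift_day_factor``: g = (-g0, -g0, +g0, +g0) with g0 = 0.1 — the
      two-block day pattern (below-average early days, above-average late).
    - ``drift_sensor_loading``: a_j = 1 except ~0 on the weak sensors.
    - ``subject_factor_loading``: lambda_j = 0.2 * mu_j except 0 on the weak
      sensors (drives the high inter-sensor correlation).
    - ``noise_sd``: 0.05 * mu_j.
    """

    n_cases: int = 63
    n_controls: int = 63
    n_sensors: int = 32
    n_days: int = 4
    sensor_means: np.ndarray | None = None
    effect_sizes: np.ndarray | None = None
    drift_day_factor: np.ndarray | None = None
    drift_sensor_loading: np.ndarray | None = None
    subject_factor_loading: np.ndarray | None = None
    noise_sd: np.ndarray | float | None = None
    day_allocation: str | Mapping[str, Sequence[float]] = "balanced"
    drift_mode: str = "relative"  # or "additive": x += a_j*g_d instead of mu*(1+a*g)
    seed: int = 0

    def resolved(self) -> "SimulationConfig":
        """Return a copy with every vector parameter materialized and checked."""
        for name, length in (
            ("sensor_means", self.n_sensors),
            ("effect_sizes", self.n_sensors),
            ("drift_sensor_loading", self.n_sensors),
            ("subject_factor_loading", self.n_sensors),
            ("drift_day_factor", self.n_days),
        ):
            vec = getattr(self, name)
            if vec is not None and np.asarray(vec, dtype=float).shape != (length,):
                raise ConfigError(
                    f"{name} must have length {length}, got shape {np.asarray(vec).shape}"
                )
        mu = np.asarray(self.sensor_means, dtype=float) if self.sensor_means is not None else _default_mu(self.n_sensors)
        beta = (
            np.asarray(self.effect_sizes, dtype=float)
            if self.effect_sizes is not None
            else 0.12 * mu * _indicator(self.n_sensors, EFFECT_SENSORS_1BASED, 0.0, 1.0)
        )
        if self.drift_day_factor is not None:
            g = np.asarray(self.drift_day_factor, dtype=float)
        else:
            g0 = 0.1
            half = self.n_days // 2
            g = np.array([-g0] * half + [g0] * (self.n_days - half), dtype=float)
        a = (
            np.asarray(self.drift_sensor_loading, dtype=float)
            if self.drift_sensor_loading is not None
            else _indicator(self.n_sensors, WEAK_SENSORS_1BASED, 1.0, 0.05)
        )
        lam = (
            np.asarray(self.subject_factor_loading, dtype=float)
            if self.subject_factor_loading is not None
            else 0.2 * mu * _indicator(self.n_sensors, WEAK_SENSORS_1BASED, 1.0, 0.0)
        )
        if self.noise_sd is None:
            sd = 0.05 * mu
        else:
            sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (self.n_sensors,)).copy()

        cfg = SimulationConfig(
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            n_sensors=self.n_sensors,
            n_days=self.n_days,
            sensor_means=mu,
            effect_sizes=beta,
            drift_day_factor=g,
            drift_sensor_loading=a,
            subject_factor_loading=lam,
            noise_sd=sd,
            day_allocation=self.day_allocation,
            drift_mode=self.drift_mode,
            seed=self.seed,
        )
        cfg._validate()
        return cfg

    def _validate(self):
        for name in ("n_cases", "n_controls", "n_sensors", "n_days"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        p, d = self.n_sensors, self.n_days
        for name, vec, length in (
            ("sensor_means", self.sensor_means, p),
            ("effect_sizes", self.effect_sizes, p),
            ("drift_sensor_loading", self.drift_sensor_loading, p),
            ("subject_factor_loading", self.subject_factor_loading, p),
            ("noise_sd", self.noise_sd, p),
            ("drift_day_factor", self.drift_day_factor, d),
        ):
            if np.asarray(vec).shape != (length,):
                raise ConfigError(f"{name} must have length {length}, got shape {np.asarray(vec).shape}")
        if np.any(np.asarray(self.sensor_means) <= 0):
            raise ConfigError("sensor_means must be strictly positive")
        if np.any(np.asarray(self.drift_sensor_loading) < 0):
            raise ConfigError("drift_sensor_loading must be non-negative")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ConfigError("noise_sd must be non-negative")
        if self.drift_mode not in ("relative", "additive"):
            raise ConfigError(f"unknown drift_mode {self.drift_mode!r}")
        if isinstance(self.day_allocation, str):
            if self.day_allocation not in ("balanced", "confounded"):
                raise ConfigError(f"unknown day_allocation policy {self.day_allocation!r}")
        else:
            for grp in ("case", "control"):
                w = np.asarray(self.day_allocation.get(grp, ()), dtype=float)
                if w.shape != (d,) or np.any(w < 0) or w.sum() <= 0:
                    raise ConfigError(f"custom day weights for {grp!r} must be {d} non-negative values")

    def to_jsonable(self) -> dict:
        out = {}
        for key, val in asdict(self).items():
            if isinstance(val, np.ndarray):
                out[key] = val.tolist()
            elif isinstance(val, Mapping):
                out[key] = {k: list(map(float, v)) for k, v in val.items()}
            else:
                out[key] = val
        return out


@dataclass
class SimulationTruth:
    """Ground truth of one simulated panel, for recovery tests."""

    config: SimulationConfig
    subject_factor: np.ndarray          # f_i, shape (n_samples,)
    day_assignment: np.ndarray          # day labels, shape (n_samples,)
    drift: np.ndarray                   # d_jd = a_j * g_d, (n_sensors, n_days)

    def to_jsonable(self) -> dict:
        return {
            "config": self.config.to_jsonable(),
            "subject_factor": self.subject_factor.tolist(),
            "day_assignment": self.day_assignment.tolist(),
            "drift": self.drift.tolist(),
        }


def _allocate_counts(n: int, weights: np.ndarray) -> np.ndarray:
    """Deterministic largest-remainder apportionment of n samples to days."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    raw = w * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    # largest fractional remainders first; ties broken by day order
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:rem]] += 1
    return counts


def _day_indices(n: int, counts: np.ndarray) -> np.ndarray:
    """Interleave samples over days with the given per-day counts."""
    remaining = counts.copy()
    out = np.empty(n, dtype=int)
    d = 0
    for i in range(n):
        while remaining[d % len(counts)] == 0:
            d += 1
        out[i] = d % len(counts)
        remaining[d % len(counts)] -= 1
        d += 1
    return out


def _group_day_weights(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    d = config.n_days
    if config.day_allocation == "balanced":
        w = np.ones(d)
        return w, w.copy()
    if config.day_allocation == "confounded":
        # cases concentrated on the early half of days; controls balanced so
        # every day retains control coverage for the correction fit
        half = d // 2
        w_case = np.empty(d)
        w_case[:half] = CONFOUND_EARLY_FRACTION / half
        w_case[half:] = (1.0 - CONFOUND_EARLY_FRACTION) / (d - half)
        return w_case, np.ones(d)
    return (
        np.asarray(config.day_allocation["case"], dtype=float),
        np.asarray(config.day_allocation["control"], dtype=float),
    )


def simulate_panel(config: SimulationConfig) -> tuple[SensorPanel, SimulationTruth]:
    """Generate one matched case-control panel plus its ground truth.

    Identical configs (including seed) yield bit-identical output.
    """
    cfg = config.resolved()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases + cfg.n_controls
    p = cfg.n_sensors
    mu = cfg.sensor_means
    g = cfg.drift_day_factor
    a = cfg.drift_sensor_loading
    lam = cfg.subject_factor_loading
    beta = cfg.effect_sizes
    sd = cfg.noise_sd

    is_case = np.zeros(n, dtype=bool)
    is_case[: cfg.n_cases] = True

    w_case, w_ctrl = _group_day_weights(cfg)
    day_idx = np.empty(n, dtype=int)
    day_idx[: cfg.n_cases] = _day_indices(cfg.n_cases, _allocate_counts(cfg.n_cases, w_case))
    day_idx[cfg.n_cases :] = _day_indices(cfg.n_controls, _allocate_counts(cfg.n_controls, w_ctrl))
    day_labels = np.array([f"day{i + 1}" for i in range(cfg.n_days)])

    # latent structure and noise (draw order is part of the determinism contract)
    f = rng.standard_normal(n)
    eps = rng.standard_normal((n, p)) * sd[None, :]

    drift_term = a[None, :] * g[day_idx][:, None]
    if cfg.drift_mode == "relative":
        base = mu[None, :] * (1.0 + drift_term)
    else:
        base = mu[None, :] + drift_term
    x = base + beta[None, :] * is_case[:, None] + lam[None, :] * f[:, None] + eps

    # ---- covariates: cases drawn, controls mirror their matched case ----
    phenos = rng.choice(np.array(["CD", "UC"]), size=cfg.n_cases, p=[24 / 63, 39 / 63])
    age_case = np.round(np.clip(rng.normal(47.0, 16.0, cfg.n_cases), 18.0, 85.0), 1)
    sex_case = rng.choice(np.array(["F", "M"]), size=cfg.n_cases, p=[0.62, 0.38])
    smoking_case = rng.choice(
        np.array(["current", "past", "never"]), size=cfg.n_cases, p=[0.127, 0.349, 0.524]
    )
    hospital_case = rng.choice(np.array(["hospA", "hospB", "hospC"]), size=cfg.n_cases)
    activity = rng.choice(np.array(["active", "remission"]), size=cfg.n_cases, p=[0.65, 0.35])
    diet = rng.choice(
        np.array(["none", "vegetarian", "gluten_free", "lactose_free", "other"]),
        size=n,
        p=[0.81, 0.02, 0.07, 0.02, 0.08],
    )
    surgery_case = rng.choice(
        np.array(["none", "ileocecal_resection", "colectomy"]), size=cfg.n_cases, p=[0.80, 0.12, 0.08]
    )

    # 1:1 matched design: each control shares its case's matching covariates
    # (sex, smoking, hospital) with a small age offset; extra controls drawn fresh.
    m = min(cfg.n_cases, cfg.n_controls)
    extra = cfg.n_controls - m
    age_ctrl = np.round(np.clip(age_case[:m] + rng.normal(0.0, 2.0, m), 18.0, 85.0), 1)
    sex_ctrl, smoking_ctrl, hospital_ctrl = sex_case[:m].copy(), smoking_case[:m].copy(), hospital_case[:m].copy()
    if extra > 0:
        age_ctrl = np.concatenate([age_ctrl, np.round(np.clip(rng.normal(47.0, 16.0, extra), 18.0, 85.0), 1)])
        sex_ctrl = np.concatenate([sex_ctrl, rng.choice(np.array(["F", "M"]), size=extra, p=[0.62, 0.38])])
        smoking_ctrl = np.concatenate(
            [smoking_ctrl, rng.choice(np.array(["current", "past", "never"]), size=extra, p=[0.127, 0.349, 0.524])]
        )
        hospital_ctrl = np.concatenate([hospital_ctrl, rng.choice(np.array(["hospA", "hospB", "hospC"]), size=extra)])

    width = max(3, len(str(max(cfg.n_cases, cfg.n_controls))))
    ids = np.array(
        [f"case-{i + 1:0{width}d}" for i in range(cfg.n_cases)]
        + [f"ctrl-{i + 1:0{width}d}" for i in range(cfg.n_controls)]
    )
    meta = pd.DataFrame(
        {
            "sample_id": ids,
            "group": np.concatenate([phenos, np.full(cfg.n_controls, "control")]),
            "activity": np.concatenate([activity, np.full(cfg.n_controls, "not_applicable")]),
            "diet": diet,
            "surgery": np.concatenate([surgery_case, np.full(cfg.n_controls, "none")]),
            "day": day_labels[day_idx],
            "age": np.concatenate([age_case, age_ctrl]),
            "sex": np.concatenate([sex_case, sex_ctrl]),
            "smoking": np.concatenate([smoking_case, smoking_ctrl]),
            "hospital": np.concatenate([hospital_case, hospital_ctrl]),
        }
    )[list(METADATA_COLUMNS)]
    cols = sensor_names(p)
    data = pd.concat([meta, pd.DataFrame(x, columns=list(cols))], axis=1)

    panel = SensorPanel(data=data, sensor_columns=cols, day_vocabulary=tuple(day_labels))
    truth = SimulationTruth(
        config=cfg,
        subject_factor=f,
        day_assignment=day_labels[day_idx],
        drift=np.outer(a, g),
    )
    return panel, truth


def match_pairs(panel: SensorPanel, case_ids: Sequence[str]) -> list[tuple[str, str]]:
    """Pair each case with one unused control matching sex, smoking and hospital
    exactly, minimizing absolute age difference.

    Greedy over cases in ascending age order (ties by sample_id); candidate
    controls are the panel samples not listed in ``case_ids``.

    Raises
    ------
    UnmatchableCaseError
        If some case has no remaining control with identical categoricals.
    """
    case_ids = list(case_ids)
    known = set(panel.data["sample_id"])
    unknown = [c for c in case_ids if c not in known]
    if unknown:
        raise ConfigError(f"case id(s) not in panel: {unknown}")
    df = panel.data.set_index("sample_id")
    cases = df.loc[case_ids]
    candidates = df.drop(index=case_ids)

    used: set[str] = set()
    pairs: list[tuple[str, str]] = []
    for cid in sorted(cases.index, key=lambda s: (cases.loc[s, "age"], s)):
        c = cases.loc[cid]
        pool = candidates[
            (candidates["sex"] == c["sex"])
            & (candidates["smoking"] == c["smoking"])
            & (candidates["hospital"] == c["hospital"])
            & (~candidates.index.isin(used))
        ]
        if len(pool) == 0:
            raise UnmatchableCaseError(cid)
        diffs = (pool["age"] - c["age"]).abs()
        best = min(zip(diffs, pool.index))
        used.add(best[1])
        pairs.append((cid, best[1]))
    # restore original case order for readability
    return sorted(pairs, key=lambda pr: case_ids.index(pr[0]))


# ---------------------------------------------------------------------------
# Named scenarios (the documented study conditions for tests / reports)
# ---------------------------------------------------------------------------

def study_scenario(seed: int = 0, **overrides) -> SimulationConfig:
    """Default study conditions: 63+63 samples, 4 days, drift + effect on."""
    return SimulationConfig(seed=seed, **overrides)


def null_scenario(seed: int = 0) -> SimulationConfig:
    """Calibration null: no effect, no drift, independent sensors."""
    cfg = SimulationConfig(seed=seed)
    return SimulationConfig(
        seed=seed,
        effect_sizes=np.zeros(cfg.n_sensors),
        drift_sensor_loading=np.zeros(cfg.n_sensors),
        subject_factor_loading=np.zeros(cfg.n_sensors),
    )


def confounded_null_scenario(seed: int = 0) -> SimulationConfig:
    """No disease effect, drift on, cases concentrated on early days.

    Subject factor off so per-sensor tests are independent (calibration
    scenarios are scored against a binomial reference).
    """
    cfg = SimulationConfig(seed=seed)
    return SimulationConfig(
        seed=seed,
        effect_sizes=np.zeros(cfg.n_sensors),
        subject_factor_loading=np.zeros(cfg.n_sensors),
        day_allocation="confounded",
    )


def drift_demo_scenario(seed: int = 0) -> SimulationConfig:
    """Headline end-to-end scenario: 6 true sensors, strong two-block drift
    (g0 = 0.25), confounded day allocation, correlated sensors."""
    cfg = SimulationConfig(seed=seed)
    g = np.array([-0.25, -0.25, 0.25, 0.25])
    return SimulationConfig(seed=seed, drift_day_factor=g, day_allocation="confounded")
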