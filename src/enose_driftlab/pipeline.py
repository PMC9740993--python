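"""End-to-end orchestration: simulate/load -> diagnose -> correct -> test ->
classify, with a machine-readable manifest.

A run writes exactly ten artifacts in a fixed order plus ``manifest.json``
(config echo, seed, artifact SHA-256 checksums and a summary block). Reruns
with identical configuration produce byte-identical artifacts, so manifests
can be compared checksum-by-checksum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .classify import evaluate, loocv_predict, optimal_cutoff
from .diagnostics import build_heatmap_matrix, day_separation_score, scale_panel, spearman_matrix
from .drift_correction import apply_correction, correction_report, fit_drift
from .errors import IncompatibleRunsError, PipelineStageError
from .group_stats import select_sensors, test_sensors
from .panel import SensorPanel
from .synthetic_data import SimulationConfig, simulate_panel

log = logging.getLogger("enose_driftlab")

ARTIFACTS = (
    "panel.csv",
    "scaled_before.tsv",
    "scaled_after.tsv",
    "spearman.tsv",
    "drift_model.json",
    "drift_report.tsv",
    "group_tests.tsv",
    "selected_sensors.json",
    "cv_predictions.tsv",
    "classification_report.json",
)


@dataclass
class PipelineConfig:
    """One reproducible run: exactly one input source (file or simulation)."""

    simulation: SimulationConfig | None = None
    panel_path: str | None = None
    n_sensors: int = 32
    correction_enabled: bool = True
    correction_mode: str = "relative"
    restrict_to_cases: bool = False
    pool_adjacent: bool = False
    control_group: str = "control"
    test_method: str = "mann_whitney"
    alpha: float = 0.05
    adjust: str = "none"
    selection_policy: str = "fixed"
    cutoff_criterion: str = "youden"
    cutoff: float | None = None
    seed: int = 0

    def __post_init__(self):
        if (self.simulation is None) == (self.panel_path is None):
            raise ValueError("exactly one of simulation / panel_path must be set")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = pio.read_yaml(path)
        sim = raw.pop("simulation", None)
        seed = raw.get("seed", 0)
        if sim is not None:
            sim.setdefault("seed", seed)
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **{k: v for k, v in raw.items()})

    def echo(self) -> dict:
        out = {
            k: getattr(self, k)
            for k in (
                "panel_path",
                "n_sensors",
                "correction_enabled",
                "correction_mode",
                "restrict_to_cases",
                "pool_adjacent",
                "control_group",
                "test_method",
                "alpha",
                "adjust",
                "selection_policy",
                "cutoff_criterion",
                "cutoff",
                "seed",
            )
        }
        out["simulation"] = self.simulation.to_jsonable() if self.simulation else None
        return out


def _stage(name: str, out_dir: Path):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                (out_dir / "FAILED").write_text(f"{name}: {exc}\n", encoding="utf-8")
                raise PipelineStageError(name, exc) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full pipeline; returns the manifest dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": config.echo(), "seed": config.seed}
    summary: dict = {}

    with _stage("input", out):
        if config.simulation is not None:
            panel, truth = simulate_panel(config.simulation)
            pio.write_json(truth.to_jsonable(), out / "truth.json")
            manifest["simulation_truth"] = "truth.json"
        else:
            panel = pio.read_panel(config.panel_path, pio.default_schema(config.n_sensors))
        pio.write_panel(panel, out / "panel.csv")

    with _stage("diagnose", out):
        scaled_before = scale_panel(panel)
        matrix, _ann = build_heatmap_matrix(scaled_before, ["group", "day"])
        pio.write_tsv(matrix, out / "scaled_before.tsv", index=True)
        corr = spearman_matrix(panel)
        pio.write_tsv(corr.to_frame(), out / "spearman.tsv", index=True)
        summary["day_separation_before"] = day_separation_score(scaled_before)

    with _stage("correct", out):
        model = fit_drift(
            panel,
            control_selector=config.control_group,
            mode=config.correction_mode,
            pool_adjacent=config.pool_adjacent,
        )
        pio.write_json(model.to_jsonable(), out / "drift_model.json")
        per_sensor, per_day = correction_report(model)
        pio.write_tsv(per_sensor, out / "drift_report.tsv")
        summary["mean_abs_deviation_per_day"] = per_day["mean_abs_dev"].tolist()
        if config.correction_enabled:
            corrected = apply_correction(panel, model, restrict_to_cases=config.restrict_to_cases)
        else:
            corrected = panel
        scaled_after = scale_panel(corrected)
        matrix, _ann = build_heatmap_matrix(scaled_after, ["group", "day"])
        pio.write_tsv(matrix, out / "scaled_after.tsv", index=True)
        summary["day_separation_after"] = day_separation_score(scaled_after)
        summary["drift_rank1_share"] = model.rank1_share()

    with _stage("test", out):
        results = test_sensors(corrected, method=config.test_method)
        pio.write_tsv(pd.DataFrame([r.__dict__ for r in results]), out / "group_tests.tsv")
        selected = select_sensors(results, alpha=config.alpha, adjust=config.adjust)
        pio.write_json({"selected": selected, "alpha": config.alpha, "adjust": config.adjust},
                       out / "selected_sensors.json")
        summary["n_selected_sensors"] = len(selected)

    with _stage("classify", out):
        preds = loocv_predict(
            corrected,
            sensor_subset=selected,
            selection_policy=config.selection_policy,
            method=config.test_method,
            alpha=config.alpha,
            adjust=config.adjust,
        )
        pio.write_tsv(
            pd.DataFrame([p.__dict__ for p in preds]), out / "cv_predictions.tsv"
        )
        cutoff = config.cutoff if config.cutoff is not None else optimal_cutoff(
            preds, criterion=config.cutoff_criterion
        )
        report = evaluate(preds, cutoff)
        payload = report.to_jsonable()
        payload["selected_sensors"] = selected
        pio.write_json(payload, out / "classification_report.json")
        summary["cutoff"] = cutoff
        summary.update(report.rounded())
        summary["accuracy_full"] = report.accuracy
        summary["brier_full"] = report.brier

    manifest["artifacts"] = {name: pio.sha256_file(out / name) for name in ARTIFACTS}
    manifest["summary"] = summary
    pio.write_json(manifest, out / "manifest.json")
    log.info("pipeline run complete: %s (%d artifacts)", out, len(ARTIFACTS))
    return manifest


def compare_runs(run_a, run_b, out_dir=None) -> dict:
    """Side-by-side deltas (B - A) of the headline summary quantities.

    Both runs must have processed the same input panel (identical panel
    checksum); otherwise raises :class:`IncompatibleRunsError`.
    """
    ma = pio.read_json(Path(run_a) / "manifest.json")
    mb = pio.read_json(Path(run_b) / "manifest.json")
    if ma["artifacts"]["panel.csv"] != mb["artifacts"]["panel.csv"]:
        raise IncompatibleRunsError("runs were made on different input panels")
    keys = (
        "day_separation_before",
        "day_separation_after",
        "n_selected_sensors",
        "accuracy_full",
        "brier_full",
        "sensitivity",
        "specificity",
    )
    rows = []
    for k in keys:
        va, vb = ma["summary"].get(k), mb["summary"].get(k)
        delta = None if va is None or vb is None else vb - va
        rows.append({"quantity": k, "run_a": va, "run_b": vb, "delta": delta})
    delta_report = {
        "run_a": str(run_a),
        "run_b": str(run_b),
        "deltas": {r["quantity"]: r["delta"] for r in rows},
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_tsv(pd.DataFrame(rows), out / "compare.tsv")
        pio.write_json(delta_report, out / "compare.json")
    return delta_report
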