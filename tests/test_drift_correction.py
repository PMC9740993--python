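"""Drift model estimation and correction: hand-computed fits, exact
equalization, case invariance, parameter recovery, mode equivalence."""

import numpy as np
import pytest
from sklearn.base import clone

from enose_driftlab.drift_correction import (
    DriftCorrector,
    DriftModel,
    apply_correction,
    correction_report,
    fit_drift,
)
from enose_driftlab.errors import (
    NearZeroMeanError,
    SingularCorrectionError,
    UncoveredDayError,
)
from enose_driftlab.io import write_tsv
from enose_driftlab.synthetic_data import SimulationConfig, simulate_panel
from tests.conftest import build_panel


def _two_day_panel(extra_case_value=None):
    """One sensor; controls (1,1) on day1 and (3,3) on day2, optional case."""
    values = [[1.0], [1.0], [3.0], [3.0]]
    group = ["control"] * 4
    day = ["day1", "day1", "day2", "day2"]
    if extra_case_value is not None:
        values.append([extra_case_value])
        group.append("CD")
        day.append("day2")
    return build_panel(values, group=group, day=day, day_vocabulary=["day1", "day2"])


class TestFitDrift:
    def test_equal_day_means_give_zero_deviation(self):
        panel = build_panel([[2.0], [2.0], [2.0], [2.0]],
                            day=["day1", "day1", "day2", "day2"])
        model = fit_drift(panel)
        assert np.allclose(model.dev, 0.0)

    def test_hand_computed_two_day_fit(self):
        model = fit_drift(_two_day_panel())
        assert model.mu[0] == pytest.approx(2.0)
        assert model.dev[0] == pytest.approx([-0.5, 0.5])

    def test_single_control_per_day(self):
        panel = build_panel([[2.0], [4.0]], day=["day1", "day2"])
        model = fit_drift(panel)
        assert model.mu[0] == pytest.approx(3.0)
        assert model.dev[0] == pytest.approx([-1 / 3, 1 / 3])

    def test_control_count_weighted_deviations_average_to_zero(self):
        panel, _ = simulate_panel(SimulationConfig(seed=3, day_allocation="confounded"))
        model = fit_drift(panel)
        weighted = model.dev @ model.control_counts
        assert np.max(np.abs(weighted / model.control_counts.sum())) < 1e-10

    def test_cases_never_influence_the_fit(self):
        panel, _ = simulate_panel(SimulationConfig(seed=4))
        model = fit_drift(panel)
        x = panel.responses.copy()
        x[~panel.is_control] *= 100.0  # wildly perturb cases only
        perturbed = panel.with_responses(x)
        model2 = fit_drift(perturbed)
        assert np.array_equal(model.mu, model2.mu)
        assert np.array_equal(model.dev, model2.dev)

    def test_day_without_controls_is_an_error(self):
        panel = build_panel([[1.0], [2.0], [3.0]],
                            group=["control", "control", "CD"],
                            day=["day1", "day1", "day2"],
                            day_vocabulary=["day1", "day2"])
        with pytest.raises(UncoveredDayError) as exc:
            fit_drift(panel)
        assert exc.value.days == ["day2"]

    def test_pool_adjacent_borrows_nearest_covered_day(self):
        panel = build_panel([[1.0], [1.0], [3.0], [3.0], [9.9]],
                            group=["control"] * 4 + ["CD"],
                            day=["day1", "day1", "day2", "day2", "day3"],
                            day_vocabulary=["day1", "day2", "day3"])
        model = fit_drift(panel, pool_adjacent=True)
        assert model.pooled_days == ("day3",)
        assert model.dev[0, 2] == model.dev[0, 1]

    def test_near_zero_control_mean_rejected_in_relative_mode(self):
        panel = build_panel([[-1.0], [1.0], [-1.0], [1.0]],
                            day=["day1", "day1", "day2", "day2"])
        with pytest.raises(NearZeroMeanError):
            fit_drift(panel, mode="relative")
        fit_drift(panel, mode="additive")  # additive mode stays defined


class TestApplyCorrection:
    def test_zero_model_is_identity(self):
        panel, _ = simulate_panel(SimulationConfig(seed=0, n_cases=5, n_controls=5))
        model = fit_drift(panel)
        zero = DriftModel(mu=model.mu, dev=np.zeros_like(model.dev),
                          delta=np.zeros_like(model.dev), mode="relative",
                          day_vocabulary=model.day_vocabulary,
                          control_counts=model.control_counts, sensors=model.sensors)
        corrected = apply_correction(panel, zero)
        assert np.array_equal(corrected.responses, panel.responses)

    @pytest.mark.parametrize("mode", ["relative", "additive"])
    def test_hand_computed_case_correction(self, mode):
        panel = _two_day_panel(extra_case_value=3.0)
        model = fit_drift(panel, mode=mode)
        corrected = apply_correction(panel, model)
        # relative: 3/(1+0.5) = 2 ; additive: 3 - 2*0.5 = 2
        assert corrected.responses[-1, 0] == pytest.approx(2.0)

    def test_metadata_unchanged(self):
        panel, _ = simulate_panel(SimulationConfig(seed=1))
        corrected = apply_correction(panel, fit_drift(panel))
        assert corrected.metadata().equals(panel.metadata())

    def test_restrict_to_cases_leaves_controls_untouched(self):
        panel, _ = simulate_panel(SimulationConfig(seed=2))
        model = fit_drift(panel)
        corrected = apply_correction(panel, model, restrict_to_cases=True)
        ctrl = panel.is_control
        assert np.array_equal(corrected.responses[ctrl], panel.responses[ctrl])
        assert not np.array_equal(corrected.responses[~ctrl], panel.responses[~ctrl])

    @pytest.mark.parametrize("mode", ["relative", "additive"])
    def test_equalization_of_control_day_means(self, mode):
        # the method's defining algebraic property, over random instances
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n_sensors = int(rng.integers(1, 6))
            n_days = int(rng.integers(2, 5))
            cfg = SimulationConfig(
                n_cases=int(rng.integers(1, 10)),
                n_controls=int(rng.integers(2 * n_days, 40)),
                n_sensors=n_sensors,
                n_days=n_days,
                sensor_means=rng.uniform(0.5, 2.0, n_sensors),
                effect_sizes=rng.normal(0, 0.1, n_sensors),
                drift_day_factor=rng.uniform(-0.3, 0.3, n_days),
                drift_sensor_loading=rng.uniform(0, 1, n_sensors),
                subject_factor_loading=rng.uniform(0, 0.3, n_sensors),
                noise_sd=float(rng.uniform(0.01, 0.2)),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            panel, _ = simulate_panel(cfg)
            corrected = apply_correction(panel, fit_drift(panel, mode=mode))
            x = corrected.responses[corrected.is_control]
            days = corrected.days[corrected.is_control]
            day_means = np.array([x[days == d].mean(axis=0) for d in corrected.day_vocabulary
                                  if (days == d).any()])
            spread = day_means.max(axis=0) - day_means.min(axis=0)
            assert np.max(spread) < 1e-10

    def test_unseen_day_label_rejected(self):
        panel = _two_day_panel()
        model = fit_drift(panel)
        other = build_panel([[1.0]], day=["day9"])
        with pytest.raises(UncoveredDayError):
            apply_correction(other, model)

    def test_singular_relative_factor_rejected(self):
        model = DriftModel(mu=np.array([1.0]), dev=np.array([[-1.0, 1.0]]),
                           delta=np.array([[-1.0, 1.0]]),
                           mode="relative", day_vocabulary=("day1", "day2"),
                           control_counts=np.array([1, 1]), sensors=("S1",))
        panel = build_panel([[1.0]], day=["day1"], day_vocabulary=["day1", "day2"])
        with pytest.raises(SingularCorrectionError):
            apply_correction(panel, model)

    def test_modes_agree_to_first_order_for_small_drift(self):
        # small deviations AND small residual spread: the modes differ by
        # rel - add = d * (mu - rel) exactly, a second-order term here
        cfg = SimulationConfig(seed=6,
                               drift_day_factor=np.array([-0.01, -0.01, 0.01, 0.01]),
                               effect_sizes=np.zeros(32),
                               subject_factor_loading=np.zeros(32),
                               noise_sd=0.002)
        panel, _ = simulate_panel(cfg)
        model = fit_drift(panel, mode="relative")
        rel = apply_correction(panel, model)
        add = apply_correction(panel, fit_drift(panel, mode="additive"))
        assert np.max(np.abs(model.dev)) <= 0.02
        # exact algebraic identity between the two corrections
        idx = np.array([model.day_vocabulary.index(d) for d in panel.days])
        dev = model.dev[:, idx].T
        identity = dev * (model.mu[None, :] - rel.responses)
        assert np.max(np.abs((rel.responses - add.responses) - identity)) < 1e-12
        # first-order agreement at the documented quadratic scale
        bound = 2 * np.max(np.abs(model.dev)) ** 2 * np.max(np.abs(panel.responses))
        assert np.max(np.abs(rel.responses - add.responses)) <= bound


class TestRecovery:
    def _rmse(self, n_controls, noise_sd, seed):
        cfg = SimulationConfig(
            seed=seed, n_cases=1, n_controls=n_controls,
            subject_factor_loading=np.zeros(32), noise_sd=noise_sd,
        )
        panel, truth = simulate_panel(cfg)
        model = fit_drift(panel)
        return float(np.sqrt(np.mean((model.dev - truth.drift) ** 2)))

    def test_rmse_shrinks_with_control_sample_size(self):
        small = np.mean([self._rmse(50, None, 100 + r) for r in range(5)])
        large = np.mean([self._rmse(400, None, 200 + r) for r in range(5)])
        assert large < small

    def test_zero_noise_recovers_drift_exactly(self):
        assert self._rmse(80, 0.0, 7) < 1e-12


class TestReportAndEstimatorAPI:
    def test_zero_model_report_has_zero_ranges(self):
        panel = build_panel([[2.0], [2.0], [2.0], [2.0]], day=["day1", "day1", "day2", "day2"])
        per_sensor, per_day = correction_report(fit_drift(panel))
        assert (per_sensor["dev_range"] == 0.0).all()
        assert (per_day["mean_abs_dev"] == 0.0).all()

    def test_two_day_model_range(self):
        per_sensor, per_day = correction_report(fit_drift(_two_day_panel()))
        assert per_sensor.loc[0, "dev_range"] == pytest.approx(1.0)
        assert per_day["mean_abs_dev"].tolist() == pytest.approx([0.5, 0.5])

    def test_report_bytes_deterministic(self, tmp_path):
        model = fit_drift(_two_day_panel())
        p1 = write_tsv(correction_report(model)[0], tmp_path / "a.tsv")
        p2 = write_tsv(correction_report(model)[0], tmp_path / "b.tsv")
        assert p1.read_bytes() == p2.read_bytes()

    def test_sklearn_estimator_contract(self):
        panel, _ = simulate_panel(SimulationConfig(seed=0, n_cases=10, n_controls=20))
        est = DriftCorrector(mode="additive", pool_adjacent=True)
        assert est.get_params() == {"mode": "additive", "pool_adjacent": True}
        est2 = clone(est).set_params(mode="relative")
        est2.fit(panel.responses, day=panel.days, control=panel.is_control,
                 day_vocabulary=panel.day_vocabulary)
        out = est2.transform(panel.responses, day=panel.days)
        assert out.shape == panel.responses.shape
        assert est2.dev_.shape == (panel.n_sensors, len(panel.day_vocabulary))

    def test_rank1_share_high_under_common_drift(self):
        panel, _ = simulate_panel(SimulationConfig(seed=8))
        assert fit_drift(panel).rank1_share() > 0.8
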