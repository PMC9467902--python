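import math

import numpy as np
import pytest
from scipy.integrate import quad

from hipecmd.simulate import (
    DEFAULT_PEAK_TARGETS,
    NoiseModel,
    TissueKinetics,
    TrueCatheterState,
    closed_form_nca,
    default_kinetics,
    interval_average,
    kinetics_from_peak,
    simulate_dialysate_series,
    simulate_retrodialysis_pair,
    simulate_study,
    true_concentration,
)
from hipecmd.study_design import PLASMA, StudyConfig, TISSUE_COMPARTMENTS, build_schedule

KIN = TissueKinetics("test", amplitude=30.0, k_uptake=0.02, k_elim=0.005)


class TestTruthCurve:
    def test_starts_at_zero(self):
        assert true_concentration(KIN, 0.0) == 0.0

    def test_closed_form_tmax(self):
        cf = closed_form_nca(KIN, 480)
        assert cf.tmax == pytest.approx(math.log(0.02 / 0.005) / 0.015, rel=1e-12)
        assert cf.tmax == pytest.approx(92.42, abs=0.01)

    def test_vanishes_at_long_times(self):
        assert true_concentration(KIN, 1e7) == pytest.approx(0.0, abs=1e-12)

    def test_half_life_closed_form(self):
        assert closed_form_nca(KIN, 480).half_life == pytest.approx(138.63, abs=0.01)

    def test_cmax_matches_dense_grid_search(self):
        """Closed-form peak equals the brute-force maximum on a 0.01-min grid."""
        cf = closed_form_nca(KIN, 480)
        grid = np.arange(0.0, 480.0, 0.01)
        dense = true_concentration(KIN, grid)
        assert cf.cmax == pytest.approx(dense.max(), rel=1e-8)
        assert cf.tmax == pytest.approx(grid[np.argmax(dense)], abs=0.01)

    def test_auc_approaches_analytic_limit(self):
        """AUC(0, t) -> A (1/ke - 1/ku) as t grows."""
        limit = 30.0 * (1 / 0.005 - 1 / 0.02)
        assert closed_form_nca(KIN, 1e6).auc_0_tlast == pytest.approx(limit, rel=1e-9)

    def test_equal_rates_rejected(self):
        with pytest.raises(ValueError):
            TissueKinetics("bad", 10.0, 0.01, 0.01)

    def test_interval_average_matches_quadrature(self):
        for interval in [(0, 30), (120, 150), (420, 480)]:
            numeric = quad(lambda t: true_concentration(KIN, t), *interval)[0] / (
                interval[1] - interval[0]
            )
            assert interval_average(KIN, interval) == pytest.approx(numeric, rel=1e-8)

    def test_average_below_endpoint_on_rising_window(self):
        assert interval_average(KIN, (0, 30)) < true_concentration(KIN, 30)

    def test_degenerate_interval_rejected(self):
        with pytest.raises(ValueError):
            interval_average(KIN, (30, 30))


class TestKineticsCalibration:
    @pytest.mark.parametrize("comp, target", sorted(DEFAULT_PEAK_TARGETS.items()))
    def test_default_kinetics_hit_peak_targets(self, comp, target):
        cmax, tmax = target
        cf = closed_form_nca(default_kinetics()[comp], 480)
        assert cf.cmax == pytest.approx(cmax, rel=1e-9)
        assert cf.tmax == pytest.approx(tmax, rel=1e-9)

    def test_population_peaks_inside_study_envelope(self):
        """Tissue Cmax within 10-26 ug/mL and Tmax within 105-206 min."""
        for comp in TISSUE_COMPARTMENTS:
            cf = closed_form_nca(default_kinetics()[comp], 480)
            assert 10.0 <= cf.cmax <= 26.0
            assert 105.0 <= cf.tmax <= 206.0


class TestNoiseModel:
    def test_cv_matches_ladder_at_its_points(self):
        nm = NoiseModel()
        for conc, cv in nm.ladder:
            assert nm.cv_percent(conc) == pytest.approx(cv)

    def test_cv_clamped_outside_ladder(self):
        nm = NoiseModel()
        assert nm.cv_percent(0.001) == pytest.approx(20.8)
        assert nm.cv_percent(1e4) == pytest.approx(6.8)

    def test_factors_have_unit_mean_and_ladder_cv(self):
        nm = NoiseModel()
        rng = np.random.default_rng(3)
        factors = nm.factors(rng, np.full(200_000, 4.0))
        assert factors.mean() == pytest.approx(1.0, rel=5e-3)
        assert factors.std() == pytest.approx(0.097, rel=0.02)


class TestDialysateSeries:
    schedule = build_schedule()

    def _state(self, rr=100.0, status="ok"):
        return TrueCatheterState("pig01", "liver", rr, status)

    def test_noise_free_full_recovery_is_identity(self):
        series = simulate_dialysate_series(
            KIN, self._state(), self.schedule, None, np.random.default_rng(0)
        )
        expected = np.array([interval_average(KIN, iv) for iv in self.schedule])
        assert np.array_equal(series["conc_ug_per_ml"].to_numpy(), expected)
        assert (series["below_loq"] == 0).all()

    def test_half_recovery_halves_measurements(self):
        series = simulate_dialysate_series(
            KIN, self._state(rr=50.0), self.schedule, None, np.random.default_rng(0)
        )
        expected = 0.5 * np.array([interval_average(KIN, iv) for iv in self.schedule])
        assert np.allclose(series["conc_ug_per_ml"], expected, rtol=1e-15)

    def test_failed_catheter_yields_no_samples(self):
        series = simulate_dialysate_series(
            KIN, self._state(status="displaced"), self.schedule, None, np.random.default_rng(0)
        )
        assert series.empty

    def test_fixed_seed_is_deterministic(self):
        nm = NoiseModel()
        a = simulate_dialysate_series(KIN, self._state(), self.schedule, nm, np.random.default_rng(11))
        b = simulate_dialysate_series(KIN, self._state(), self.schedule, nm, np.random.default_rng(11))
        assert a.equals(b)

    def test_censoring_flags_iff_below_loq(self):
        """Censored flags appear exactly when the pre-censoring value < LOQ."""
        tiny = TissueKinetics("tiny", amplitude=0.02, k_uptake=0.02, k_elim=0.005)
        nm = NoiseModel()
        rng = np.random.default_rng(5)
        series = simulate_dialysate_series(tiny, self._state(), self.schedule, nm, rng)
        assert series["below_loq"].sum() > 0
        flagged = series["below_loq"] == 1
        assert (series.loc[flagged, "conc_ug_per_ml"] == nm.loq_ug_per_ml).all()
        assert (series.loc[~flagged, "conc_ug_per_ml"] >= nm.loq_ug_per_ml).all()


class TestRetrodialysis:
    def test_liver_mean_recovery_leaves_10p5(self):
        """A catheter recovering 89.5% leaves 10.5 ug/mL in a 100 ug/mL perfusate."""
        state = TrueCatheterState("pig01", "liver", 89.5)
        pair = simulate_retrodialysis_pair(state, 100.0, None, np.random.default_rng(0))
        assert np.allclose(pair["dialysate_conc_ug_per_ml"], 10.5)
        assert len(pair) == 2

    def test_complete_recovery_leaves_nothing(self):
        state = TrueCatheterState("pig01", "liver", 100.0)
        pair = simulate_retrodialysis_pair(state, 100.0, None, np.random.default_rng(0))
        assert (pair["dialysate_conc_ug_per_ml"] == 0.0).all()


class TestStudySimulation:
    def test_default_design_counts(self):
        cfg = StudyConfig(p_malfunction=0.0, p_displaced=0.0, seed=1)
        study = simulate_study(cfg)
        dial = study.samples[study.samples.sample_type == "dialysate"]
        plasma = study.samples[study.samples.sample_type == "plasma"]
        assert len(dial) == 8 * 8 * 12
        assert len(plasma) == 8 * 12
        assert len(study.calibration) == 8 * 8 * 2
        assert study.ledger.n_ok == 64

    def test_same_seed_reproduces_dataset_exactly(self):
        a = simulate_study(StudyConfig(seed=9))
        b = simulate_study(StudyConfig(seed=9))
        assert a.samples.equals(b.samples)
        assert a.calibration.equals(b.calibration)
        assert [s.true_rr_percent for s in a.truth.catheter_states] == [
            s.true_rr_percent for s in b.truth.catheter_states
        ]

    def test_all_measurements_non_negative(self, noisy_study):
        assert (noisy_study.samples["conc_ug_per_ml"] >= 0).all()

    def test_true_recoveries_within_percentage_range(self, noisy_study):
        rrs = [s.true_rr_percent for s in noisy_study.truth.catheter_states]
        assert all(0 < rr <= 100 for rr in rrs)

    def test_failed_catheters_contribute_nothing(self, noisy_study):
        failed = {
            (s.animal_id, s.compartment)
            for s in noisy_study.truth.catheter_states
            if s.status != "ok"
        }
        assert failed, "default dropout rates should lose some catheters at this seed"
        dial = noisy_study.samples[noisy_study.samples.sample_type == "dialysate"]
        observed = set(zip(dial.animal_id, dial.compartment))
        assert observed.isdisjoint(failed)

    def test_truth_json_round_trip(self, tmp_path, noisy_study):
        path = tmp_path / "truth.json"
        noisy_study.truth.to_json(path)
        import json

        loaded = json.loads(path.read_text())
        assert loaded["seed"] == noisy_study.truth.seed
        assert set(loaded["kinetics"]) == set(TISSUE_COMPARTMENTS) | {PLASMA}

    def test_plasma_sampled_at_midpoints_without_recovery(self):
        cfg = StudyConfig(noise=False, p_malfunction=0.0, p_displaced=0.0, seed=2)
        study = simulate_study(cfg)
        plasma = study.samples[study.samples.sample_type == "plasma"]
        kin = study.truth.kinetics[PLASMA]
        one = plasma[plasma.animal_id == "pig01"].sort_values("midpoint_min")
        expected = true_concentration(kin, one["midpoint_min"].to_numpy())
        assert np.allclose(one["conc_ug_per_ml"], expected, rtol=1e-15)
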