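"""Ensemble statistics: ramp CV, histograms, survival, scans."""

import numpy as np
import pytest

import ripoptosim as rs
from ripoptosim.hybrid import DeathEvent, Scenario
from ripoptosim.params import ValidationError
from ripoptosim.population import (EnsembleResult, delay_histogram,
                                   parameter_scan, population_average,
                                   ramp_cv, run_ensemble, survival_fraction)
from _helpers import make_traj


class TestRampCV:
    def test_constant_rate_zero_cv(self):
        t = np.arange(100.0)
        traj = make_traj(t, np.full(100, 2.0))
        assert ramp_cv(traj, DeathEvent(None, 1.0)) == 0.0

    def test_alternating_rate_cv_one(self):
        """Rates {0, 2r} on a uniform grid: mean r, population std r, CV 1."""
        t = np.arange(100.0)
        rate = np.tile([0.0, 4.0], 50)
        traj = make_traj(t, rate)
        assert ramp_cv(traj, DeathEvent(None, 1.0)) == pytest.approx(1.0)

    def test_window_excludes_post_death_points(self):
        t = np.arange(10.0)
        rate = np.array([1.0] * 5 + [100.0] * 5)
        cv_all = ramp_cv(make_traj(t, rate), DeathEvent(None, 1.0))
        cv_ramp = ramp_cv(make_traj(t, rate), DeathEvent(5.0, 1.0))
        assert cv_ramp == 0.0
        assert cv_all > 0.9

    def test_zero_mean_defined_as_zero(self):
        t = np.arange(5.0)
        assert ramp_cv(make_traj(t, np.zeros(5)), DeathEvent(None, 1.0)) == 0.0

    def test_increment_variant(self):
        t = np.arange(50.0)
        rate = np.linspace(0, 5, 50)
        traj = make_traj(t, rate)
        a = ramp_cv(traj, DeathEvent(None, 1.0), cv_on="rate")
        b = ramp_cv(traj, DeathEvent(None, 1.0), cv_on="increments")
        assert a > 0 and b > 0
        with pytest.raises(ValidationError):
            ramp_cv(traj, DeathEvent(None, 1.0), cv_on="bogus")


def _mini_ensemble(cfg, n=4, dose=50.0, clustering=True, seed=21, t_max=90.0):
    return run_ensemble(cfg, Scenario(dose, clustering), n, seed, t_max=t_max)


def test_single_cell_ensemble_reduces_to_hybrid(cfg):
    res = _mini_ensemble(cfg, n=1)
    from ripoptosim.hybrid import derive_cell_seed
    traj, death = rs.simulate_cell_hybrid(
        cfg, 50.0, True, derive_cell_seed(21, 0), t_max=90.0)
    assert res.death_times[0] == pytest.approx(death.death_time)


def test_ensemble_reproducible_under_master_seed(cfg):
    a = _mini_ensemble(cfg, n=5)
    b = _mini_ensemble(cfg, n=5)
    np.testing.assert_array_equal(a.death_times, b.death_times)
    np.testing.assert_array_equal(a.ramp_cvs, b.ramp_cvs)


def test_ensemble_cells_independent_of_ensemble_size(cfg):
    """Per-cell streams derive from (master_seed, index): the first cells of a
    larger ensemble replicate a smaller one (order/parallelization contract)."""
    a = _mini_ensemble(cfg, n=3)
    b = _mini_ensemble(cfg, n=6)
    np.testing.assert_array_equal(a.death_times, b.death_times[:3])


def test_ensemble_validation(cfg):
    with pytest.raises(ValidationError):
        run_ensemble(cfg, Scenario(5.0, True), 0, 1)


def synthetic_result(delays, t_max=1440.0, cvs=None):
    delays = np.asarray(delays, dtype=float)
    n = delays.size
    censored = np.isnan(delays)
    if cvs is None:
        cvs = np.linspace(1.0, 0.1, n)
    z = np.zeros((n, 3))
    return EnsembleResult(
        scenario=Scenario(5.0, True), n_cells=n, master_seed=0, t_max=t_max,
        death_times=delays, censored=censored, ramp_cvs=np.asarray(cvs),
        seeds=np.zeros(n, dtype=np.int64), times=np.arange(3.0),
        cum_active_casp8=z, fret_rate=z, mean_fadd=z, max_mass=z,
    )


class TestDelayHistogram:
    def test_identical_delays_not_bimodal(self):
        res = synthetic_result(np.full(50, 300.0))
        rep = delay_histogram(res, dip_boot=200)
        assert rep.dip_pvalue >= 0.05
        assert not rep.bimodal

    def test_known_mixture_flagged_bimodal(self):
        delays, expected = rs.generate_fixtures("two_mode_delays", seed=3)
        rep = delay_histogram(synthetic_result(delays), dip_boot=300)
        assert rep.bimodal == expected["bimodal"]
        assert rep.dip_pvalue < 0.05
        assert rep.ashman_d is None or rep.ashman_d > 2.0

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValidationError):
            delay_histogram(synthetic_result(np.full(5, 100.0)))

    def test_histogram_counts_cover_all_deaths(self):
        res = synthetic_result(np.linspace(30, 900, 40))
        rep = delay_histogram(res, bin_width=60.0)
        assert rep.counts.sum() == 40


class TestSurvival:
    def test_zero_horizon(self):
        res = synthetic_result(np.linspace(10, 100, 20))
        assert survival_fraction(res, 0.0) == 1.0

    def test_all_dead(self):
        res = synthetic_result(np.linspace(10, 100, 20))
        assert survival_fraction(res, 200.0) == 0.0

    def test_censored_count_as_survivors(self):
        d = np.array([50.0, np.nan, 150.0, np.nan])
        res = synthetic_result(d)
        assert survival_fraction(res, 100.0) == pytest.approx(0.75)
        assert survival_fraction(res, 1000.0) == pytest.approx(0.5)


class TestPopulationAverage:
    def test_identical_traces_zero_cv(self):
        arr = np.tile(np.linspace(0, 5, 20), (6, 1))
        mean, cv = population_average(arr)
        np.testing.assert_allclose(cv, 0.0, atol=1e-12)
        np.testing.assert_allclose(mean, arr[0])

    def test_misaligned_grid_rejected(self):
        arr = np.zeros((3, 10))
        with pytest.raises(ValidationError):
            population_average(arr, times=np.arange(7))
        with pytest.raises(ValidationError):
            population_average(arr[:1])


class TestParameterScan:
    def test_unknown_parameter_rejected(self, cfg):
        with pytest.raises(ValidationError):
            parameter_scan(cfg, "volume", [1.0], 5.0)
        with pytest.raises(ValidationError):
            parameter_scan(cfg, "xiap_total", [], 5.0)

    def test_single_value_reduces_to_one_model_run(self, cfg):
        scan = parameter_scan(cfg, "xiap_total", [63.0], 5.0)
        direct = rs.deterministic_full_model(cfg, 5.0, clustering=True)
        assert scan.death_delays[0] == pytest.approx(direct.death_time)

    def test_procasp6_scan_runs(self, cfg):
        scan = parameter_scan(cfg, "procasp6_total", [30.0, 60.0, 120.0], 5.0)
        assert np.isfinite(scan.death_delays).all()
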