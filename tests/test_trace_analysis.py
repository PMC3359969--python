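"""Interval extraction, Hill fits, dwell-time fits and power spectra."""

import math

import numpy as np
import pytest
from scipy import stats

from confspread import (
    ModelParams,
    SimConfig,
    Trajectory,
    cw_bias,
    domain_occupancy,
    extract_intervals,
    fit_exponential,
    fit_gamma,
    hill_fit,
    power_spectrum,
    sensitivity_curve,
    simulate,
)

DT = 1e-4


def make_traj(n_active, n=34, dt=DT):
    na = np.asarray(n_active, dtype=np.int16)
    nd = np.where((na == 0) | (na == n), 1, 2).astype(np.int16)
    return Trajectory(
        dt_sample=dt,
        n_active=na,
        n_bound=na.copy(),
        n_domains=nd,
        n_protomers=n,
    )


class TestExtractIntervals:
    def test_single_switch_hand_crafted(self):
        # enters CW at sample 0, last CW sample at 1, enters CCW at sample 5
        traj = make_traj([34, 34, 30, 20, 5, 0, 0])
        ivs = extract_intervals(traj)
        assert ivs.n_switches == 1
        dur, direction = ivs.switch_times[0]
        assert direction == "CW->CCW"
        assert dur == pytest.approx(4 * DT)
        assert ivs.locked_intervals == [(pytest.approx(5 * DT), "CW")]

    def test_locked_interval_is_entry_to_entry(self):
        # five CCW samples, then a two-step climb to CW
        traj = make_traj([0, 0, 0, 0, 0, 10, 34])
        ivs = extract_intervals(traj)
        (dur, side), = ivs.locked_intervals
        assert side == "CCW"
        assert dur == pytest.approx(6 * DT)
        assert ivs.switch_times[0][0] == pytest.approx(2 * DT)
        assert ivs.switch_times[0][1] == "CCW->CW"

    def test_no_alternation_flags_incomplete(self):
        ivs = extract_intervals(make_traj([34] * 50))
        assert not ivs.complete
        assert ivs.locked_intervals == [] and ivs.switch_times == []

    def test_intervals_tile_the_record(self, bestfit_traj):
        # entry-to-entry definition: locked intervals sum exactly to the span
        # between first and last locked-state entries
        ivs = extract_intervals(bestfit_traj)
        na = np.asarray(bestfit_traj.n_active)
        n = bestfit_traj.n_protomers
        level = np.where(na == n, 1, np.where(na == 0, -1, 0))
        nz = np.flatnonzero(level)
        s = level[nz]
        entries = nz[np.concatenate(([0], np.flatnonzero(np.diff(s) != 0) + 1))]
        span = (entries[-1] - entries[0]) * bestfit_traj.dt_sample
        assert ivs.durations().sum() == pytest.approx(span, rel=1e-12)

    def test_sides_alternate_and_switch_bounded(self, bestfit_traj):
        ivs = extract_intervals(bestfit_traj)
        sides = [s for _, s in ivs.locked_intervals]
        assert all(a != b for a, b in zip(sides, sides[1:]))
        for (locked, _), (sw, _) in zip(ivs.locked_intervals, ivs.switch_times):
            assert sw <= locked + 1e-12

    def test_switch_direction_independence(self, bestfit_traj):
        # switch-time statistics do not depend on the direction of the switch
        ivs = extract_intervals(bestfit_traj)
        fwd = ivs.switch_durations("CCW->CW")
        rev = ivs.switch_durations("CW->CCW")
        assert min(len(fwd), len(rev)) > 50
        assert stats.ks_2samp(fwd, rev).pvalue > 0.01


class TestCwBias:
    def test_saturated(self):
        assert cw_bias(make_traj([34] * 10)) == 1.0
        assert cw_bias(make_traj([0] * 10)) == 0.0

    def test_even_split(self):
        assert cw_bias(make_traj([34] * 5 + [0] * 5)) == 0.5

    def test_tie_counts_half(self):
        assert cw_bias(make_traj([17] * 10)) == 0.5


class TestHillFit:
    def test_recovers_exact_hill_exponent(self):
        h_true = 10.0
        c = np.geomspace(0.75, 1.33, 7)
        pts = [(ci, ci**h_true / (1 + ci**h_true)) for ci in c]
        fit = hill_fit(pts)
        assert fit.h == pytest.approx(h_true, abs=1e-6)

    @pytest.mark.parametrize("window", [(0.15, 0.85), (0.2, 0.8), (0.05, 0.95)])
    def test_window_independent_on_exact_data(self, window):
        h_true = 6.0
        c = np.geomspace(0.5, 2.0, 15)
        pts = [(ci, ci**h_true / (1 + ci**h_true)) for ci in c]
        assert hill_fit(pts, fit_window=window).h == pytest.approx(h_true, abs=1e-9)

    def test_flat_response_has_zero_slope(self):
        pts = [(c, 0.5) for c in (0.5, 1.0, 2.0)]
        assert hill_fit(pts).h == pytest.approx(0.0, abs=1e-12)

    def test_saturated_points_are_excluded(self):
        h_true = 4.0
        c = np.geomspace(0.3, 3.0, 11)
        pts = [(ci, ci**h_true / (1 + ci**h_true)) for ci in c]
        fit = hill_fit(pts)
        assert fit.n_used < len(pts)
        assert fit.h == pytest.approx(h_true, abs=1e-6)

    def test_too_few_points_in_window(self):
        with pytest.raises(ValueError):
            hill_fit([(0.5, 0.01), (1.0, 0.5), (2.0, 0.99)])


class TestDwellTimeFits:
    def test_exponential_estimator_consistency(self, rng):
        sample = rng.exponential(0.74, 10_000)
        fit = fit_exponential(sample)
        se = 0.74 / math.sqrt(sample.size)
        assert fit.mean == pytest.approx(0.74, abs=3 * se)
        assert fit.rate == pytest.approx(1 / fit.mean)
        assert fit.ks_pvalue > 0.01
        # the log-linear histogram slope is a rougher estimate of the rate
        assert fit.hist_rate == pytest.approx(fit.rate, rel=0.25)

    def test_constant_durations_rejected_as_exponential(self):
        fit = fit_exponential([0.5] * 200)
        assert fit.ks_pvalue < 0.01

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_exponential([0.1] * 10)

    def test_gamma_estimator_consistency(self, rng):
        sample = rng.gamma(2.0, 0.03, 10_000)
        fit = fit_gamma(sample)
        assert fit.shape == pytest.approx(2.0, rel=0.05)
        assert fit.mean == pytest.approx(sample.mean(), rel=0.01)
        assert fit.sd == pytest.approx(fit.scale * math.sqrt(fit.shape))

    def test_gamma_of_exponential_sample_has_unit_shape(self, rng):
        sample = rng.exponential(0.1, 20_000)
        assert fit_gamma(sample).shape == pytest.approx(1.0, rel=0.05)

    def test_nonpositive_durations_rejected(self):
        with pytest.raises(ValueError):
            fit_gamma([0.1] * 50 + [0.0])


class TestDomainOccupancy:
    def test_fully_locked_trace(self):
        occ = domain_occupancy(make_traj([34] * 100))
        assert occ == {1: 1.0}

    def test_fractions_sum_to_one(self, duke_traj):
        occ = domain_occupancy(duke_traj)
        assert sum(occ.values()) == pytest.approx(1.0)
        assert set(occ) <= {1, 2, 4, 6, 8, 10}

    def test_opposite_state_convention(self):
        traj = make_traj([34, 34, 20, 0])
        traj.n_domains = np.array([1, 1, 4, 1], dtype=np.int16)
        occ = domain_occupancy(traj, opposite_state_convention=True)
        assert occ == {0: 0.75, 2: 0.25}


def synthetic_telegraph(rate, duration, dt, rng):
    """Two-state telegraph signal with the given per-direction switching rate."""
    n = int(duration / dt)
    out = np.empty(n, dtype=np.int16)
    t_next = rng.exponential(1 / rate)
    state = 1
    for i in range(n):
        t = i * dt
        while t >= t_next:
            state = 1 - state
            t_next += rng.exponential(1 / rate)
        out[i] = state * 34
    return make_traj(out, dt=dt)


class TestPowerSpectrum:
    def test_constant_trace_has_no_power(self):
        spec = power_spectrum(make_traj([17] * 4096), n_segments=4)
        assert np.allclose(spec.power, 0.0)

    def test_telegraph_corner_frequency(self, rng):
        # a symmetric telegraph with rate k each way has a Lorentzian spectrum
        # with corner at f_c = k / pi
        k = 20.0
        traj = synthetic_telegraph(k, duration=400.0, dt=1e-3, rng=rng)
        spec = power_spectrum(traj, n_segments=16)
        assert spec.fc == pytest.approx(k / math.pi, rel=0.15)
        assert not spec.has_interior_peak

    def test_oscillation_flags_interior_peak(self, rng):
        # positive control: a resonant (multi-step-like) signal has a
        # spectral local maximum that the detector must report
        dt = 1e-3
        t = np.arange(400_000) * dt
        sig = 10 * np.sin(2 * math.pi * 5.0 * t) + rng.normal(0, 3, t.size) + 17
        spec = power_spectrum(make_traj(sig.astype(np.int16), dt=dt), n_segments=16)
        assert spec.has_interior_peak

    def test_too_short_trace(self):
        with pytest.raises(ValueError):
            power_spectrum(make_traj([0, 34] * 10), n_segments=8)


class TestSensitivityCurve:
    def test_symmetric_response_mirrors_in_concentration(self):
        # for ea0 == ea1 the model maps (c, Y) -> (1/c, 1-Y)
        p = ModelParams(ea0=0.65, ea1=0.65, ej=4.15, n_protomers=10)
        cs = [0.8, 1.25]
        biases = {}
        for i, c in enumerate(cs):
            traj = simulate(p.replace(c_rel=c), SimConfig(duration=40.0, seed=300 + i))
            biases[c] = cw_bias(traj)
        assert biases[0.8] == pytest.approx(1 - biases[1.25], abs=0.1)

    def test_fits_simulated_points(self):
        p = ModelParams(ea0=0.65, ea1=0.65, ej=4.15, n_protomers=10)
        grid = np.geomspace(0.6, 1.65, 7)
        curve = sensitivity_curve(p, grid, duration=20.0, seed=41)
        assert len(curve.points) == 7
        assert curve.n_used >= 3
        assert 1.0 < curve.h < 6.0
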