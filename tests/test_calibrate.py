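"""Rms-width statistics, quartic calibration, inversion, mixing flags."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rmwcal as rc
from rmwcal.calibrate import (
    deviation_stats,
    fit_calibration,
    infer_wepl,
    range_mixing_flag,
    rms_width,
    select_window,
    session_sigma,
)
from rmwcal.scoring import DoseRateProfile


def _profile(rates, bin_width=0.25):
    return DoseRateProfile(bin_width_ms=bin_width, dose_rate=np.asarray(rates, float),
                           wepl_cm=0.0)


def _brute_moments(times, weights):
    """Independent brute-force weighted-moment oracle (plain python sums)."""
    s = float(sum(weights))
    tbar = sum(w * t for t, w in zip(times, weights)) / s
    m2 = sum(w * (t - tbar) ** 2 for t, w in zip(times, weights)) / s
    m3 = sum(w * (t - tbar) ** 3 for t, w in zip(times, weights)) / s
    m4 = sum(w * (t - tbar) ** 4 for t, w in zip(times, weights)) / s
    sd = m2 ** 0.5
    return sd, m3 / sd**3, m4 / sd**4 - 3.0


class TestRmsWidth:
    def test_uniform_full_cycle_closed_form(self):
        # point-mass moments over n bin centers: the continuous 100/sqrt(12)
        # up to the discrete correction sqrt((n^2-1)/n^2), ~3e-6 at n=400
        stat = rms_width(_profile(np.ones(400)))
        assert stat.sigma_rms_ms == pytest.approx(100.0 / np.sqrt(12.0), rel=1e-5)
        n = 400
        exact = (100.0 / np.sqrt(12.0)) * np.sqrt((n**2 - 1) / n**2)
        assert stat.sigma_rms_ms == pytest.approx(exact, rel=1e-12)
        assert stat.skewness == pytest.approx(0.0, abs=1e-9)

    def test_single_bin_is_degenerate_point_mass(self):
        rates = np.zeros(400)
        rates[37] = 5.0
        stat = rms_width(_profile(rates))
        assert stat.sigma_rms_ms == 0.0
        assert stat.skewness == 0.0
        assert stat.degenerate

    def test_rectangular_burst_closed_form(self):
        rates = np.zeros(400)
        rates[:80] = 2.0  # [0, 20) ms
        stat = rms_width(_profile(rates))
        assert stat.sigma_rms_ms == pytest.approx(20.0 / np.sqrt(12.0), rel=1e-4)
        n = 80  # discrete point-mass correction over 80 bins
        exact = (20.0 / np.sqrt(12.0)) * np.sqrt((n**2 - 1) / n**2)
        assert stat.sigma_rms_ms == pytest.approx(exact, rel=1e-12)
        assert stat.skewness == pytest.approx(0.0, abs=1e-9)

    def test_all_zero_signal_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            rms_width(_profile(np.zeros(400)))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            rates = rng.random(400) * rng.integers(1, 100)
            prof = _profile(rates)
            got = rms_width(prof)
            sd, sk, ku = _brute_moments(list(prof.times_ms), list(rates))
            assert got.sigma_rms_ms == pytest.approx(sd, rel=1e-12)
            assert got.skewness == pytest.approx(sk, rel=1e-9, abs=1e-12)
            assert got.excess_kurtosis == pytest.approx(ku, rel=1e-9, abs=1e-12)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), seed=st.integers(0, 100))
    def test_amplitude_invariance(self, scale, seed):
        rates = np.random.default_rng(seed).random(400) + 0.01
        a = rms_width(_profile(rates))
        b = rms_width(_profile(rates * scale))
        assert b.sigma_rms_ms == pytest.approx(a.sigma_rms_ms, rel=1e-9)
        assert b.skewness == pytest.approx(a.skewness, rel=1e-9)
        assert b.excess_kurtosis == pytest.approx(a.excess_kurtosis, rel=1e-9)


class TestSessionSigma:
    def test_counts_and_noise_free_limit(self, beam10, water):
        sess = rc.generate_session(
            beam10, water, [9.0], noise=rc.NoiseModel.noiseless(), seed=0
        )
        summary, records = session_sigma(sess)
        assert len(records) == 12 * 19
        ref = rms_width(rc.score_profile(beam10, water, 9.0)).sigma_rms_ms
        assert summary.sigma_ms.iloc[0] == pytest.approx(ref, abs=0.05)
        assert summary.se_ms.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_se_shrinks_with_more_cycles(self, beam10, water):
        short = rc.generate_session(beam10, water, [9.0], seed=3, n_cycles=19)
        long = rc.generate_session(beam10, water, [9.0], seed=3, n_cycles=76)
        se_short = session_sigma(short)[0].se_ms.iloc[0]
        se_long = session_sigma(long)[0].se_ms.iloc[0]
        # 4x the cycles: SE should drop by about half
        assert se_long < 0.75 * se_short


class TestSelectWindow:
    @pytest.mark.parametrize("key", ["10/9.9", "15/14", "21/18"])
    def test_window_contains_expected_detector_region(self, beams, calibrations, key):
        _, window, _ = calibrations[key]
        detector = beams[key].prescribed_range_cm - 1.0
        assert window[0] <= detector - 0.5
        assert window[1] >= detector + 0.5

    def test_lower_edge_two_cm_inside_proximal_edge(self, beams, calibrations):
        _, window, _ = calibrations["10/9.9"]
        # proximal edge of the 10/9.9 plateau is near 0.1 cm
        assert window[0] == pytest.approx(2.1, abs=0.3)

    def test_small_modulation_gives_empty_window(self, water):
        beam = rc.design_scout_beam(9.0, 2.4)
        scan = rc.scan_plateau(beam, water)
        with pytest.raises(ValueError, match="empty calibration window"):
            select_window(scan, beam)


class TestFitCalibration:
    WINDOW = (2.0, 9.0)

    def test_exact_quartic_recovered(self):
        coef = np.array([30.0, -2.2, 0.05, -0.004, 0.0001])
        w = np.linspace(*self.WINDOW, 30)
        s = np.polynomial.polynomial.polyval(w, coef)
        assert (np.diff(s) < 0).all()  # monotone decreasing by construction
        curve = fit_calibration(w, s, window=self.WINDOW)
        np.testing.assert_allclose(curve.coefficients, coef, atol=1e-9)
        assert curve.adjusted_r2 == pytest.approx(1.0, abs=1e-12)

    def test_five_points_insufficient_dof(self):
        w = np.linspace(2, 9, 5)
        with pytest.raises(ValueError, match="insufficient dof"):
            fit_calibration(w, 30 - 2 * w)

    def test_non_monotone_fit_rejected(self):
        w = np.linspace(2, 9, 40)
        s = (w - 5.5) ** 2  # parabola: not invertible
        with pytest.raises(ValueError, match="not invertible"):
            fit_calibration(w, s, window=self.WINDOW)

    @pytest.mark.parametrize("key", ["10/9.9", "15/14", "21/18"])
    def test_sigma_strictly_decreasing_on_window(self, calibrations, key):
        scan, window, _ = calibrations[key]
        sel = (scan.wepl_grid_cm >= window[0]) & (scan.wepl_grid_cm <= window[1])
        sigmas = np.array(
            [rms_width(scan.profile(i)).sigma_rms_ms
             for i in np.flatnonzero(sel)]
        )
        assert (np.diff(sigmas) < 0).all()


class TestInferWepl:
    def test_round_trip_inversion(self, cal10):
        _, window, curve = cal10
        for w0 in [3.0, 6.0, 9.0]:
            est = infer_wepl(curve, float(curve(w0)))
            assert est.wepl_cm == pytest.approx(w0, abs=1e-3)

    def test_sigma_outside_range_rejected(self, cal10):
        _, _, curve = cal10
        with pytest.raises(ValueError, match="out of calibration range"):
            infer_wepl(curve, 60.0)

    def test_steeper_slope_gives_smaller_se(self, cal10):
        _, _, curve = cal10
        # the curve steepens toward the distal end
        shallow = infer_wepl(curve, float(curve(4.0)), se_ms=0.1)
        deep = infer_wepl(curve, float(curve(9.0)), se_ms=0.1)
        assert abs(curve.derivative(9.0)) > abs(curve.derivative(4.0))
        assert deep.se_cm < shallow.se_cm

    def test_noiseless_round_trip_identity_across_window(self, beam10, water, cal10):
        scan, window, curve = cal10
        sel = (scan.wepl_grid_cm >= window[0]) & (scan.wepl_grid_cm <= window[1])
        idx = np.flatnonzero(sel)[:: max(1, sel.sum() // 40)]
        for i in idx:
            sigma = rms_width(scan.profile(i)).sigma_rms_ms
            est = infer_wepl(curve, sigma)
            # systematic quartic-fit residual only: within the grid scale
            assert est.wepl_cm == pytest.approx(scan.wepl_grid_cm[i], abs=0.1)


class TestDeviationStats:
    def test_perfect_estimates(self):
        d = deviation_stats([1.0, 2.0], [1.0, 2.0])
        assert (d.mean_mm, d.sd_mm, d.max_mm) == (0.0, 0.0, 0.0)

    def test_arithmetic(self):
        d = deviation_stats([1.1, 2.2, 3.3], [1.0, 2.0, 3.0])
        assert d.mean_mm == pytest.approx(2.0)
        assert d.max_mm == pytest.approx(3.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deviation_stats([1.0], [1.0, 2.0])


class TestRangeMixingFlag:
    def test_reference_profile_not_flagged(self, beam10, water, cal10):
        scan, _, curve = cal10
        i = int(np.argmin(np.abs(scan.wepl_grid_cm - 8.0)))
        flagged, score, _ = range_mixing_flag(rms_width(scan.profile(i)), curve, scan)
        assert not flagged
        assert score <= 3.0

    def test_mixture_of_two_wepls_flagged(self, beam10, water, cal10):
        scan, _, curve = cal10
        i = int(np.argmin(np.abs(scan.wepl_grid_cm - 8.5)))
        j = int(np.argmin(np.abs(scan.wepl_grid_cm - 9.5)))
        mixed = 0.5 * scan.rates[i] + 0.5 * scan.rates[j]
        stat = rms_width(_profile(mixed))
        flagged, score, reason = range_mixing_flag(stat, curve, scan)
        assert flagged
        assert score > 3.0

    def test_amplitude_scaling_never_changes_flag(self, cal10):
        scan, _, curve = cal10
        i = int(np.argmin(np.abs(scan.wepl_grid_cm - 8.5)))
        j = int(np.argmin(np.abs(scan.wepl_grid_cm - 9.5)))
        for scale in [1e-3, 1.0, 1e3]:
            mixed = scale * (0.5 * scan.rates[i] + 0.5 * scan.rates[j])
            flagged, _, _ = range_mixing_flag(rms_width(_profile(mixed)), curve, scan)
            assert flagged

    def test_degenerate_profile_flagged_with_reason(self, cal10):
        _, _, curve = cal10
        scan = cal10[0]
        stat = rc.RmsWidthStat(0.0, 0.0, 0.0, degenerate=True)
        flagged, _, reason = range_mixing_flag(stat, curve, scan)
        assert flagged
        assert reason == "degenerate"
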