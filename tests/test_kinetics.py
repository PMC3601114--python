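"""Stance detection, CoM power/work, approach speed, force peaks."""

import numpy as np
import pytest

from synergyflow import kinetics as kin
from synergyflow import synthetic


class TestDetectStance:
    def test_step_function(self):
        fz_trace = np.zeros(1000)
        fz_trace[500:] = 100.0
        ev = kin.detect_stance(fz_trace, rate=1000.0)
        assert ev.ic == 500
        assert ev.toe_off == 1000  # still loaded at the end of the trace

    def test_single_sample_spike_debounced(self):
        fz_trace = np.zeros(1000)
        fz_trace[100] = 25.0
        fz_trace[500:900] = 300.0
        ev = kin.detect_stance(fz_trace, rate=1000.0, debounce_ms=5)
        assert ev.ic == 500
        assert ev.toe_off == 900

    def test_short_unloading_dip_bridged(self):
        fz_trace = np.zeros(1000)
        fz_trace[200:800] = 400.0
        fz_trace[450:453] = 0.0  # 3 ms dip, below the 5 ms debounce
        ev = kin.detect_stance(fz_trace, rate=1000.0, debounce_ms=5)
        assert ev.toe_off == 800

    def test_no_contact_raises(self):
        with pytest.raises(ValueError, match="never exceeds"):
            kin.detect_stance(np.full(100, 5.0), rate=1000.0)

    def test_matches_planted_events(self):
        trace, planted = synthetic.synthesize_kinetics(330, 71, 1500, 2.67, seed=3)
        ev = kin.detect_stance(trace.fz, trace.rate)
        assert abs(ev.ic - planted.ic) <= 1
        assert abs(ev.toe_off - planted.toe_off) <= 1

    def test_invariant_to_subthreshold_baseline_noise(self):
        trace, planted = synthetic.synthesize_kinetics(seed=5)
        rng = np.random.default_rng(0)
        noisy = trace.fz + rng.uniform(0, 9.0, trace.fz.size)  # < threshold/2
        ev = kin.detect_stance(noisy, trace.rate)
        assert abs(ev.ic - planted.ic) <= 1


class TestComPower:
    def test_downward_velocity_under_load_gives_negative_power(self):
        grf = np.zeros((3, 10))
        grf[2] = 710.0
        v = np.zeros((3, 10))
        v[2] = -0.5
        p = np.einsum("ij,ij->j", grf, v) / 71.0
        assert np.all(p < 0)

    def test_constant_negative_power_work_oracle(self):
        """-10 W/kg sustained for 0.1 s integrates to exactly -1 J/kg."""
        rate, mass = 1000.0, 70.0
        n_neg, n_pos = 101, 100  # 101 samples = 100 intervals = 0.1 s
        grf = np.zeros((3, n_neg + n_pos))
        grf[2] = mass  # so power (W/kg) equals vertical velocity
        v = np.zeros((3, n_neg + n_pos))
        v[2, :n_neg] = -10.0
        v[2, n_neg:] = 10.0
        res = kin.com_power(grf, v, mass, rate)
        assert res.w_lac == pytest.approx(-1.0, abs=1e-9)
        assert res.w_prp == pytest.approx(0.99, abs=1e-9)

    def test_work_signs_invariant(self):
        trace, ev = synthetic.synthesize_kinetics(seed=2)
        res = kin.com_power(trace.grf, trace.com_velocity, trace.body_mass,
                            trace.rate, events=ev)
        assert res.w_lac <= 0 <= res.w_prp
        assert res.la_span[1] <= res.prp_span[0]

    def test_phase_work_sums_to_full_trace_integral(self):
        trace, ev = synthetic.synthesize_kinetics(seed=1)
        res = kin.com_power(trace.grf, trace.com_velocity, trace.body_mass,
                            trace.rate, events=ev)
        from scipy.integrate import trapezoid

        total = trapezoid(res.com_power[ev.ic : ev.toe_off], dx=1 / trace.rate)
        # one sign change: the two phase integrals tile the stance integral
        assert res.w_lac + res.w_prp == pytest.approx(total, abs=1e-6)

    def test_per_weight_convention_scales_by_g(self):
        trace, ev = synthetic.synthesize_kinetics(seed=1)
        pm = kin.com_power(trace.grf, trace.com_velocity, trace.body_mass,
                           trace.rate, events=ev, per="mass")
        pw = kin.com_power(trace.grf, trace.com_velocity, trace.body_mass,
                           trace.rate, events=ev, per="weight")
        assert pw.w_lac == pytest.approx(pm.w_lac / kin.GRAVITY)

    def test_multiple_sign_changes_warns_and_picks_longest(self):
        rate = 1000.0
        grf = np.zeros((3, 400))
        grf[2] = 70.0
        v = np.zeros((3, 400))
        v[2, :20] = 1.0     # brief positive blip
        v[2, 20:200] = -5.0  # main absorption
        v[2, 200:] = 5.0     # propulsion
        with pytest.warns(UserWarning, match="sign changes"):
            res = kin.com_power(grf, v, 70.0, rate)
        assert res.la_span == (20, 200)


class TestComSpeed:
    def test_constant_velocity_recovered(self):
        rate = 256.0
        t = np.arange(512) / rate
        pos = np.vstack([2.67 * t, np.zeros_like(t), np.zeros_like(t)])
        speed = kin.com_speed(pos, rate, ic=400)
        assert speed == pytest.approx(2.67, rel=1e-6)

    def test_stationary_com(self):
        pos = np.zeros((3, 512))
        assert kin.com_speed(pos, 256.0, ic=400) == pytest.approx(0.0, abs=1e-9)

    def test_synthetic_trace_matches_planted_speed(self):
        trace, ev = synthetic.synthesize_kinetics(com_speed=2.67, seed=9)
        speed = kin.com_speed(trace.com_position, trace.rate, ev.ic)
        assert speed == pytest.approx(2.67, rel=0.01)

    def test_window_out_of_range(self):
        pos = np.zeros((3, 100))
        with pytest.raises(ValueError):
            kin.com_speed(pos, 1000.0, ic=50)  # window starts before sample 0


class TestHorizontalForcePeaks:
    def test_triangular_pulse_arithmetic(self):
        grf = np.zeros((3, 400))
        ev = kin.GaitEvents(ic=100, toe_off=380, left_ic=0)
        grf[1, 100:240] = np.concatenate(
            [np.linspace(0, 710, 70), np.linspace(710, 0, 70)]
        )
        hf_ap, hf_ml = kin.horizontal_force_peaks(grf, ev, body_mass=71.0)
        assert hf_ap == pytest.approx(10.0)
        assert hf_ml == pytest.approx(0.0)

    def test_second_half_peak_excluded(self):
        grf = np.zeros((3, 400))
        ev = kin.GaitEvents(ic=0, toe_off=400, left_ic=0)
        grf[0, 50] = 100.0   # first half
        grf[0, 300] = 500.0  # second half, must be ignored
        _, hf_ml = kin.horizontal_force_peaks(grf, ev, body_mass=100.0)
        assert hf_ml == pytest.approx(1.0)

    def test_synthetic_defaults_reproduced(self):
        trace, ev = synthetic.synthesize_kinetics(seed=0)
        hf_ap, hf_ml = kin.horizontal_force_peaks(trace.grf, ev, trace.body_mass)
        assert hf_ap == pytest.approx(10.0, rel=0.01)
        assert hf_ml == pytest.approx(3.5, rel=0.01)


class TestSeriesPeaks:
    def _phases(self):
        trace, ev = synthetic.synthesize_kinetics(seed=1)
        power = kin.com_power(trace.grf, trace.com_velocity, trace.body_mass,
                              trace.rate, events=ev)
        return trace, ev, power

    def test_monotone_ramp_peaks_at_end_of_propulsion(self):
        trace, ev, power = self._phases()
        series = np.linspace(0, 1, power.com_power.size)
        peaks = kin.series_peaks(series, power, ev, mode="max")
        _, timing = peaks["prp"]
        assert timing > 95.0
        assert peaks["la"][0] < peaks["prp"][0]

    def test_planted_bumps_located_within_one_sample(self):
        trace, ev, power = self._phases()
        series = np.zeros(power.com_power.size)
        la_idx = (power.la_span[0] + power.la_span[1]) // 2
        prp_idx = (power.prp_span[0] + power.prp_span[1]) // 2
        series[la_idx] = 2.0
        series[prp_idx] = 3.0
        peaks = kin.series_peaks(series, power, ev, mode="max")
        stance = ev.toe_off - ev.ic
        assert peaks["la"] == (2.0, pytest.approx(100 * (la_idx - ev.ic) / (stance - 1)))
        assert peaks["prp"] == (3.0, pytest.approx(100 * (prp_idx - ev.ic) / (stance - 1)))


class TestResampling:
    def test_power_commutes_with_resampling_for_bandlimited_input(self):
        rate_lo, rate_hi = 256.0, 1024.0
        t = np.arange(257) / rate_lo
        v = np.vstack([np.sin(2 * np.pi * 3 * t),
                       np.cos(2 * np.pi * 2 * t),
                       np.sin(2 * np.pi * 5 * t)])
        f = np.vstack([np.cos(2 * np.pi * 4 * t) + 2,
                       np.sin(2 * np.pi * 3 * t) + 2,
                       np.cos(2 * np.pi * 2 * t) + 2])
        p_lo = np.einsum("ij,ij->j", f, v)
        p_lo_up = kin.resample_to_rate(p_lo, rate_lo, rate_hi)
        f_up = kin.resample_to_rate(f, rate_lo, rate_hi)
        v_up = kin.resample_to_rate(v, rate_lo, rate_hi)
        p_hi = np.einsum("ij,ij->j", f_up, v_up)
        denom = np.max(np.abs(p_hi))
        assert np.max(np.abs(p_hi - p_lo_up)) / denom < 0.01
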