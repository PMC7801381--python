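"""Synthetic session generator: determinism, schedules, planted structure."""
import numpy as np
import pytest
from scipy.signal import welch

from gecog import synth
from gecog.calibration import calibrate_signal, fit_transfer_curve, gate_noise
from gecog.intervals import IntervalSet


def small_states(seed=0):
    return synth.generate_states(
        duration=7200.0, seed=seed, n_cycles=6, n_rem=4, n_hvs_imm=30,
        n_hvs_rem=8, n_rears=10,
    )


def test_seed_determinism_bit_identical():
    a, b = small_states(3), small_states(3)
    assert a.to_json() == b.to_json()
    la = synth.generate_lfp(a, fs=125.0, n_channels=2)
    lb = synth.generate_lfp(b, fs=125.0, n_channels=2)
    np.testing.assert_array_equal(la, lb)
    ma = synth.generate_motion(a, fs=60.0)
    mb = synth.generate_motion(b, fs=60.0)
    np.testing.assert_array_equal(ma.xyz, mb.xyz)
    # different seed differs
    assert not np.array_equal(la, synth.generate_lfp(small_states(4), fs=125.0, n_channels=2))


def test_schedule_counts_and_transitions():
    t = small_states()
    assert len(t.states["REM"]) == 4
    assert sum(1 for h in t.hvs if h.state == "IMM") == 30
    assert sum(1 for h in t.hvs if h.state == "REM") == 8
    assert len(t.rears) == 10
    # REM reachable only from SWS: every REM onset is an SWS offset
    sws_ends = set(np.round(t.states["SWS"].ends, 6))
    assert all(round(s, 6) in sws_ends for s in t.states["REM"].starts)
    # blocks tile the day exactly; motor states partition it
    total = sum(t.states[k].total() for k in ("SWS", "REM", "AwT", "AwNT"))
    assert total == pytest.approx(t.duration, abs=1e-6)
    assert t.motor["active"].total() + t.motor["inactive"].total() == pytest.approx(t.duration)
    # every planted event sits inside its host state
    for h in t.hvs:
        host = t.states["IMM"] if h.state == "IMM" else t.states["REM"]
        assert host.contains(h.onset) and host.contains(h.offset)
    for r in t.rears:
        assert t.motor["active"].contains(r.onset)
    # REM episodes all exceed the 40-s inclusion rule
    assert np.all(t.states["REM"].durations > 40.0)


def test_dwell_time_medians(rng):
    t = synth.generate_states(duration=450_000.0, seed=7, n_cycles=300, n_rem=150,
                              n_hvs_imm=100, n_hvs_rem=150, n_rears=50)
    sws = t.states["SWS"].durations
    assert abs(np.median(sws) - 240.0) < 0.10 * 240.0
    rem = t.states["REM"].durations
    assert abs(np.median(rem) - 110.0) < 0.10 * 110.0
    hvs = np.array([h.duration for h in t.hvs])
    assert abs(np.median(hvs) - 5.0) < 0.10 * 5.0


def test_capacity_errors():
    with pytest.raises(ValueError):
        synth.generate_states(duration=900.0, seed=0, n_cycles=2, n_rem=2,
                              n_hvs_imm=500, n_hvs_rem=2, n_rears=2)
    with pytest.raises(ValueError):
        synth.generate_states(duration=600.0, seed=0, n_cycles=4, n_rem=8)


def band_var(x, fs, lo, hi):
    f, p = welch(x, fs=fs, nperseg=int(8 * fs))
    sel = (f >= lo) & (f < hi)
    return np.trapezoid(p[sel], f[sel])


def test_lfp_state_spectral_contrasts(short_run):
    truth, lfp, _, _ = short_run
    fs = 250.0
    x = lfp[0]
    t_ax = np.arange(x.size) / fs
    rem_m = truth.states["REM"].to_mask(t_ax)
    sws_m = truth.states["SWS"].to_mask(t_ax)
    rem_seg = x[rem_m][: int(100 * fs)]
    sws_seg = x[sws_m][: int(100 * fs)]
    # REM: theta dominates delta by design
    assert band_var(rem_seg, fs, 5.0, 9.5) / band_var(rem_seg, fs, 2.0, 4.0) > 5.0
    # SWS: delta dominates theta-free spectrum
    assert band_var(sws_seg, fs, 1.0, 4.0) > 5.0 * band_var(rem_seg, fs, 1.0, 4.0)


def test_planted_hvs_exceed_z_threshold(short_run):
    truth, lfp, _, result = short_run
    from gecog.spectral import band_power

    series = band_power(result.hvs_spec, (20.0, 50.0), agg="mean")
    z = (series.values - series.values.mean()) / series.values.std()
    for h in truth.hvs:
        sel = (series.times >= h.onset + 1.0) & (series.times <= h.offset - 1.0)
        assert z[sel].max() > 0.7


def test_planted_coupling_measurable_by_regression(rng):
    """Short-time theta power regressed on the planted ISA phase recovers
    the configured depth and preferred phase within 10%."""
    rem = IntervalSet(np.array([[0.0, 1800.0]]), "REM")
    empty = IntervalSet()
    truth = synth.GroundTruth(
        duration=1800.0, seed=11,
        states={"SWS": empty, "REM": rem, "AwT": empty, "AwNT": empty,
                "AwNT_active": empty, "IMM": empty},
        motor={"active": empty, "inactive": rem},
        hvs=[], rears=[],
        couplings=[synth.Coupling("isa", "theta", 0.8, 340.0, ("REM",))],
    )
    params = synth.LfpParams(pink_rms=5e-6, white_rms=1e-6)
    fs = 100.0
    x = synth.generate_lfp(truth, fs=fs, n_channels=1, params=params)[0]
    from gecog.coupling import analytic_band

    isa = analytic_band(x, fs, params.isa_freq, 0.04)
    theta = analytic_band(x, fs, params.theta_freq, 1.0)
    ok = isa.valid & theta.valid
    phi = np.radians(isa.phase[ok])
    P = theta.power[ok]
    X = np.c_[np.ones(phi.size), np.cos(phi), np.sin(phi)]
    beta, *_ = np.linalg.lstsq(X, P, rcond=None)
    depth = np.hypot(beta[1], beta[2]) / beta[0]
    phase = np.degrees(np.arctan2(beta[2], beta[1])) % 360.0
    assert abs(depth - 0.8) < 0.08
    assert abs((phase - 340.0 + 180) % 360 - 180) < 10.0


def test_sensor_forward_round_trip_and_noise(rng):
    fs = 500.0
    n = int(400 * fs)
    model = synth.SensorModel(include_drift=False)
    # 1/f-only noise: gate-referred rms equal in two equal-log-width bands
    sess = synth.sensor_forward(np.zeros((1, n)), fs, model=model, seed=2)
    sw = sess.sweeps[0]
    curve = fit_transfer_curve(sw.vgs, sw.ids, sess.bias[0])
    ns = gate_noise(sess.ids_traces[0], fs, curve, sess.bias[1])
    r = ns.vgs_rms((0.05, 0.5)) / ns.vgs_rms((20.0, 200.0))
    assert abs(r - 1.0) < 0.12  # white floor + quantisation add a little
    # AC path: infra-slow content attenuated >= 20 dB vs the DC path
    t = np.arange(n) / fs
    slow = 200e-6 * np.sin(2 * np.pi * 0.01 * t)
    quiet = synth.SensorModel(include_drift=False, pink_ids_rms=0.0, white_ids_rms=0.0,
                              lsb_dc=1e-15, lsb_ac=1e-15)
    s2 = synth.sensor_forward(np.vstack([slow, slow]), fs, model=quiet, seed=3,
                              dc_channels=np.array([True, False]))
    att = s2.ids_traces[1].std() / s2.ids_traces[0].std()
    assert 20 * np.log10(att) < -20.0


def test_cnp_drift_track_through_sweeps():
    model = synth.SensorModel()
    v0 = model.v_cnp(0.0)
    assert model.v_cnp(86400.0) - v0 == pytest.approx(0.05, abs=1e-3)
    # initial rate ~ drift_total / tau = 20 mV/h
    rate = (model.v_cnp(3600.0) - v0) / 1e-3  # mV after the first hour
    assert 10.0 < rate < 20.0


def test_motion_all_sleep_is_inactive():
    from gecog.behavior import head_speed, segment_motor_state

    span = IntervalSet(np.array([[0.0, 600.0]]))
    empty = IntervalSet()
    truth = synth.GroundTruth(
        duration=600.0, seed=5,
        states={"SWS": span, "REM": empty, "AwT": empty, "AwNT": empty,
                "AwNT_active": empty, "IMM": empty},
        motor={"active": empty, "inactive": span}, hvs=[], rears=[],
    )
    track = synth.generate_motion(truth, fs=60.0)
    st = segment_motor_state(track, head_speed(track))
    assert st["active"].total() == 0.0
    assert track.z.max() < 200.0


def test_generate_session_container(tmp_path):
    from gecog.session import read_session, write_session

    sess, truth = synth.generate_session(duration=1800.0, seed=2, n_channels=8, n_dc=2)
    assert sess.n_channels == 8
    assert int(sess.dc_channel_mask.sum()) == 2
    assert sess.motion is not None
    path = tmp_path / "s.h5"
    write_session(sess, path)
    r = read_session(path)
    np.testing.assert_array_equal(r.ids_traces, sess.ids_traces)
    back = synth.GroundTruth.from_json(r.truth_json)
    assert back.to_json() == truth.to_json()
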