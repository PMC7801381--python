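"""Event-triggered averages, permutation/rank tests, HVS and rear analyses."""
import numpy as np
import pytest

from gecog.brain_states import HvsEvent
from gecog.behavior import RearEvent
from gecog.events import (
    hvs_characterize,
    isa_state_contrast,
    prepost_permutation,
    rear_gamma,
    triggered_average,
)
from gecog.intervals import IntervalSet
from gecog.session import ArrayGeometry
from gecog.spectral import Spectrogram


def test_triggered_average_constant_step_and_edges(rng):
    dt = 0.5
    times = np.arange(2000) * dt
    const = np.full(2000, 3.0)
    events = np.array([100.0, 400.0, 700.0])
    ens = triggered_average(times, const, events, window=(-10, 10))
    assert np.allclose(ens.mean(), 3.0) and np.allclose(ens.trials.var(axis=0), 0.0)
    # planted step at each event
    sig = np.zeros(2000)
    for ev in events:
        sig[times >= ev] += 0.0  # keep zero before adding per-event steps
    step = np.zeros(2000)
    for ev in events:
        step[int(ev / dt):] = step[int(ev / dt):]  # no cumulative effect
    step = np.where((times[None, :] >= events[:, None]).any(axis=0), 0.0, 0.0)
    x = np.zeros(2000)
    for ev in events:
        lo = int(ev / dt)
        x[lo : lo + 20] += 5.0
    ens2 = triggered_average(times, x, events, window=(-10, 10))
    m = ens2.mean()
    assert np.allclose(m[ens2.rel_times < 0], 0.0)
    assert m[np.argmin(np.abs(ens2.rel_times - 2.0))] == pytest.approx(5.0)
    # event at the recording edge is dropped and counted
    ens3 = triggered_average(times, const, np.array([2.0, 400.0]), window=(-10, 10))
    assert ens3.n == 1 and ens3.n_dropped == 1
    with pytest.raises(ValueError):
        triggered_average(times, const, np.array([2.0]), window=(-10, 10))
    # linearity
    a = rng.standard_normal(2000)
    b = rng.standard_normal(2000)
    ea = triggered_average(times, a, events).mean()
    eb = triggered_average(times, b, events).mean()
    eab = triggered_average(times, a + b, events).mean()
    np.testing.assert_allclose(eab, ea + eb, atol=1e-12)


def make_ensemble(rng, n_trials=20, n_bins=3, effect_bin=None, factor=10.0):
    dt = 0.5
    rel = np.arange(-60, 61) * dt
    trials = rng.random((n_trials, rel.size, n_bins)) + 1.0
    if effect_bin is not None:
        trials[:, rel >= 0, effect_bin] *= factor
    from gecog.events import TriggeredEnsemble

    return TriggeredEnsemble(rel_times=rel, trials=trials,
                             event_times=np.arange(n_trials, dtype=float),
                             window=(-30.0, 30.0))


def test_prepost_permutation_detects_separable_effect(rng):
    ens = make_ensemble(rng, effect_bin=1)
    stat, p = prepost_permutation(ens, n_perm=1000, rng=rng)
    assert p[1] == pytest.approx(1 / 1001)
    assert p[0] > 0.05 and p[2] > 0.05
    assert stat[1] > 0


def test_prepost_permutation_two_sided_symmetry(rng):
    ens = make_ensemble(rng, effect_bin=0, factor=0.1)
    r1 = np.random.default_rng(11)
    stat, p = prepost_permutation(ens, n_perm=500, rng=r1)
    r2 = np.random.default_rng(11)
    stat2, p2 = prepost_permutation(ens, pre=(0.0, 30.0), post=(-30.0, 0.0),
                                    n_perm=500, rng=r2)
    np.testing.assert_allclose(stat, -stat2)
    np.testing.assert_allclose(p, p2)
    with pytest.raises(ValueError):
        prepost_permutation(make_ensemble(rng, n_trials=3), rng=rng)


def alternating_states(n_epochs=6, dur=200.0):
    sws, rem = [], []
    t = 0.0
    for k in range(2 * n_epochs):
        (sws if k % 2 == 0 else rem).append((t, t + dur))
        t += dur
    return {
        "SWS": IntervalSet(np.array(sws)),
        "REM": IntervalSet(np.array(rem)),
    }, t


def test_isa_state_contrast_direction(rng):
    states, total = alternating_states()
    fs = 10.0
    t = np.arange(int(total * fs)) / fs
    amp = np.where(states["REM"].to_mask(t), 3.0, 1.0)
    x = amp * np.cos(2 * np.pi * 0.05 * t) + 0.1 * rng.standard_normal(t.size)
    df = isa_state_contrast(x, fs, states)
    row = df.iloc[0]
    assert row.rem_gt_sws and row.p < 0.05
    # identical distributions: no strong claim
    y = np.cos(2 * np.pi * 0.05 * t) + 0.1 * rng.standard_normal(t.size)
    df2 = isa_state_contrast(y, fs, states)
    assert df2.iloc[0].p > 0.001
    # single-epoch state is rejected
    with pytest.raises(ValueError):
        isa_state_contrast(x, fs, {"SWS": states["SWS"],
                                   "REM": IntervalSet(np.array([[0.0, 10.0]]))})


def fake_spec(dur=4000.0, fmax=55.0, step=0.5):
    freqs = np.arange(1.0, fmax, 0.25)
    times = (np.arange(int(dur / step)) + 0.5) * step
    return Spectrogram(times=times, freqs=freqs, power=np.ones((times.size, freqs.size)),
                       window=4.0, step=step, fs=250.0, nw=3.0, k=5)


def make_hvs(onset, dur, freq, state):
    return HvsEvent(onset=onset, offset=onset + dur, core_onset=onset - 1.0,
                    core_offset=onset + dur + 1.0, peak_power=10.0, peak_freq=freq,
                    peak_time=onset + dur / 2, peak_z=5.0, state=state)


def test_hvs_characterize_contrasts_and_dc_transients():
    spec = fake_spec(dur=6300.0)
    events = []
    for k in range(10):
        events.append(make_hvs(150.0 + 300 * k, 5.0, 8.5, "IMM"))
    for k in range(10):
        events.append(make_hvs(150.0 + 300 * (k + 10), 5.0, 7.5, "REM"))
    # plant spectral bumps at each event's fundamental
    for ev in events:
        fi = np.argmin(np.abs(spec.freqs - ev.peak_freq))
        sel = (spec.times >= ev.onset) & (spec.times < ev.offset)
        spec.power[sel, fi] += 9.0
    fs_dc = 10.0
    t = np.arange(int(6300 * fs_dc)) / fs_dc
    dc = np.zeros((2, t.size))
    for ev in events:
        sel = (t >= ev.onset) & (t < ev.offset)
        bump = np.sin(np.pi * (t[sel] - ev.onset) / (ev.offset - ev.onset)) ** 2
        dc[0, sel] += 200e-6 * bump  # posterior: positive source
        dc[1, sel] -= 200e-6 * bump  # frontal: negative sink
    geom = ArrayGeometry(1, 2, np.array([[0, 0], [0, 1]]), ap_axis="cols")
    summary = hvs_characterize(events, spec, dc_traces=dc, fs_dc=fs_dc, geometry=geom)
    assert summary.contrasts["peak_freq"]["p"] < 0.01
    assert summary.contrasts["peak_freq"]["rem_median"] < summary.contrasts["peak_freq"]["imm_median"]
    assert summary.table.rel_power.median() > 5.0
    ch0 = summary.dc_transients[summary.dc_transients.channel == 0]
    ch1 = summary.dc_transients[summary.dc_transients.channel == 1]
    assert ch0.peak.median() == pytest.approx(200e-6, rel=0.15)
    assert ch1.trough.median() == pytest.approx(-200e-6, rel=0.15)
    assert summary.hourly_duration.sum() == pytest.approx(sum(e.duration for e in events))


def test_hvs_characterize_flat_dc_is_silent():
    spec = fake_spec(dur=1000.0)
    events = [make_hvs(150.0, 5.0, 8.5, "IMM"), make_hvs(400.0, 5.0, 8.5, "IMM")]
    dc = np.zeros((1, 10_000))
    summary = hvs_characterize(events, spec, dc_traces=dc, fs_dc=10.0)
    assert np.abs(summary.dc_transients[["peak", "trough"]].to_numpy()).max() < 1e-12


def test_rear_gamma_suppression_ratios():
    spec = fake_spec(dur=3000.0, fmax=210.0)
    rears = [RearEvent(onset=200.0 + 120 * k, offset=200.0 + 120 * k + 9.0 + 0.5 * k,
                       peak_height=250.0) for k in range(12)]
    high = (spec.freqs >= 90) & (spec.freqs <= 200)
    for r in rears:
        sel = (spec.times >= r.onset) & (spec.times < r.offset)
        spec.power[np.ix_(sel, high)] *= 0.5
    res = rear_gamma(spec, rears, window=(-8.0, 8.0))
    assert res.ratios["high_gamma"] == pytest.approx(0.5, abs=0.05)
    assert res.ratios["gamma"] == pytest.approx(1.0, abs=0.05)
    assert np.all(np.diff(res.sort_durations) >= 0)
    # suppression extent tracks rear duration in the sorted per-trial image
    post = res.trial_matrix[:, res.ensembles["high_gamma"].rel_times >= 0]
    suppressed = (post < 0.75).sum(axis=1)
    assert suppressed[-1] >= suppressed[0]
    # no planted effect: both ratios are unity
    res2 = rear_gamma(fake_spec(dur=3000.0, fmax=210.0), rears, window=(-8.0, 8.0))
    assert res2.ratios["high_gamma"] == pytest.approx(1.0, abs=0.01)
    assert res2.ratios["gamma"] == pytest.approx(1.0, abs=0.01)
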