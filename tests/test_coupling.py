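"""Phase-amplitude coupling statistic, surrogates, FDR and histograms."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gecog.coupling import (
    analytic_band,
    comodulogram,
    fdr_mask,
    modulation_strength,
    phase_amplitude_histogram,
    surrogate_test,
    topo_map,
)
from gecog.session import ArrayGeometry
from gecog.synth import _band_noise


def test_analytic_band_cosine_phase_and_power():
    fs, f0 = 100.0, 2.0
    t = np.arange(int(60 * fs)) / fs
    b = analytic_band(np.cos(2 * np.pi * f0 * t), fs, f0, 0.5)
    want = (360.0 * f0 * t) % 360.0
    d = np.abs(((b.phase - want) + 180) % 360 - 180)[b.valid]
    assert np.percentile(d, 95) < 5.0  # 0 deg at the peaks, advancing with t
    p = b.power[b.valid]
    assert p.std() / p.mean() < 0.02


def test_analytic_band_amplitude_modulation():
    fs = 100.0
    t = np.arange(int(120 * fs)) / fs
    a = 1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
    b = analytic_band(a * np.cos(2 * np.pi * 10 * t), fs, 10.0, 2.0)
    sel = b.valid.copy()
    sel[: int(5 * fs)] = sel[-int(5 * fs):] = False
    ratio = b.power[sel] / a[sel] ** 2
    assert np.percentile(np.abs(ratio / np.median(ratio) - 1), 95) < 0.02


def test_analytic_band_white_noise_phase_uniform(rng):
    """Mean resultant of decorrelated phase samples stays at the Rayleigh
    null level across seeds."""
    fs, f0, bw = 50.0, 5.0, 1.0
    n = int(400 * fs)
    step = int(2 * fs)  # sample phases every 2 s (> 1/bw) to decorrelate
    fails = 0
    for seed in range(50):
        g = np.random.default_rng(seed)
        b = analytic_band(g.standard_normal(n), fs, f0, bw)
        ph = np.radians(b.phase[b.valid][::step])
        r = np.abs(np.mean(np.exp(1j * ph)))
        p = np.exp(-ph.size * r**2)  # Rayleigh approximation
        fails += p <= 0.01
    assert fails <= 4


def test_analytic_band_validation():
    with pytest.raises(ValueError):
        analytic_band(np.zeros(1000), 100.0, 60.0, 2.0)  # above Nyquist
    with pytest.warns(UserWarning):
        analytic_band(np.zeros(200), 100.0, 2.0, 0.5)  # < 10 cycles


def test_modulation_closed_form():
    """P = 1 + cos(phi - phi0) gives M = 0.5 exp(i phi0) in the limit."""
    phi0 = 123.0
    ph = np.linspace(0.0, 360.0 * 200, 200 * 500, endpoint=False) % 360.0
    P = 1 + np.cos(np.radians(ph - phi0))
    M = modulation_strength(ph, P)
    assert abs(abs(M) - 0.5) < 0.005
    assert abs((np.degrees(np.angle(M)) - phi0 + 180) % 360 - 180) < 2.0


def test_modulation_uniform_phase_constant_power():
    ph = np.linspace(0.0, 360.0 * 100, 100 * 360, endpoint=False) % 360.0
    assert abs(modulation_strength(ph, np.ones_like(ph))) < 0.02


def test_modulation_equals_brute_force(rng):
    ph = rng.uniform(0, 360, 5000)
    P = rng.random(5000)
    M = modulation_strength(ph, P)
    brute = sum(p * np.exp(1j * np.radians(a)) for a, p in zip(ph, P)) / P.sum()
    assert abs(M - brute) < 1e-12
    with pytest.raises(ValueError):
        modulation_strength(ph, np.zeros(5000))


@given(scale=st.floats(0.1, 100.0), rot=st.floats(0.0, 360.0))
@settings(max_examples=30, deadline=None)
def test_modulation_invariances(scale, rot):
    rng = np.random.default_rng(7)
    ph = rng.uniform(0, 360, 2000)
    P = rng.random(2000) + 0.1
    M = modulation_strength(ph, P)
    assert modulation_strength(ph, scale * P) == pytest.approx(M, abs=1e-12)
    Mr = modulation_strength((ph + rot) % 360, P)
    assert abs(Mr) == pytest.approx(abs(M), abs=1e-9)
    want = (np.degrees(np.angle(M)) + rot) % 360
    got = np.degrees(np.angle(Mr)) % 360
    assert abs((got - want + 180) % 360 - 180) < 1e-6


def test_surrogate_perfect_modulation_beats_all(rng):
    fs = 10.0
    slow = _band_noise(int(600 * fs), fs, 0.05, 0.15, rng)
    b = analytic_band(slow, fs, 0.1, 0.05)
    P = 1 + np.cos(np.radians(b.phase))  # depth-1, perfectly aligned
    p, M = surrogate_test(b.phase, P, fs, n_surr=200, rng=rng)
    assert p == pytest.approx(1 / 201)
    assert p > 0  # the +1 correction forbids p = 0
    with pytest.raises(ValueError):
        surrogate_test(b.phase[: int(50 * fs)], P[: int(50 * fs)], fs, rng=rng)


def test_fdr_trivial_and_bh_arithmetic():
    assert not fdr_mask(np.ones((10, 10))).any()
    # a single p = 1/1001 among 100 cells misses q=0.001 (needs p <= 1e-5)
    p = np.ones(100)
    p[0] = 1 / 1001
    assert not fdr_mask(p, rate=0.001).any()
    assert fdr_mask(p, rate=0.2)[0]
    with pytest.raises(ValueError):
        fdr_mask(np.array([0.0, 0.5]))


def test_comodulogram_recovers_planted_isa_theta_cell(rng):
    """Narrowband ISA around 0.08 Hz modulating 8.5 Hz power
    (depth 0.8, preferred phase 340 deg)."""
    fs, dur = 25.0, 2400.0
    t = np.arange(int(dur * fs)) / fs
    x = _band_noise(t.size, fs, 0.06, 0.10, rng)  # aperiodic, like real ISA
    slow = analytic_band(x, fs, 0.08, 0.04)
    amp = np.sqrt(1 + 0.8 * np.cos(np.radians(slow.phase - 340.0)))
    y = amp * np.cos(2 * np.pi * 8.5 * t) + 0.05 * rng.standard_normal(t.size)
    # with 199 surrogates min p = 1/200, so the FDR rate must exceed
    # (cells / n_surr); the production default pairs 1000 surrogates with 0.001
    res = comodulogram(
        x, y, fs, slow_freqs=[0.06, 0.08, 0.10], fast_freqs=[6.5, 8.5, 10.5],
        n_surr=199, rate=0.05, rng=rng,
    )
    assert res.sig[1, 1]
    assert abs((res.preferred_phase[1, 1] - 340 + 180) % 360 - 180) < 10.0
    assert np.unravel_index(np.argmax(res.strength), res.strength.shape) == (1, 1)
    # off-band slow rows stay weak
    assert res.strength[[0, 2], [0, 2]].max() < 0.1


def test_comodulogram_null_is_silent(rng):
    fs, dur = 25.0, 1200.0
    hits = 0
    for _ in range(5):
        x = _band_noise(int(dur * fs), fs, 0.05, 0.15, rng)
        y = _band_noise(int(dur * fs), fs, 6.0, 10.0, rng)
        res = comodulogram(x, y, fs, slow_freqs=[0.08], fast_freqs=[8.0],
                           n_surr=199, rate=0.001, rng=rng)
        hits += int(res.sig.sum())
    assert hits == 0


def test_comodulogram_theta_gamma(rng):
    """Theta-band (7 Hz) phase modulating 130 Hz gamma power."""
    fs, dur = 500.0, 240.0
    t = np.arange(int(dur * fs)) / fs
    x = _band_noise(t.size, fs, 6.0, 8.0, rng)  # frequency-wandering theta
    slow = analytic_band(x, fs, 7.0, 2.0)
    amp = np.sqrt(1 + 0.8 * np.cos(np.radians(slow.phase)))
    y = amp * np.cos(2 * np.pi * 130.0 * t) + 0.05 * rng.standard_normal(t.size)
    res = comodulogram(
        x, y, fs, slow_freqs=[7.0], fast_freqs=[100.0, 130.0, 160.0],
        slow_bw=2.0, fast_bw=30.0, n_surr=99, rate=0.05,
        max_shift=60.0, min_shift=1.0, slow_fs=fs, rng=rng,
    )
    assert res.sig[0, 1]
    # the carrier cell dominates (neighbours pick up envelope sidebands only)
    assert np.argmax(res.strength[0]) == 1


def test_phase_amplitude_histogram_phase_locking(rng):
    fs = 1.0
    t = np.arange(int(6000 * fs)) / fs
    s1 = np.cos(2 * np.pi * 0.02 * t)
    for s2, want_deg in ((-s1, 180.0), (s1.copy(), 0.0)):
        h, pe, ae = phase_amplitude_histogram(s1, s2, fs, n_phase_bins=24)
        assert h.sum() == pytest.approx(1.0)
        marg = h.sum(axis=1)
        centers = 0.5 * (pe[:-1] + pe[1:])
        # circular mean and concentration of the phase-difference marginal
        z = np.sum(marg * np.exp(1j * np.radians(centers)))
        assert abs((np.degrees(np.angle(z)) - want_deg + 180) % 360 - 180) < 15.0
        assert abs(z) > 0.95
    # independent narrowband noises: the phase-difference marginal is flat
    a = _band_noise(6000, fs, 0.01, 0.05, rng)
    b = _band_noise(6000, fs, 0.01, 0.05, rng)
    h, pe, _ = phase_amplitude_histogram(a, b, fs, n_phase_bins=12)
    marg = h.sum(axis=1)
    n = h.shape[0]
    chi2 = ((marg - 1 / n) ** 2 / (1 / n)).sum()
    assert chi2 < 3.0  # far from any concentration


def test_topo_map():
    g = ArrayGeometry.grid(8, 8)
    uniform = topo_map(np.ones(64), g)
    assert np.allclose(uniform, 1.0)
    dead = np.zeros(64, dtype=bool)
    dead[13] = True
    m = topo_map(np.ones(64), g, dead_mask=dead)
    assert np.isnan(m).sum() == 1
    grad = topo_map(np.arange(64.0), g)
    assert np.all(np.diff(grad.mean(axis=1)) > 0)  # monotone along AP rows
    with pytest.raises(Exception):
        topo_map(np.ones(10), g)
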