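"""Infra-slow and theta phase-amplitude coupling with surrogate statistics.

The coupling statistic is the power-weighted mean resultant of the slow
oscillation's phase, normalised by the mean power:

    M = < P(t) * exp(i * phi(t)) > / < P(t) >

|M| in [0, 1] measures how strongly the fast-band power P concentrates at a
preferred slow phase arg(M) (degrees, 0 at the slow oscillation's peak).
Significance comes from surrogate pairs in which the power series is
circularly shifted by a random lag (up to 100 s, small lags excluded), and
the per-comodulogram grid of empirical p-values is masked by
Benjamini-Hochberg FDR control at an error rate of 0.001.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, resample_poly, sosfiltfilt
from statsmodels.stats.multitest import multipletests

from .session import ArrayGeometry

__all__ = [
    "AnalyticBand",
    "ModulationResult",
    "analytic_band",
    "modulation_strength",
    "surrogate_test",
    "fdr_mask",
    "comodulogram",
    "topo_map",
    "phase_amplitude_histogram",
]

log = logging.getLogger(__name__)


@dataclass
class AnalyticBand:
    """Instantaneous phase and power of one narrow band.

    Phase is in degrees [0, 360) with 0 at the oscillation peak; power is
    the squared magnitude of the analytic signal by default (``kind='squared'``)
    or the magnitude itself (``kind='abs'``).  ``valid`` masks filter edges.
    """

    f0: float
    bw: float
    fs: float
    phase: np.ndarray
    power: np.ndarray
    valid: np.ndarray
    kind: str = "squared"


def _bandpass_sos(f0: float, bw: float, fs: float):
    lo, hi = f0 - bw / 2, f0 + bw / 2
    if lo <= 0 or hi >= fs / 2:
        raise ValueError(f"band [{lo:.4g}, {hi:.4g}] Hz outside (0, Nyquist)")
    return butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")


def analytic_band(
    x: np.ndarray, fs: float, f0: float, bw: float, power: str = "squared"
) -> AnalyticBand:
    """Zero-phase band-pass (half-power points at f0 +- bw/2) and analytic signal."""
    x = np.asarray(x, dtype=float)
    sos = _bandpass_sos(f0, bw, fs)
    y = sosfiltfilt(sos, x)
    a = hilbert(y)
    phase = np.degrees(np.angle(a)) % 360.0
    p = np.abs(a) ** 2 if power == "squared" else np.abs(a)
    valid = np.ones(x.size, dtype=bool)
    n_cycle = int(round(fs / f0))
    if x.size < 10 * n_cycle:
        warnings.warn(
            f"trace shorter than 10 cycles of {f0} Hz; masking filter edges"
        )
    # the zero-phase narrow-band filter settles over ~1/bw seconds
    n_edge = min(int(round(fs * max(1.0 / f0, 3.0 / bw))), x.size // 4)
    valid[:n_edge] = False
    valid[-n_edge:] = False
    return AnalyticBand(f0=f0, bw=bw, fs=fs, phase=phase, power=p, valid=valid, kind=power)


def modulation_strength(
    phase_deg: np.ndarray, power: np.ndarray, valid: np.ndarray | None = None
) -> complex:
    """Power-weighted resultant of the slow-phase vectors, power-normalised."""
    phase_deg = np.asarray(phase_deg, dtype=float)
    power = np.asarray(power, dtype=float)
    if valid is not None:
        phase_deg = phase_deg[valid]
        power = power[valid]
    total = power.sum()
    if total == 0:
        raise ValueError("mean power is zero; modulation undefined")
    return complex(np.sum(power * np.exp(1j * np.radians(phase_deg))) / total)


def surrogate_test(
    phase_deg: np.ndarray,
    power: np.ndarray,
    fs: float,
    n_surr: int = 1000,
    max_shift: float = 100.0,
    min_shift: float = 5.0,
    rng: np.random.Generator | None = None,
    valid: np.ndarray | None = None,
) -> tuple[float, complex]:
    """Empirical p for |M| against circularly time-shifted surrogates.

    Each surrogate shifts the power series by a lag drawn uniformly from
    +-[min_shift, max_shift] seconds (near-zero lags are excluded so the
    null is not contaminated by the observed alignment); the +1-corrected
    p-value is ``(1 + #{|M_surr| >= |M_obs|}) / (n_surr + 1)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    phase_deg = np.asarray(phase_deg, dtype=float)
    power = np.asarray(power, dtype=float)
    if valid is not None:
        phase_deg = phase_deg[valid]
        power = power[valid]
    n = power.size
    if n <= max_shift * fs:
        raise ValueError("trace must be longer than the maximum surrogate shift")
    m_obs = modulation_strength(phase_deg, power)
    lo, hi = int(round(min_shift * fs)), int(round(max_shift * fs))
    lags = rng.integers(lo, hi + 1, size=n_surr) * rng.choice([-1, 1], size=n_surr)
    total = power.sum()
    count = 0
    for lag in lags:
        m_s = np.sum(np.roll(power, lag) * np.exp(1j * np.radians(phase_deg))) / total
        if abs(m_s) >= abs(m_obs):
            count += 1
    p = (1 + count) / (n_surr + 1)
    return float(p), m_obs


def fdr_mask(p: np.ndarray, rate: float = 0.001) -> np.ndarray:
    """Benjamini-Hochberg step-up over all cells of one comodulogram."""
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(p.ravel(), alpha=rate, method="fdr_bh")
    return reject.reshape(p.shape)


@dataclass
class ModulationResult:
    """Comodulogram: complex M, p-values and FDR mask per (slow f, fast f)."""

    slow_freqs: np.ndarray
    fast_freqs: np.ndarray
    M: np.ndarray  # complex, (n_slow, n_fast)
    p: np.ndarray
    sig: np.ndarray
    rate: float

    @property
    def strength(self) -> np.ndarray:
        return np.abs(self.M)

    @property
    def preferred_phase(self) -> np.ndarray:
        return np.degrees(np.angle(self.M)) % 360.0


def comodulogram(
    slow_trace: np.ndarray,
    fast_trace: np.ndarray,
    fs: float,
    slow_freqs: np.ndarray,
    fast_freqs: np.ndarray,
    slow_bw: float = 0.04,
    fast_bw: float = 0.4,
    n_surr: int = 1000,
    max_shift: float = 100.0,
    min_shift: float = 5.0,
    rate: float = 0.001,
    slow_fs: float = 10.0,
    rng: np.random.Generator | None = None,
) -> ModulationResult:
    """Modulation strength + surrogate test + FDR mask on a frequency grid.

    The slow (phase-providing) trace is decimated to ``slow_fs`` before the
    very narrow infra-slow filters are applied, which keeps them numerically
    stable; the fast-band power is block-averaged onto the same time base.
    """
    rng = np.random.default_rng() if rng is None else rng
    slow_freqs = np.asarray(slow_freqs, dtype=float)
    fast_freqs = np.asarray(fast_freqs, dtype=float)
    q = max(1, int(round(fs / slow_fs)))
    fs_lo = fs / q
    slow_lo = resample_poly(np.asarray(slow_trace, dtype=float), 1, q) if q > 1 else np.asarray(slow_trace, dtype=float)

    M = np.empty((slow_freqs.size, fast_freqs.size), dtype=complex)
    p = np.empty_like(M, dtype=float)
    powers = []
    for ff in fast_freqs:
        fb = analytic_band(fast_trace, fs, ff, fast_bw)
        pw = fb.power
        if q > 1:
            m = (pw.size // q) * q
            pw = pw[:m].reshape(-1, q).mean(axis=1)
        powers.append(pw)
    for i, sf in enumerate(slow_freqs):
        sb = analytic_band(slow_lo, fs_lo, sf, slow_bw)
        for j, pw in enumerate(powers):
            n = min(sb.phase.size, pw.size)
            valid = sb.valid[:n]
            p[i, j], M[i, j] = surrogate_test(
                sb.phase[:n],
                pw[:n],
                fs_lo,
                n_surr=n_surr,
                max_shift=max_shift,
                min_shift=min_shift,
                rng=rng,
                valid=valid,
            )
    return ModulationResult(
        slow_freqs=slow_freqs,
        fast_freqs=fast_freqs,
        M=M,
        p=p,
        sig=fdr_mask(p, rate),
        rate=rate,
    )


def topo_map(
    values: np.ndarray, geometry: ArrayGeometry, dead_mask: np.ndarray | None = None
) -> np.ndarray:
    """Per-channel values onto the physical grid; dead channels become NaN."""
    values = np.asarray(values, dtype=float)
    if dead_mask is not None:
        values = values.copy()
        values[np.asarray(dead_mask, dtype=bool)] = np.nan
    return geometry.to_grid(values)


def phase_amplitude_histogram(
    sig1: np.ndarray,
    sig2: np.ndarray,
    fs: float,
    band: tuple[float, float] = (0.005, 0.05),
    n_phase_bins: int = 24,
    n_amp_bins: int = 24,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint density of sig1 amplitude over the phase difference of two signals.

    Both signals are band-passed, the Hilbert phase difference is wrapped to
    [0, 360) and binned against the envelope amplitude of ``sig1``.  Returns
    (density, phase_edges, amp_edges) with the density normalised to unit
    total mass.  Anti-phase infra-slow fluctuations concentrate all mass at
    180 degrees.
    """
    sig1 = np.asarray(sig1, dtype=float)
    sig2 = np.asarray(sig2, dtype=float)
    if sig1.size != sig2.size:
        raise ValueError("signals must have equal length")
    f0 = 0.5 * (band[0] + band[1])
    bw = band[1] - band[0]
    b1 = analytic_band(sig1, fs, f0, bw, power="abs")
    b2 = analytic_band(sig2, fs, f0, bw, power="abs")
    dphi = (b1.phase - b2.phase) % 360.0
    amp = b1.power  # envelope amplitude of sig1
    ok = b1.valid & b2.valid
    hist, pe, ae = np.histogram2d(
        dphi[ok], amp[ok], bins=[n_phase_bins, n_amp_bins], range=[[0, 360], [0, amp[ok].max() * 1.0001]]
    )
    hist = hist / hist.sum()
    return hist, pe, ae
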