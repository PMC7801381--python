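"""Whitened multitaper time-frequency decomposition and band powers.

All state logic runs on multitaper spectrograms of AR(1)-prewhitened LFP:
4-s windows sliding in 0.5-s steps over 1-200 Hz for the standard preset,
and 60-s windows in 5-s steps for the infra-slow preset.  The multitaper
estimate averages periodograms over K orthogonal DPSS tapers (time-bandwidth
NW), trading spectral resolution (2*NW/window Hz) for variance.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.signal.windows import dpss

__all__ = [
    "SpectralParameterError",
    "Spectrogram",
    "BandPowerSeries",
    "whiten",
    "multitaper_spectrogram",
    "band_power",
    "ISA_PRESET",
    "LFP_PRESET",
]

log = logging.getLogger(__name__)

#: standard LFP preset: 4-s windows, 0.5-s steps, 1-200 Hz
LFP_PRESET = dict(window=4.0, step=0.5, fmin=1.0, fmax=200.0, nw=3.0, k=5)
#: infra-slow preset for DC channels: 60-s windows, 5-s steps, 0.015-4 Hz
ISA_PRESET = dict(window=60.0, step=5.0, fmin=0.015, fmax=4.0, nw=3.0, k=5)


class SpectralParameterError(Exception):
    pass


def whiten(x: np.ndarray, return_coef: bool = False, max_coef: float = 0.999):
    """First-order AR prewhitening: y[t] = x[t] - a*x[t-1].

    ``a`` is the lag-1 autocorrelation of ``x`` (clipped to ``max_coef`` so
    a pure trend degenerates gracefully).  Constant input has no defined
    lag-1 autocorrelation; it is returned zero-mean with a warning.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("whiten requires finite samples")
    xc = x - x.mean()
    denom = np.dot(xc, xc)
    if denom == 0:
        warnings.warn("constant input: whitening coefficient undefined, returning zero-mean input")
        return (xc, 0.0) if return_coef else xc
    a = float(np.dot(xc[1:], xc[:-1]) / denom)
    a = float(np.clip(a, -max_coef, max_coef))
    y = x.copy()
    y[1:] -= a * x[:-1]
    y[0] = y[1] if y.size > 1 else 0.0  # no predecessor for the first sample
    return (y, a) if return_coef else y


@dataclass
class Spectrogram:
    """Time x frequency power array with its estimation metadata.

    ``times`` are window centres (s); ``power`` is a one-sided density
    (units^2/Hz) averaged over tapers, so summing over frequency times the
    bin width approximates the windowed signal variance.
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # (n_times, n_freqs)
    window: float
    step: float
    fs: float
    nw: float
    k: int
    whitened: bool = False
    whiten_coef: float | None = None

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])

    def crop_freqs(self, fmin: float, fmax: float) -> "Spectrogram":
        sel = (self.freqs >= fmin) & (self.freqs <= fmax)
        return replace(self, freqs=self.freqs[sel], power=self.power[:, sel])


def multitaper_spectrogram(
    x: np.ndarray,
    fs: float,
    window: float = 4.0,
    step: float = 0.5,
    fmin: float = 1.0,
    fmax: float = 200.0,
    nw: float = 3.0,
    k: int = 5,
    whiten_first: bool = False,
    chunk: int = 8192,
) -> Spectrogram:
    """Sliding-window DPSS multitaper spectrogram.

    Windows are detrended (constant) before tapering; window centres sit at
    ``window/2 + j*step``.  Computation is chunked so day-long recordings
    stay within a moderate memory footprint.
    """
    x = np.asarray(x, dtype=float)
    if fmax > fs / 2:
        raise SpectralParameterError(f"fmax {fmax} Hz above Nyquist {fs / 2} Hz")
    nper = int(round(window * fs))
    hop = int(round(step * fs))
    if x.size < nper:
        raise SpectralParameterError("trace shorter than one window")
    coef = None
    if whiten_first:
        x, coef = whiten(x, return_coef=True)
    tapers = dpss(nper, nw, Kmax=k)  # unit-energy tapers
    freqs = np.fft.rfftfreq(nper, 1.0 / fs)
    sel = (freqs >= fmin) & (freqs <= fmax)
    nwin = (x.size - nper) // hop + 1
    power = np.empty((nwin, int(sel.sum())), dtype=np.float64)
    scale = np.full(freqs.size, 2.0 / (fs * k))
    scale[0] = 1.0 / (fs * k)
    if nper % 2 == 0:
        scale[-1] = 1.0 / (fs * k)
    scale = scale[sel]
    offsets = np.arange(nper)
    for j0 in range(0, nwin, chunk):
        j1 = min(j0 + chunk, nwin)
        idx = np.arange(j0, j1)[:, None] * hop + offsets
        seg = x[idx]
        seg -= seg.mean(axis=1, keepdims=True)
        acc = np.zeros((j1 - j0, int(sel.sum())))
        for w in tapers:
            X = np.fft.rfft(seg * w, axis=1)[:, sel]
            acc += X.real**2 + X.imag**2
        power[j0:j1] = acc * scale
    times = window / 2 + np.arange(nwin) * step
    return Spectrogram(
        times=times,
        freqs=freqs[sel],
        power=power,
        window=window,
        step=step,
        fs=fs,
        nw=nw,
        k=k,
        whitened=whiten_first,
        whiten_coef=coef,
    )


@dataclass
class BandPowerSeries:
    """Band-aggregated power over time, optionally z-scored.

    ``agg='sum'`` integrates density over the band (power); ``agg='mean'``
    averages density across band bins.  Z-scoring uses the full series as
    reference; the (mu, sigma) used are retained.
    """

    times: np.ndarray
    values: np.ndarray
    band: tuple[float, float]
    step: float
    agg: str = "sum"
    zscored: bool = False
    mu: float | None = None
    sigma: float | None = None

    def zscore(self) -> "BandPowerSeries":
        mu = float(self.values.mean())
        sigma = float(self.values.std())
        if sigma == 0:
            raise ValueError("cannot z-score a constant series")
        return replace(
            self, values=(self.values - mu) / sigma, zscored=True, mu=mu, sigma=sigma
        )

    def same_base(self, other: "BandPowerSeries") -> bool:
        return self.times.size == other.times.size and np.allclose(self.times, other.times)


def band_power(
    spec: Spectrogram,
    band: tuple[float, float],
    zscore: bool = False,
    agg: str = "sum",
) -> BandPowerSeries:
    """Power in ``[lo, hi)`` by bin centre, as a time series.

    ``sum`` returns the integrated band power (sum of density bins times the
    bin width); ``mean`` returns the mean density across the band's bins.
    """
    lo, hi = band
    sel = (spec.freqs >= lo) & (spec.freqs < hi)
    if not sel.any():
        raise SpectralParameterError(f"band [{lo}, {hi}) Hz contains no spectrogram bins")
    if agg == "sum":
        values = spec.power[:, sel].sum(axis=1) * spec.df
    elif agg == "mean":
        values = spec.power[:, sel].mean(axis=1)
    else:
        raise ValueError("agg must be 'sum' or 'mean'")
    series = BandPowerSeries(
        times=spec.times, values=values, band=(lo, hi), step=spec.step, agg=agg
    )
    return series.zscore() if zscore else series
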