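"""Transfer-curve calibration and sensitivity/noise figures of merit.

A graphene solution-gated FET transduces the gate (tissue) potential into a
drain-source current through the slope of its stationary I_ds-V_gs curve.
The curve has a current minimum at the charge neutrality point (CNP) where
the transconductance G_m = dI_ds/dV_gs changes sign.  Calibration inverts
the small-signal relation

    I_ds(t) = I_ds(V_bias) + G_m(V_bias) * V_sig(t)

so dividing the current fluctuation by the *signed* local slope recovers
the gate signal with the correct polarity on both the hole (G_m < 0) and
electron (G_m > 0) branches.

Noise is expressed gate-referred: S_Vgs(f) = S_Ids(f) / G_m^2, and the
figure of merit V_gs-rms over a band is the square root of the integrated
gate-referred PSD.  For 1/f current noise the band rms is equal in any two
bands of equal logarithmic width.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import make_smoothing_spline

__all__ = [
    "CalibrationError",
    "CnpRangeError",
    "ExtrapolationError",
    "GmBelowFloorError",
    "BandError",
    "TransferCurve",
    "NoiseSpectrum",
    "FreqResponse",
    "CnpDriftTrack",
    "fit_transfer_curve",
    "working_channel_mask",
    "calibrate_signal",
    "gate_noise",
    "fit_freq_response",
    "correct_freq_response",
    "track_cnp",
]

log = logging.getLogger(__name__)


class CalibrationError(Exception):
    pass


class CnpRangeError(CalibrationError):
    """The current minimum sits at the sweep boundary; channel unusable."""


class ExtrapolationError(CalibrationError):
    """Requested bias outside the swept gate-voltage range."""


class GmBelowFloorError(CalibrationError):
    """Operating point too close to the CNP; channel should be masked."""


class BandError(CalibrationError):
    """Requested band not resolvable from the trace length / sampling rate."""


@dataclass
class TransferCurve:
    """Smoothed stationary I_ds-V_gs relation of one channel.

    ``Gm_curve`` is dI_ds/dV_gs (siemens) on ``vgs_grid``; ``gm_curve`` is
    Gm normalised by V_ds (S/V), the usual device figure of merit.
    """

    vgs_grid: np.ndarray
    ids_smooth: np.ndarray
    v_ds: float
    v_cnp: float
    Gm_curve: np.ndarray
    timestamp: float = 0.0
    _spline: object | None = field(default=None, repr=False)

    @property
    def gm_curve(self) -> np.ndarray:
        return self.Gm_curve / self.v_ds

    def ids_at(self, vgs: float) -> float:
        self._check_range(vgs)
        if self._spline is not None:
            return float(self._spline(vgs))
        return float(np.interp(vgs, self.vgs_grid, self.ids_smooth))

    def Gm_at(self, vgs: float) -> float:
        self._check_range(vgs)
        if self._spline is not None:
            return float(self._spline.derivative()(vgs))
        return float(np.interp(vgs, self.vgs_grid, self.Gm_curve))

    def gm_at(self, vgs: float) -> float:
        return self.Gm_at(vgs) / self.v_ds

    def _check_range(self, vgs: float) -> None:
        if vgs < self.vgs_grid[0] or vgs > self.vgs_grid[-1]:
            raise ExtrapolationError(
                f"bias {vgs:.3f} V outside swept range "
                f"[{self.vgs_grid[0]:.3f}, {self.vgs_grid[-1]:.3f}] V"
            )


def fit_transfer_curve(
    vgs: np.ndarray,
    ids: np.ndarray,
    v_ds: float,
    timestamp: float = 0.0,
    grid_points: int = 512,
    boundary_margin: float = 0.02,
) -> TransferCurve:
    """Fit a cubic smoothing spline (GCV-selected smoothing) to one sweep.

    The CNP is located on the fitted curve and then refined by a local
    quadratic fit of the raw sweep points around the minimum (the curve is
    smooth and locally parabolic there, and the vertex estimate is far less
    noise-sensitive than the raw or spline argmin).  The transconductance
    curve is the analytic derivative of the spline.  The minimum must lie
    inside the sweep (not within ``boundary_margin`` of the range at either
    edge), otherwise the channel is unusable.
    """
    vgs = np.asarray(vgs, dtype=float)
    ids = np.asarray(ids, dtype=float)
    if v_ds == 0:
        raise CalibrationError("V_ds must be non-zero")
    if vgs.size < 7:
        raise CalibrationError("need at least 7 sweep points")
    if np.any(np.diff(vgs) <= 0):
        raise CalibrationError("V_gs grid must be strictly increasing")
    spline = make_smoothing_spline(vgs, ids)
    grid = np.linspace(vgs[0], vgs[-1], grid_points)
    fit = spline(grid)
    i_min = int(np.argmin(fit))
    margin = boundary_margin * (vgs[-1] - vgs[0])
    if grid[i_min] - vgs[0] < margin or vgs[-1] - grid[i_min] < margin:
        raise CnpRangeError("current minimum at the sweep boundary; CNP out of range")
    dspl = spline.derivative()
    v_cnp = float(grid[i_min])
    # local quadratic vertex refinement on the raw points around the minimum
    half = 0.25 * (vgs[-1] - vgs[0])
    sel = np.abs(vgs - v_cnp) <= half
    if sel.sum() >= 7:
        a2, a1, _ = np.polyfit(vgs[sel], ids[sel], 2)
        vertex = -a1 / (2 * a2)
        if a2 > 0 and abs(vertex - v_cnp) <= half:
            v_cnp = float(vertex)
    return TransferCurve(
        vgs_grid=grid,
        ids_smooth=fit,
        v_ds=float(v_ds),
        v_cnp=v_cnp,
        Gm_curve=dspl(grid),
        timestamp=timestamp,
        _spline=spline,
    )


def working_channel_mask(gms: np.ndarray, factor: float = 0.7) -> np.ndarray:
    """Working-channel rule: |gm| at the operating point >= factor x array median."""
    gms = np.abs(np.asarray(gms, dtype=float))
    return gms >= factor * np.median(gms)


def calibrate_signal(
    ids_trace: np.ndarray,
    curve: TransferCurve,
    vgs_bias: float,
    gm_floor: float | None = None,
) -> np.ndarray:
    """Convert a drain-source current trace to an equivalent gate voltage.

    V_sig(t) = (I_ds(t) - I_ds(bias)) / G_m(bias), with the signed slope so
    the polarity is correct on both branches.  ``gm_floor`` (S/V) rejects
    operating points too close to the CNP.
    """
    Gm0 = curve.Gm_at(vgs_bias)
    if gm_floor is not None and abs(Gm0 / curve.v_ds) < gm_floor:
        raise GmBelowFloorError(
            f"|gm| = {abs(Gm0 / curve.v_ds):.2e} S/V below floor {gm_floor:.2e}"
        )
    i0 = curve.ids_at(vgs_bias)
    return (np.asarray(ids_trace, dtype=float) - i0) / Gm0


@dataclass
class NoiseSpectrum:
    """Current and gate-referred noise PSDs with band-rms accessors."""

    freqs: np.ndarray
    S_Ids: np.ndarray  # A^2/Hz
    S_Vgs: np.ndarray  # V^2/Hz
    Gm: float

    def _band_rms(self, psd: np.ndarray, band: tuple[float, float]) -> float:
        lo, hi = band
        if lo >= hi:
            raise BandError("band must satisfy lo < hi")
        if lo < self.freqs[1] or hi > self.freqs[-1]:
            raise BandError(
                f"band [{lo}, {hi}] Hz outside resolvable range "
                f"[{self.freqs[1]:.4g}, {self.freqs[-1]:.4g}] Hz"
            )
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        return float(np.sqrt(np.trapezoid(psd[sel], self.freqs[sel])))

    def vgs_rms(self, band: tuple[float, float]) -> float:
        return self._band_rms(self.S_Vgs, band)

    def ids_rms(self, band: tuple[float, float]) -> float:
        return self._band_rms(self.S_Ids, band)


DEFAULT_NOISE_BANDS = ((0.05, 0.5), (1.0, 10.0), (20.0, 200.0))


def gate_noise(
    ids_trace: np.ndarray,
    fs: float,
    curve: TransferCurve,
    vgs_bias: float,
    bands: tuple = DEFAULT_NOISE_BANDS,
) -> NoiseSpectrum:
    """Welch PSD of the current noise, gate-referred through Gm(bias)^2.

    Hann window, 50% overlap, segment length 8x the longest band period
    (capped at the trace length); one-sided density normalisation.
    """
    x = np.asarray(ids_trace, dtype=float)
    T = x.size / fs
    longest = max(1.0 / b[0] for b in bands)
    if T < 10 * longest:
        raise BandError(
            f"trace ({T:.1f} s) shorter than 10x the longest band period ({longest:.1f} s)"
        )
    for lo, hi in bands:
        if hi > fs / 2:
            raise BandError(f"band edge {hi} Hz above Nyquist {fs / 2} Hz")
    nper = min(int(round(8 * longest * fs)), x.size)
    freqs, S_Ids = signal.welch(
        x, fs=fs, window="hann", nperseg=nper, noverlap=nper // 2, detrend="constant"
    )
    Gm0 = curve.Gm_at(vgs_bias)
    return NoiseSpectrum(freqs=freqs, S_Ids=S_Ids, S_Vgs=S_Ids / Gm0**2, Gm=Gm0)


@dataclass
class FreqResponse:
    """Transconductance magnitude vs frequency, normalised to 1 at 1 Hz.

    The graphene-electrolyte interface attenuates the response with a
    fractional power law |g_m|(f) ~ f^(-alpha), alpha ~ 0.1.
    """

    freqs: np.ndarray
    mag: np.ndarray  # normalised to 1 at 1 Hz
    alpha: float
    phase: np.ndarray | None = None


def fit_freq_response(freqs: np.ndarray, gains: np.ndarray) -> FreqResponse:
    """Least-squares fit of log|g_m| vs log f -> attenuation exponent alpha.

    ``gains`` may be complex; only magnitudes enter the exponent fit.  The
    fit is scale-invariant: rescaling all gains leaves alpha unchanged.
    """
    freqs = np.asarray(freqs, dtype=float)
    gains = np.asarray(gains)
    mags = np.abs(gains).astype(float)
    if freqs.size < 4:
        raise CalibrationError("need at least 4 frequencies")
    if freqs.max() / freqs.min() < 100:
        raise CalibrationError("frequencies must span at least 2 decades")
    if np.any(mags <= 0):
        raise CalibrationError("gains must have positive magnitude")
    slope, intercept = np.polyfit(np.log(freqs), np.log(mags), 1)
    alpha = -float(slope)
    mag1 = np.exp(intercept)  # fitted magnitude at 1 Hz used for normalisation
    phase = np.angle(gains) if np.iscomplexobj(gains) else None
    return FreqResponse(freqs=freqs, mag=mags / mag1, alpha=alpha, phase=phase)


def correct_freq_response(
    trace: np.ndarray, fs: float, resp: FreqResponse, use_phase: bool = False
) -> np.ndarray:
    """Undo the fractional power-law attenuation in the frequency domain.

    Divides the spectrum by the fitted |g_m|(f) = f^(-alpha) (unity at
    1 Hz); the DC bin is left untouched.  Phase correction is optional and
    off by default (magnitude-only).
    """
    if resp.alpha >= 0.5:
        raise CalibrationError("alpha >= 0.5 fails the sanity bound")
    x = np.asarray(trace, dtype=float)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1.0 / fs)
    gain = np.ones_like(f)
    gain[1:] = f[1:] ** (-resp.alpha)
    if use_phase and resp.phase is not None:
        ph = np.interp(np.log(np.maximum(f, resp.freqs[0])), np.log(resp.freqs), resp.phase)
        gain = gain * np.exp(1j * ph)
        gain[0] = 1.0
    X[1:] = X[1:] / gain[1:]
    return np.fft.irfft(X, n=x.size)


@dataclass
class CnpDriftTrack:
    """CNP position over time; chronic recordings drift tens of mV per day."""

    timestamps: np.ndarray  # s
    v_cnp: np.ndarray  # V
    rebias_bound: float = 0.05  # V

    @property
    def accumulated_drift(self) -> np.ndarray:
        return self.v_cnp - self.v_cnp[0]

    @property
    def drift_rate(self) -> np.ndarray:
        """Finite-difference rate in V/h, aligned to interval midpoints."""
        return np.diff(self.v_cnp) / (np.diff(self.timestamps) / 3600.0)

    @property
    def rebias_recommended(self) -> bool:
        return bool(np.any(np.abs(self.accumulated_drift) > self.rebias_bound))


def track_cnp(
    sweeps: list[tuple[float, np.ndarray, np.ndarray]],
    v_ds: float,
    rebias_bound: float = 0.05,
) -> CnpDriftTrack:
    """CNP drift track from timestamped sweeps ``(timestamp, vgs, ids)``.

    Sweeps whose transfer-curve fit fails are skipped with a warning.
    """
    if len(sweeps) < 2:
        raise CalibrationError("need at least 2 timestamped sweeps")
    ts, cnps = [], []
    for stamp, vgs, ids in sweeps:
        try:
            curve = fit_transfer_curve(vgs, ids, v_ds, timestamp=stamp)
        except CalibrationError as err:
            warnings.warn(f"sweep at t={stamp:.0f}s skipped: {err}")
            continue
        ts.append(stamp)
        cnps.append(curve.v_cnp)
    if len(ts) < 2:
        raise CalibrationError("fewer than 2 sweeps survived fitting")
    return CnpDriftTrack(
        timestamps=np.asarray(ts), v_cnp=np.asarray(cnps), rebias_bound=rebias_bound
    )
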