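"""Event-triggered analyses: triggered averages, pre/post permutation tests,
state-contrast rank tests, HVS characterisation and rear-triggered gamma.

All tests here are nonparametric.  The REM-onset contrast compares, per
frequency bin, the across-trial medians of spectral power in the 30 s before
vs after the transition, with a paired permutation null (pre/post label
flips within trials).  State contrasts of integrated infra-slow power use
the Wilcoxon rank-sum test.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import butter, resample_poly, sosfiltfilt

from .brain_states import HvsEvent
from .behavior import RearEvent
from .intervals import IntervalSet
from .session import ArrayGeometry
from .spectral import Spectrogram, band_power

__all__ = [
    "TriggeredEnsemble",
    "triggered_average",
    "prepost_permutation",
    "isa_state_contrast",
    "hvs_characterize",
    "HvsSummary",
    "rear_gamma",
    "RearGammaResult",
]

log = logging.getLogger(__name__)


@dataclass
class TriggeredEnsemble:
    """Per-trial windows aligned on event times.

    ``trials`` has shape (n, n_rel) for a series or (n, n_rel, n_freqs) for
    a spectrogram.  Events whose window overlaps the recording edges are
    dropped and counted in ``n_dropped``.
    """

    rel_times: np.ndarray
    trials: np.ndarray
    event_times: np.ndarray
    window: tuple[float, float]
    n_dropped: int = 0
    freqs: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.trials.shape[0]

    def mean(self) -> np.ndarray:
        return self.trials.mean(axis=0)

    def median(self) -> np.ndarray:
        return np.median(self.trials, axis=0)


def triggered_average(
    times: np.ndarray,
    values: np.ndarray,
    events: np.ndarray,
    window: tuple[float, float] = (-30.0, 30.0),
) -> TriggeredEnsemble:
    """Extract aligned windows around each event on a uniform time base.

    ``values`` is (n_times,) for a series or (n_times, n_freqs) for a
    spectrogram.  Linear: the ensemble of a sum is the sum of ensembles.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    events = np.atleast_1d(np.asarray(events, dtype=float))
    dt = times[1] - times[0]
    i_lo = int(np.floor(window[0] / dt))
    i_hi = int(np.ceil(window[1] / dt))
    rel = np.arange(i_lo, i_hi + 1) * dt
    trials, used = [], []
    dropped = 0
    for ev in events:
        i0 = int(round((ev - times[0]) / dt))
        if i0 + i_lo < 0 or i0 + i_hi >= times.size:
            dropped += 1
            continue
        trials.append(values[i0 + i_lo : i0 + i_hi + 1])
        used.append(ev)
    if not trials:
        raise ValueError("no complete trials within the recording")
    return TriggeredEnsemble(
        rel_times=rel,
        trials=np.stack(trials),
        event_times=np.asarray(used),
        window=window,
        n_dropped=dropped,
    )


def prepost_permutation(
    ensemble: TriggeredEnsemble,
    pre: tuple[float, float] = (-30.0, 0.0),
    post: tuple[float, float] = (0.0, 30.0),
    n_perm: int = 1000,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frequency-bin paired permutation test of pre vs post power.

    Per trial the median over the pre and post windows is taken; the
    statistic is the difference of across-trial medians (post - pre).  The
    null swaps pre/post labels independently per trial; the two-sided
    p-value carries the +1 correction.  Returns (stat, p) per bin.
    """
    rng = np.random.default_rng() if rng is None else rng
    if ensemble.n < 5:
        raise ValueError("need at least 5 trials")
    t = ensemble.rel_times
    pre_sel = (t >= pre[0]) & (t < pre[1])
    post_sel = (t >= post[0]) & (t < post[1])
    trials = ensemble.trials
    if trials.ndim == 2:
        trials = trials[:, :, None]
    a = np.median(trials[:, pre_sel, :], axis=1)  # (n_trials, n_bins)
    b = np.median(trials[:, post_sel, :], axis=1)
    stat = np.median(b, axis=0) - np.median(a, axis=0)
    count = np.zeros(stat.shape, dtype=int)
    n = a.shape[0]
    for _ in range(n_perm):
        flip = rng.integers(0, 2, size=n).astype(bool)
        aa = np.where(flip[:, None], b, a)
        bb = np.where(flip[:, None], a, b)
        s = np.median(bb, axis=0) - np.median(aa, axis=0)
        count += np.abs(s) >= np.abs(stat)
    p = (1 + count) / (n_perm + 1)
    return stat.squeeze(), p.squeeze()


def _slow_band_signal(x: np.ndarray, fs: float, band: tuple[float, float], fs_lo: float = 2.0):
    """Decimate then zero-phase band-pass an infra-slow band; returns (y, fs_lo)."""
    q = max(1, int(round(fs / fs_lo)))
    y = resample_poly(np.asarray(x, dtype=float), 1, q) if q > 1 else np.asarray(x, dtype=float)
    fs2 = fs / q
    sos = butter(2, band, btype="bandpass", fs=fs2, output="sos")
    return sosfiltfilt(sos, y), fs2


def isa_state_contrast(
    dc_traces: np.ndarray,
    fs: float,
    states: dict[str, IntervalSet],
    band: tuple[float, float] = (0.01, 0.1),
    min_epochs: int = 5,
) -> pd.DataFrame:
    """Wilcoxon rank-sum contrast of per-epoch integrated ISA power, SWS vs REM.

    Per epoch the integrated band power is the mean square of the band-passed
    DC trace over the epoch.  Channels (or states) with fewer than
    ``min_epochs`` epochs are skipped with a warning.  The direction flag is
    True when REM median power exceeds SWS.
    """
    dc_traces = np.atleast_2d(np.asarray(dc_traces, dtype=float))
    sws, rem = states["SWS"], states["REM"]
    if len(sws) < min_epochs or len(rem) < min_epochs:
        raise ValueError(
            f"need at least {min_epochs} epochs per state "
            f"(got {len(sws)} SWS, {len(rem)} REM)"
        )
    rows = []
    for ch, x in enumerate(dc_traces):
        y, fs2 = _slow_band_signal(x, fs, band)
        t = np.arange(y.size) / fs2

        def epoch_powers(iv: IntervalSet) -> np.ndarray:
            out = []
            for s, e in iv:
                sel = (t >= s) & (t < e)
                if sel.sum() >= 2:
                    out.append(float(np.mean(y[sel] ** 2)))
            return np.asarray(out)

        p_sws = epoch_powers(sws)
        p_rem = epoch_powers(rem)
        if p_sws.size < min_epochs or p_rem.size < min_epochs:
            warnings.warn(f"channel {ch} skipped: too few usable epochs")
            continue
        res = stats.ranksums(p_rem, p_sws)
        rows.append(
            dict(
                channel=ch,
                statistic=float(res.statistic),
                p=float(res.pvalue),
                rem_gt_sws=bool(np.median(p_rem) > np.median(p_sws)),
                n_sws=p_sws.size,
                n_rem=p_rem.size,
            )
        )
    return pd.DataFrame(rows)


@dataclass
class HvsSummary:
    """Per-event HVS table plus state contrasts and topographic aggregates."""

    table: pd.DataFrame
    dc_transients: pd.DataFrame  # one row per (event, channel)
    contrasts: dict
    hourly_duration: np.ndarray
    power_change_map: np.ndarray | None = None


def hvs_characterize(
    events: list[HvsEvent],
    spec: Spectrogram,
    dc_traces: np.ndarray | None = None,
    fs_dc: float | None = None,
    geometry: ArrayGeometry | None = None,
    baseline: tuple[float, float] = (-10.0, -2.0),
    dc_cut: float = 1.0,
) -> HvsSummary:
    """Per-event features and IMM-vs-REM contrasts for detected HVS.

    Peak power is expressed relative to a pre-onset baseline window (the
    spectrogram density at the event's peak frequency over the baseline
    mean).  DC transients are the extremum of the <= ``dc_cut`` Hz low-passed
    DC trace within the event, relative to the baseline mean, per channel.
    """
    if not events:
        raise ValueError("no events to characterise")
    rows = []
    t, f = spec.times, spec.freqs
    for k, ev in enumerate(events):
        fi = int(np.argmin(np.abs(f - ev.peak_freq)))
        b0, b1 = ev.onset + baseline[0], ev.onset + baseline[1]
        sel = (t >= b0) & (t < b1)
        if not sel.any():
            # nearest usable pre-event span
            log.info("event %d lacks a clean baseline window; using nearest span", k)
            sel = (t >= max(t[0], b0)) & (t < max(t[0] + (baseline[1] - baseline[0]), b1))
        base = float(spec.power[sel, fi].mean()) if sel.any() else np.nan
        peak_i = int(np.argmin(np.abs(t - ev.peak_time)))
        rel_power = float(spec.power[peak_i, fi] / base) if base > 0 else np.nan
        rows.append(
            dict(
                event=k,
                onset=ev.onset,
                offset=ev.offset,
                duration=ev.duration,
                state=ev.state,
                peak_freq=ev.peak_freq,
                peak_power=ev.peak_power,
                rel_power=rel_power,
            )
        )
    table = pd.DataFrame(rows)

    dc_rows = []
    if dc_traces is not None:
        dc_traces = np.atleast_2d(np.asarray(dc_traces, dtype=float))
        sos = butter(2, dc_cut, btype="lowpass", fs=fs_dc, output="sos")
        for ch, x in enumerate(dc_traces):
            y = sosfiltfilt(sos, x)
            tt = np.arange(y.size) / fs_dc
            for k, ev in enumerate(events):
                bsel = (tt >= ev.onset + baseline[0]) & (tt < ev.onset + baseline[1])
                esel = (tt >= ev.onset) & (tt < ev.offset)
                if not bsel.any() or not esel.any():
                    continue
                b = float(y[bsel].mean())
                dc_rows.append(
                    dict(
                        event=k,
                        channel=ch,
                        state=ev.state,
                        peak=float(y[esel].max() - b),
                        trough=float(y[esel].min() - b),
                    )
                )
    dc_transients = pd.DataFrame(dc_rows)

    contrasts = {}
    imm = table[table.state == "IMM"]
    rem = table[table.state == "REM"]
    if len(imm) >= 2 and len(rem) >= 2:
        for col in ("rel_power", "peak_freq"):
            res = stats.ranksums(imm[col], rem[col])
            contrasts[col] = dict(
                statistic=float(res.statistic),
                p=float(res.pvalue),
                imm_median=float(imm[col].median()),
                rem_median=float(rem[col].median()),
            )
        if len(dc_transients):
            for col in ("peak", "trough"):
                gi = dc_transients[dc_transients.state == "IMM"][col]
                gr = dc_transients[dc_transients.state == "REM"][col]
                res = stats.ranksums(gi, gr)
                contrasts[f"dc_{col}"] = dict(statistic=float(res.statistic), p=float(res.pvalue))

    n_hours = int(np.ceil(t[-1] / 3600.0))
    hourly = np.zeros(max(n_hours, 1))
    for ev in events:
        hourly[min(int(ev.onset // 3600), hourly.size - 1)] += ev.duration

    power_map = None
    if geometry is not None and len(dc_transients):
        med = (
            dc_transients.groupby("channel")["peak"].median().reindex(range(geometry.n_channels))
        )
        power_map = geometry.to_grid(med.to_numpy())

    return HvsSummary(
        table=table,
        dc_transients=dc_transients,
        contrasts=contrasts,
        hourly_duration=hourly,
        power_change_map=power_map,
    )


@dataclass
class RearGammaResult:
    """Rear-onset-triggered band power and per-band pre/post contrast."""

    ensembles: dict[str, TriggeredEnsemble]
    ratios: dict[str, float]  # median across trials of post/pre mean power
    trial_matrix: np.ndarray  # high band, trials sorted by rear duration
    sort_durations: np.ndarray


def rear_gamma(
    spec: Spectrogram,
    rears: list[RearEvent],
    bands: dict[str, tuple[float, float]] | None = None,
    window: tuple[float, float] = (-10.0, 10.0),
    high_band: str = "high_gamma",
) -> RearGammaResult:
    """Rear-onset-triggered gamma-band power and suppression ratios.

    High-frequency (90-200 Hz) epicortical activity is suppressed during
    rearing while 60-70 Hz gamma is not; the per-band summary is the median
    across trials of post-onset over pre-onset mean power.
    """
    if bands is None:
        hi = min(200.0, float(spec.freqs[-1]))
        bands = {"gamma": (60.0, 70.0), "high_gamma": (90.0, hi)}
    onsets = np.array([r.onset for r in rears])
    durations = np.array([r.duration for r in rears])
    ensembles, ratios = {}, {}
    kept = None
    for name, band in bands.items():
        series = band_power(spec, band, agg="mean")
        ens = triggered_average(series.times, series.values, onsets, window=window)
        ensembles[name] = ens
        t = ens.rel_times
        pre = ens.trials[:, t < 0].mean(axis=1)
        post = ens.trials[:, t >= 0].mean(axis=1)
        ratios[name] = float(np.median(post / pre))
        if name == high_band:
            kept = ens
    if kept is None:
        kept = next(iter(ensembles.values()))
    # match kept trials back to durations (dropped-edge events excluded)
    used = np.isin(onsets, kept.event_times)
    durs = durations[used]
    order = np.argsort(durs)
    return RearGammaResult(
        ensembles=ensembles,
        ratios=ratios,
        trial_matrix=kept.trials[order],
        sort_durations=durs[order],
    )
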