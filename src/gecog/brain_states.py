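"""Brain-state scoring: SW, Theta and HVS detection and their combination.

The scored vocabulary is {SWS, REM, AwT, AwNT}, mutually exclusive and
collectively exhaustive over the scored span, plus high-voltage spindles
(HVS) as an overlay that occurs during, but does not interrupt, the
background state.  Alert immobility (IMM) is the intersection of the
inactive motor state with the awake states.

Detection rules:

* SW: z-score of the summed delta (1-4 Hz) + alpha-beta (10-25 Hz) power
  exceeds -0.1; gaps shorter than 5 s concatenated.
* Theta: theta (5-9.5 Hz) to delta (2-4 Hz) mean-density ratio above a
  threshold; gaps shorter than 10 s concatenated.
* HVS: the non-sinusoidal 7-9 Hz oscillation carries strong harmonics, so
  the mean 20-50 Hz multitaper power is z-scored and thresholded at 0.7;
  candidates shorter than 1 s are skipped.  Per-event onset/offset are then
  refined to the half-of-peak-power crossings, which undoes the outward
  smearing a 4-s analysis window applies to a burst-like event; the raw
  z-crossing extent is kept as the event core.

Combination: HVS extents are excised from the SW/Theta streams before state
assignment (they are overlaid events, not background), SWS = SW in the
inactive motor state at more than 10 s from the last preceding HVS, REM =
inactive Theta longer than 5 s directly preceded (<= 1 s) by SW, remaining
Theta is AwT and everything else AwNT.  Finally the states flanking each
HVS are merged across it when they agree.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .intervals import IntervalSet
from .spectral import BandPowerSeries, Spectrogram, band_power

__all__ = [
    "HvsEvent",
    "StateLabels",
    "detect_sw",
    "detect_hvs",
    "detect_theta",
    "combine_states",
    "PARTITION_STATES",
]

log = logging.getLogger(__name__)

PARTITION_STATES = ("SWS", "REM", "AwT", "AwNT")


@dataclass
class HvsEvent:
    """One detected high-voltage spindle.

    ``onset``/``offset`` are the half-peak-power crossings (the event
    extent); ``core_onset``/``core_offset`` the raw z > 0.7 crossing extent,
    throughout which the 20-50 Hz z-score stays above threshold.
    """

    onset: float
    offset: float
    core_onset: float
    core_offset: float
    peak_power: float  # density at the first spectral peak, event-mean spectrum
    peak_freq: float  # first-spectral-peak frequency (Hz)
    peak_time: float  # time of maximal 20-50 Hz power
    peak_z: float
    state: str | None = None  # background state at onset (IMM/REM/SWS/other)

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class StateLabels:
    """Scored state intervals plus the HVS overlay."""

    states: dict[str, IntervalSet]
    hvs_events: list[HvsEvent] = field(default_factory=list)
    span: tuple[float, float] = (0.0, 0.0)

    def __getitem__(self, key: str) -> IntervalSet:
        return self.states[key]

    def label_at(self, t: float) -> str | None:
        for name in PARTITION_STATES:
            if self.states[name].contains(t):
                return name
        return None

    def check_partition(self, tol: float = 1e-6) -> bool:
        """Partition invariant: the four states tile the span disjointly."""
        total = sum(self.states[s].total() for s in PARTITION_STATES)
        span_len = self.span[1] - self.span[0]
        if abs(total - span_len) > tol:
            return False
        for i, a in enumerate(PARTITION_STATES):
            for b in PARTITION_STATES[i + 1 :]:
                if self.states[a].intersect(self.states[b]).total() > tol:
                    return False
        return True


def _check_base(a: BandPowerSeries, b: BandPowerSeries) -> None:
    if not a.same_base(b):
        raise ValueError("band-power series do not share a time base")


def detect_sw(
    delta: BandPowerSeries,
    alphabeta: BandPowerSeries,
    z_thr: float = -0.1,
    merge_gap: float = 5.0,
) -> IntervalSet:
    """Slow-wave states: z(delta + alpha-beta summed power) > z_thr."""
    _check_base(delta, alphabeta)
    s = delta.values + alphabeta.values
    z = (s - s.mean()) / s.std()
    return IntervalSet.from_samples(delta.times, z > z_thr, "SW").merge_gaps(merge_gap)


def detect_theta(
    theta: BandPowerSeries,
    delta: BandPowerSeries,
    ratio_thr: float = 4.0,
    merge_gap: float = 10.0,
    eps: float = 1e-12,
) -> IntervalSet:
    """Theta states: theta/delta mean-density ratio above ``ratio_thr``.

    The default threshold of 4 was chosen for prewhitened spectra, where a
    1/f background already sits near a ratio of ~2.4 (whitening weights
    density by roughly f^2); planted or physiological theta exceeds 10.
    """
    _check_base(theta, delta)
    if ratio_thr <= 0:
        raise ValueError("ratio_thr must be positive")
    denom = delta.values.copy()
    if np.any(denom <= 0):
        log.warning("zero/negative delta power bins floored at %g", eps)
        denom = np.maximum(denom, eps)
    ratio = theta.values / denom
    return IntervalSet.from_samples(theta.times, ratio > ratio_thr, "Theta").merge_gaps(
        merge_gap
    )


def _refine_edges(
    times: np.ndarray, series: np.ndarray, i0: int, i1: int, baseline: float
) -> tuple[float, float]:
    """Half-of-peak-power crossings inside a candidate run [i0, i1]."""
    seg = series[i0 : i1 + 1]
    ipk = i0 + int(np.argmax(seg))
    level = baseline + 0.5 * (series[ipk] - baseline)
    on = times[i0]
    for k in range(ipk, i0 - 1, -1):
        if series[k] < level:
            frac = (level - series[k]) / (series[k + 1] - series[k])
            on = times[k] + frac * (times[k + 1] - times[k])
            break
    off = times[i1]
    for k in range(ipk, i1 + 1):
        if series[k] < level:
            frac = (series[k - 1] - level) / (series[k - 1] - series[k])
            off = times[k - 1] + frac * (times[k] - times[k - 1])
            break
    return float(on), float(off)


def detect_hvs(
    spec: Spectrogram,
    z_thr: float = 0.7,
    min_dur: float = 1.0,
    harm_band: tuple[float, float] = (20.0, 50.0),
    peak_search: tuple[float, float] = (6.0, 12.0),
) -> list[HvsEvent]:
    """HVS events from the 20-50 Hz harmonic band of one reference channel.

    The mean 20-50 Hz density is z-scored over the whole recording and
    thresholded at ``z_thr``; candidates shorter than ``min_dur`` are
    skipped.  Events whose mean spectrum lacks a local peak below the upper
    edge of ``peak_search`` are rejected as artifacts (a genuine HVS always
    shows its 7-9 Hz fundamental).
    """
    if spec.freqs[-1] < harm_band[1]:
        raise ValueError("spectrogram must cover the 20-50 Hz harmonic band")
    series = band_power(spec, harm_band, agg="mean")
    v = series.values
    sd = v.std()
    if sd == 0:
        return []
    z = (v - v.mean()) / sd
    candidates = IntervalSet.from_samples(series.times, z > z_thr).drop_short(min_dur)
    baseline = float(np.median(v))
    t = series.times
    dt = series.step
    events: list[HvsEvent] = []
    lo_idx = np.searchsorted(spec.freqs, peak_search[0])
    hi_idx = np.searchsorted(spec.freqs, peak_search[1], side="right")
    for s, e in candidates:
        i0 = int(np.searchsorted(t, s))
        i1 = int(np.searchsorted(t, e) - 1)
        i1 = min(max(i1, i0), t.size - 1)
        onset, offset = _refine_edges(t, v, i0, i1, baseline)
        mean_spec = spec.power[i0 : i1 + 1].mean(axis=0)
        band_spec = mean_spec[lo_idx:hi_idx]
        if band_spec.size < 3:
            continue
        k = int(np.argmax(band_spec))
        # artifact screen: require a genuine local maximum below the upper edge
        if k == band_spec.size - 1:
            interior = band_spec[1:-1]
            loc = (interior > band_spec[:-2]) & (interior > band_spec[2:])
            if not loc.any():
                log.info("event at %.1fs rejected: no spectral peak below %.0f Hz", s, peak_search[1])
                continue
            k = 1 + int(np.argmax(np.where(loc, interior, -np.inf)))
        ipk = i0 + int(np.argmax(v[i0 : i1 + 1]))
        events.append(
            HvsEvent(
                onset=onset,
                offset=offset,
                core_onset=float(s),
                core_offset=float(e),
                peak_power=float(band_spec[k]),
                peak_freq=float(spec.freqs[lo_idx + k]),
                peak_time=float(t[ipk]),
                peak_z=float(z[i0 : i1 + 1].max()),
            )
        )
    return events


def _preceded_by(theta_iv: np.ndarray, sw: IntervalSet, max_gap: float) -> bool:
    """True if an SW interval begins before the theta onset and reaches
    within ``max_gap`` seconds of it (overlap allowed)."""
    t0 = theta_iv[0]
    for s, e in sw:
        if s >= t0:
            break
        if e >= t0 - max_gap:
            return True
    return False


def combine_states(
    sw: IntervalSet,
    theta: IntervalSet,
    motor: dict[str, IntervalSet],
    hvs_events: list[HvsEvent],
    span: tuple[float, float],
    hvs_guard: float = 2.0,
    hvs_sws_gap: float = 10.0,
    rem_max_gap: float = 1.0,
    rem_min_dur: float = 5.0,
    sw_merge_gap: float = 5.0,
    theta_merge_gap: float = 10.0,
) -> StateLabels:
    """Combine SW/Theta detections, motor states and HVS into state labels.

    HVS extents (core +- ``hvs_guard``) are excised from the SW and Theta
    streams first; gap concatenation is then re-applied with the excised
    time off the clock, so a background state continues across an overlaid
    event.  Where SW and Theta overlap, Theta wins (REM requires Theta to
    follow SW contiguously).  After assignment, the span each HVS masked is
    merged into the flanking state when both flanks agree, else into the
    preceding state.
    """
    span_set = IntervalSet(np.array([span], dtype=float))
    mask_iv = np.array(
        [[ev.core_onset - hvs_guard, ev.core_offset + hvs_guard] for ev in hvs_events]
    ).reshape(-1, 2)
    mask = IntervalSet(mask_iv).intersect(span_set) if len(mask_iv) else IntervalSet()
    sw_m = sw.subtract(mask).merge_gaps(sw_merge_gap, exclude=mask)
    theta_m = theta.subtract(mask).merge_gaps(theta_merge_gap, exclude=mask)
    if sw.intersect(theta).total() > 0:
        log.info("SW and Theta overlap; Theta precedence applied")
    sw_eff = sw_m.subtract(theta_m).intersect(span_set)
    theta_m = theta_m.intersect(span_set)
    inactive = motor["inactive"].intersect(span_set)

    # REM: inactive Theta, long enough, directly preceded by SW
    rem_rows, awt_rows = [], []
    inactive_theta = theta_m.intersect(inactive)
    for iv in inactive_theta.intervals:
        if iv[1] - iv[0] > rem_min_dur and _preceded_by(iv, sw_m, rem_max_gap):
            rem_rows.append(iv)
        else:
            awt_rows.append(iv)
    rem = IntervalSet(np.array(rem_rows).reshape(-1, 2), "REM")
    awt = theta_m.subtract(rem).relabel("AwT")

    # SWS: SW in the inactive state, truncated within 10 s after any HVS
    sws = sw_eff.intersect(inactive).relabel("SWS")
    if hvs_events:
        excl = IntervalSet(
            np.array(
                [[ev.core_onset, ev.core_offset + hvs_sws_gap] for ev in hvs_events]
            )
        )
        sws = sws.subtract(excl)
    sws = sws.subtract(rem).subtract(awt)

    awnt = (
        span_set.subtract(sws).subtract(rem).subtract(awt).relabel("AwNT")
    )
    states = {"SWS": sws, "REM": rem, "AwT": awt, "AwNT": awnt}

    # merge flanking states across each HVS; the overlay never changes coverage
    eps = 1e-9
    for row in mask.intervals:
        gap = IntervalSet(row.reshape(1, 2))
        before = _label_at(states, row[0] - eps)
        after = _label_at(states, row[1] + eps)
        target = before if (before == after or after is None) else before
        if target is None:
            target = after if after is not None else "AwNT"
        for name in PARTITION_STATES:
            if name == target:
                states[name] = states[name].union(gap).relabel(name)
            else:
                states[name] = states[name].subtract(gap).relabel(name)

    imm = inactive.intersect(states["AwT"].union(states["AwNT"])).relabel("IMM")
    out = StateLabels(
        states={
            **states,
            "SW": sw.relabel("SW"),
            "Theta": theta.relabel("Theta"),
            "IMM": imm,
        },
        hvs_events=list(hvs_events),
        span=span,
    )
    for ev in out.hvs_events:
        lab = out.label_at(min(max(ev.onset, span[0]), span[1] - eps))
        if lab in ("AwT", "AwNT") and inactive.contains(ev.onset):
            ev.state = "IMM"
        elif lab in ("REM", "SWS"):
            ev.state = lab
        else:
            ev.state = "other"
    return out


def _label_at(states: dict[str, IntervalSet], t: float) -> str | None:
    for name in PARTITION_STATES:
        if states[name].contains(t):
            return name
    return None
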