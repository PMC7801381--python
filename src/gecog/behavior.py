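"""Head-motion processing: speed, active/inactive motor states, rearing.

The motor-state rules follow the standard rodent-Mocap convention: head
speed above 100 mm/s marks activity; gaps in activity shorter than 5 s are
concatenated first and active fragments shorter than 5 s are then dropped.
Rearing is an overlay of the active state, detected as head elevation above
200 mm from the floor.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter

from .intervals import IntervalSet

__all__ = [
    "MotionTrack",
    "RearEvent",
    "head_speed",
    "segment_motor_state",
    "detect_rears",
]

log = logging.getLogger(__name__)


@dataclass
class MotionTrack:
    """3D head position (mm) sampled uniformly at ``fs`` Hz.

    ``gap_mask`` flags dropped Mocap frames (True = missing).  ``z`` is
    floor-referenced, so it must be non-negative.
    """

    t: np.ndarray
    xyz: np.ndarray  # (n, 3) in mm
    fs: float
    gap_mask: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise ValueError("xyz must have shape (n, 3)")
        if self.t.size != self.xyz.shape[0]:
            raise ValueError("t and xyz lengths differ")
        if self.t.size > 1 and np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.t.size and np.nanmin(self.xyz[:, 2]) < 0:
            raise ValueError("z must be floor-referenced (non-negative)")
        if self.gap_mask is None:
            self.gap_mask = np.zeros(self.t.size, dtype=bool)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)

    @property
    def z(self) -> np.ndarray:
        return self.xyz[:, 2]

    @property
    def span(self) -> tuple[float, float]:
        dt = 1.0 / self.fs
        return float(self.t[0]), float(self.t[-1] + dt)


@dataclass(frozen=True)
class RearEvent:
    """One head elevation above the rearing threshold."""

    onset: float
    offset: float
    peak_height: float

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def _fill_gaps(track: MotionTrack, max_gap: float) -> tuple[np.ndarray, np.ndarray]:
    """Linearly interpolate dropped frames up to ``max_gap`` seconds.

    Returns filled positions and a boolean mask of samples that remain
    missing (gaps longer than ``max_gap``).
    """
    xyz = track.xyz.copy()
    missing = track.gap_mask.copy()
    if not missing.any():
        return xyz, missing
    long_missing = IntervalSet.from_samples(track.t, missing).drop_short(max_gap)
    still = long_missing.to_mask(track.t)
    fill = missing & ~still
    if fill.any():
        good = ~missing
        for ax in range(3):
            xyz[fill, ax] = np.interp(track.t[fill], track.t[good], xyz[good, ax])
    return xyz, still


def head_speed(track: MotionTrack, median_window: float = 0.25, max_gap: float = 0.5) -> np.ndarray:
    """3D head speed in mm/s on the track's time base.

    The position coordinates are despiked with a moving median of
    ``median_window`` seconds (exact on linear motion), then differentiated
    by central differences; speed is the Euclidean norm of the velocity.
    Dropped frames are linearly interpolated up to ``max_gap`` s; longer
    gaps propagate as NaN.
    """
    if track.t.size < 2:
        raise ValueError("need at least two samples to differentiate")
    xyz, still_missing = _fill_gaps(track, max_gap)
    win = max(1, int(round(median_window * track.fs)))
    if win % 2 == 0:
        win += 1
    if win > 1:
        xyz = median_filter(xyz, size=(win, 1), mode="nearest")
    vel = np.gradient(xyz, 1.0 / track.fs, axis=0)
    speed = np.linalg.norm(vel, axis=1)
    if still_missing.any():
        speed[still_missing] = np.nan
    return speed


def segment_motor_state(
    track: MotionTrack,
    speed: np.ndarray | None = None,
    thr: float = 100.0,
    min_dur: float = 5.0,
    max_gap: float = 5.0,
) -> dict[str, IntervalSet]:
    """Active/inactive motor states from head speed.

    Threshold at ``thr`` mm/s, concatenate sub-``max_gap`` gaps, then drop
    active fragments shorter than ``min_dur``.  Inactive is the exact
    complement over the track span.
    """
    if speed is None:
        speed = head_speed(track)
    with np.errstate(invalid="ignore"):
        mask = speed > thr
    active = (
        IntervalSet.from_samples(track.t, mask, "active")
        .merge_gaps(max_gap)
        .drop_short(min_dur)
    )
    span = track.span
    active = active.intersect(IntervalSet(np.array([span])))
    inactive = active.complement(span).relabel("inactive")
    return {"active": active, "inactive": inactive}


def detect_rears(
    track: MotionTrack,
    z_thr: float = 200.0,
    active: IntervalSet | None = None,
) -> list[RearEvent]:
    """Rearing events as maximal periods with head elevation above ``z_thr`` mm.

    Onset/offset are the threshold crossings, linearly interpolated between
    frames.  If ``active`` is given, events outside the active motor state
    are flagged with a warning (but kept).
    """
    z = track.z
    t = track.t
    above = z > z_thr
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    events = []
    for i0, i1 in zip(starts, ends):
        if i0 > 0:
            frac = (z_thr - z[i0 - 1]) / (z[i0] - z[i0 - 1])
            onset = t[i0 - 1] + frac * (t[i0] - t[i0 - 1])
        else:
            onset = t[0]
        if i1 < z.size:
            frac = (z[i1 - 1] - z_thr) / (z[i1 - 1] - z[i1])
            offset = t[i1 - 1] + frac * (t[i1] - t[i1 - 1])
        else:
            offset = t[-1]
        ev = RearEvent(onset=float(onset), offset=float(offset), peak_height=float(z[i0:i1].max()))
        if active is not None and not active.contains(0.5 * (ev.onset + ev.offset)):
            warnings.warn(f"rear event at {ev.onset:.2f}s falls outside the active motor state")
        events.append(ev)
    return events
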