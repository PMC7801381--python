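"""Half-open time intervals and the algebra used throughout state scoring.

Intervals are ``[start, end)`` in seconds from recording start.  An
:class:`IntervalSet` is always canonical: sorted by start, non-overlapping,
with every ``end > start``.  Touching intervals (``a.end == b.start``) are
merged on construction, which is the natural convention for half-open
intervals on a continuous time axis.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["IntervalSet", "interval_algebra"]


def _canonical(intervals) -> np.ndarray:
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if iv.size == 0:
        return iv.reshape(0, 2)
    if np.any(iv[:, 1] <= iv[:, 0]):
        raise ValueError("interval end must be greater than start")
    iv = iv[np.argsort(iv[:, 0], kind="stable")]
    out = [iv[0].copy()]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append(np.array([s, e]))
    return np.array(out)


@dataclass(frozen=True)
class IntervalSet:
    """A labelled set of half-open ``[start, end)`` intervals (seconds)."""

    intervals: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    label: str = ""

    def __post_init__(self):
        object.__setattr__(self, "intervals", _canonical(self.intervals))

    # -- basics ------------------------------------------------------------
    def __len__(self) -> int:
        return self.intervals.shape[0]

    def __iter__(self):
        return iter(map(tuple, self.intervals))

    @property
    def starts(self) -> np.ndarray:
        return self.intervals[:, 0]

    @property
    def ends(self) -> np.ndarray:
        return self.intervals[:, 1]

    @property
    def durations(self) -> np.ndarray:
        return self.intervals[:, 1] - self.intervals[:, 0]

    def total(self) -> float:
        """Total covered duration in seconds."""
        return float(self.durations.sum())

    def relabel(self, label: str) -> "IntervalSet":
        return IntervalSet(self.intervals, label)

    def contains(self, t: float) -> bool:
        i = np.searchsorted(self.starts, t, side="right") - 1
        return i >= 0 and t < self.intervals[i, 1]

    # -- set algebra -------------------------------------------------------
    def union(self, other: "IntervalSet") -> "IntervalSet":
        if len(self) == 0:
            return IntervalSet(other.intervals, self.label)
        if len(other) == 0:
            return IntervalSet(self.intervals, self.label)
        return IntervalSet(np.vstack([self.intervals, other.intervals]), self.label)

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        i = j = 0
        a, b = self.intervals, other.intervals
        while i < len(a) and j < len(b):
            s = max(a[i, 0], b[j, 0])
            e = min(a[i, 1], b[j, 1])
            if e > s:
                out.append((s, e))
            if a[i, 1] < b[j, 1]:
                i += 1
            else:
                j += 1
        return IntervalSet(np.array(out).reshape(-1, 2), self.label)

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        out = []
        b = other.intervals
        for s, e in self.intervals:
            cur = s
            for bs, be in b:
                if be <= cur or bs >= e:
                    continue
                if bs > cur:
                    out.append((cur, bs))
                cur = max(cur, be)
                if cur >= e:
                    break
            if cur < e:
                out.append((cur, e))
        return IntervalSet(np.array(out).reshape(-1, 2), self.label)

    def complement(self, span: tuple[float, float]) -> "IntervalSet":
        return IntervalSet(np.array([span], dtype=float), self.label).subtract(self)

    # -- cleaning ----------------------------------------------------------
    def merge_gaps(self, tau: float, exclude: "IntervalSet | None" = None) -> "IntervalSet":
        """Concatenate intervals separated by gaps strictly shorter than ``tau``.

        When ``exclude`` is given, time covered by it does not count towards
        the gap length (the excluded spans are treated as off-the-clock, as
        when overlaid events are excised from a detection stream).
        """
        if tau < 0:
            raise ValueError("tau must be >= 0")
        if len(self) <= 1:
            return self
        iv = self.intervals
        out = [iv[0].copy()]
        for s, e in iv[1:]:
            gap = s - out[-1][1]
            if exclude is not None and gap > 0:
                gap -= exclude.intersect(
                    IntervalSet(np.array([[out[-1][1], s]]))
                ).total()
            if gap < tau:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append(np.array([s, e]))
        return IntervalSet(np.array(out), self.label)

    def drop_short(self, tau: float) -> "IntervalSet":
        if tau < 0:
            raise ValueError("tau must be >= 0")
        keep = self.durations >= tau
        return IntervalSet(self.intervals[keep], self.label)

    # -- raster conversion ---------------------------------------------------
    def to_mask(self, times: np.ndarray) -> np.ndarray:
        """Boolean membership of each sample time (vectorised)."""
        times = np.asarray(times)
        idx = np.searchsorted(self.starts, times, side="right") - 1
        ok = idx >= 0
        mask = np.zeros(times.shape, dtype=bool)
        mask[ok] = times[ok] < self.intervals[idx[ok], 1]
        return mask

    @classmethod
    def from_samples(cls, times: np.ndarray, mask: np.ndarray, label: str = "") -> "IntervalSet":
        """Intervals from a boolean series on a uniform time grid.

        Each sample at time ``t`` is taken to represent the half-open bin
        ``[t - dt/2, t + dt/2)``, so a run of True samples from ``t_i`` to
        ``t_j`` becomes ``[t_i - dt/2, t_j + dt/2)``.
        """
        times = np.asarray(times, dtype=float)
        mask = np.asarray(mask, dtype=bool)
        if times.size != mask.size:
            raise ValueError("times and mask must have equal length")
        if times.size == 0 or not mask.any():
            return cls(np.empty((0, 2)), label)
        dt = times[1] - times[0] if times.size > 1 else 1.0
        d = np.diff(mask.astype(np.int8))
        starts = np.flatnonzero(d == 1) + 1
        ends = np.flatnonzero(d == -1) + 1
        if mask[0]:
            starts = np.r_[0, starts]
        if mask[-1]:
            ends = np.r_[ends, mask.size]
        iv = np.c_[times[starts] - dt / 2, times[ends - 1] + dt / 2]
        return cls(iv, label)


def interval_algebra(a: IntervalSet, b: IntervalSet | None, op: str, tau: float | None = None) -> IntervalSet:
    """Dispatch interval-set operations by name.

    ``op`` is one of ``union``, ``intersect``, ``subtract``, ``merge_gaps``,
    ``drop_short``.  The latter two ignore ``b`` and require ``tau``.
    """
    if op == "union":
        return a.union(b)
    if op == "intersect":
        return a.intersect(b)
    if op == "subtract":
        return a.subtract(b)
    if op == "merge_gaps":
        if tau is None:
            raise ValueError("merge_gaps requires tau")
        return a.merge_gaps(tau)
    if op == "drop_short":
        if tau is None:
            raise ValueError("drop_short requires tau")
        return a.drop_short(tau)
    raise ValueError(f"unknown interval operation {op!r}")
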