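"""Independent brute-force oracles used to cross-check interval and state logic.

Everything here works on dense boolean rasters (integer grids), deliberately
avoiding the package's interval machinery so the two routes stay independent.
"""
from __future__ import annotations

import numpy as np

from gecog.intervals import IntervalSet


def iv_to_units(ivset: IntervalSet, res: float) -> list[tuple[int, int]]:
    return [(int(round(s / res)), int(round(e / res))) for s, e in ivset]


def units_to_mask(pairs, n) -> np.ndarray:
    m = np.zeros(n, dtype=bool)
    for s, e in pairs:
        m[max(s, 0) : min(e, n)] = True
    return m


def mask_to_pairs(m: np.ndarray) -> list[tuple[int, int]]:
    out = []
    i = 0
    n = m.size
    while i < n:
        if m[i]:
            j = i
            while j < n and m[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def mask_merge_gaps(m: np.ndarray, tau_units: int) -> np.ndarray:
    """Fill False runs strictly shorter than tau between True runs."""
    out = m.copy()
    pairs = mask_to_pairs(m)
    for (s0, e0), (s1, e1) in zip(pairs, pairs[1:]):
        if s1 - e0 < tau_units:
            out[e0:s1] = True
    return out


def mask_drop_short(m: np.ndarray, tau_units: int) -> np.ndarray:
    out = m.copy()
    for s, e in mask_to_pairs(m):
        if e - s < tau_units:
            out[s:e] = False
    return out


def mask_op(a, b, op, tau_units=None):
    if op == "union":
        return a | b
    if op == "intersect":
        return a & b
    if op == "subtract":
        return a & ~b
    if op == "merge_gaps":
        return mask_merge_gaps(a, tau_units)
    if op == "drop_short":
        return mask_drop_short(a, tau_units)
    raise ValueError(op)


def random_pairs(rng, n_units, n_iv, max_len=50):
    """Random non-degenerate intervals on an integer grid (may overlap)."""
    s = rng.integers(0, n_units - 1, size=n_iv)
    e = s + rng.integers(1, max_len, size=n_iv)
    return list(zip(s.tolist(), np.minimum(e, n_units).tolist()))


def jaccard(a: IntervalSet, b: IntervalSet) -> float:
    u = a.union(b).total()
    return a.intersect(b).total() / u if u > 0 else 1.0


# ---------------------------------------------------------------------------
# dense-grid re-implementation of the written state-combination rules
# ---------------------------------------------------------------------------


def oracle_combine(
    sw: IntervalSet,
    theta: IntervalSet,
    inactive: IntervalSet,
    hvs_events,
    span,
    res: float = 0.01,
    guard: float = 2.0,
    sw_merge: float = 5.0,
    theta_merge: float = 10.0,
    rem_gap: float = 1.0,
    rem_min: float = 5.0,
    sws_gap: float = 10.0,
) -> dict[str, np.ndarray]:
    """Brute-force mask implementation of the combination rules.

    Returns per-state boolean masks on the ``res``-resolution grid covering
    ``span``.  Mirrors the written rules: excise HVS (core +- guard) from SW
    and Theta, gap-merge with excised time off the clock, Theta beats SW,
    REM = inactive Theta > rem_min preceded by SW within rem_gap, SWS = SW
    and inactive outside the 10-s post-HVS zone, rest AwNT; finally merge
    flanks across each HVS (preceding state if flanks disagree).
    """
    n = int(round((span[1] - span[0]) / res))

    def to_mask(ivset):
        m = np.zeros(n, dtype=bool)
        for s, e in ivset:
            i0 = max(int(round((s - span[0]) / res)), 0)
            i1 = min(int(round((e - span[0]) / res)), n)
            m[i0:i1] = True
        return m

    u = lambda x: int(round(x / res))
    sw_m = to_mask(sw)
    th_m = to_mask(theta)
    inact = to_mask(inactive)
    mask = np.zeros(n, dtype=bool)
    for ev in hvs_events:
        i0 = max(u(ev.core_onset - guard), 0)
        i1 = min(u(ev.core_offset + guard), n)
        mask[i0:i1] = True

    def merge_excl(m, tau):
        out = (m & ~mask).copy()
        pairs = mask_to_pairs(out)
        for (s0, e0), (s1, e1) in zip(pairs, pairs[1:]):
            gap = (s1 - e0) - int(mask[e0:s1].sum())
            if gap < u(tau):
                out[e0:s1] = True
        return out

    sw2 = merge_excl(sw_m, sw_merge)
    th2 = merge_excl(th_m, theta_merge)
    sw_eff = sw2 & ~th2

    rem = np.zeros(n, dtype=bool)
    awt = np.zeros(n, dtype=bool)
    for s, e in mask_to_pairs(th2 & inact):
        long_enough = (e - s) * res > rem_min
        preceded = _preceded(sw2, s, u(rem_gap))
        if long_enough and preceded:
            rem[s:e] = True
        else:
            awt[s:e] = True
    awt = awt | (th2 & ~inact)

    sws = sw_eff & inact
    for ev in hvs_events:
        i0 = max(u(ev.core_onset), 0)
        i1 = min(u(ev.core_offset + sws_gap), n)
        sws[i0:i1] = False
    sws = sws & ~rem & ~awt
    awnt = ~(sws | rem | awt)

    states = {"SWS": sws, "REM": rem, "AwT": awt, "AwNT": awnt}
    for s, e in mask_to_pairs(mask):
        before = _label(states, s - 1) if s > 0 else None
        after = _label(states, e) if e < n else None
        target = before if (before == after or after is None) else before
        if target is None:
            target = after if after is not None else "AwNT"
        for name, m in states.items():
            m[s:e] = name == target
    states["IMM"] = inact & (states["AwT"] | states["AwNT"])
    return states


def _label(states, i):
    for name in ("SWS", "REM", "AwT", "AwNT"):
        if states[name][i]:
            return name
    return None


def _preceded(sw_mask: np.ndarray, start: int, gap_units: int) -> bool:
    """An SW interval begins before ``start`` and reaches within the (closed)
    gap bound of it, i.e. an SW sample exists in [start-gap-1, start)."""
    lb = max(start - gap_units - 1, 0)
    return bool(sw_mask[lb:start].any())
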