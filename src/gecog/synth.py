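"""Synthetic session generator with full ground truth.

Emulates the statistical structure a DC-coupled graphene-transistor ECoG
recording of a freely behaving rat presents to the analysis chain:

* a polyphasic state schedule over {SWS, REM, AwT, AwNT-active, IMM} with
  exact, configurable event counts (the reference 24-h schedule plants
  566 immobility and 92 REM high-voltage spindles, 44 REM episodes all
  longer than 40 s and 163 rears — the reference totals the pipeline is
  checked against);
* state-sequenced LFP: 1-4 Hz slow waves and 10-14 Hz spindle bursts in
  SWS, harmonic-free 7.5 Hz theta in REM/AwT, harmonic-rich sawtooth-like
  HVS events, infra-slow activity whose phase multiplicatively modulates
  band powers, and broadband gamma with rear-related suppression;
* a transistor + headstage forward model (transfer curve with CNP drift,
  1/f current noise, DC/AC paths with a 0.15 Hz hardware high-pass and
  path-specific quantisation);
* a 3D head trajectory with active bouts, immobility and rearing events.

Everything is seed-deterministic: the same seed yields bit-identical
output.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import butter, lfilter

from .behavior import MotionTrack
from .intervals import IntervalSet
from .session import ArrayGeometry, Session, TransferSweep

__all__ = [
    "PlantedHvs",
    "PlantedRear",
    "Coupling",
    "GroundTruth",
    "LfpParams",
    "SensorModel",
    "generate_states",
    "generate_lfp",
    "generate_motion",
    "sensor_forward",
    "generate_session",
    "reference_day",
]

log = logging.getLogger(__name__)

DAY = 86400.0


@dataclass(frozen=True)
class PlantedHvs:
    onset: float
    duration: float
    freq: float
    state: str  # 'IMM' or 'REM'

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class PlantedRear:
    onset: float
    duration: float
    peak_height: float

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class Coupling:
    """One planted phase-amplitude coupling.

    The power of ``fast`` ('theta' | 'spindle' | 'high_gamma') is modulated
    by the phase of ``slow`` ('isa' | 'theta') as (1 + depth*cos(phi -
    phase_deg)), restricted to the listed states.
    """

    slow: str
    fast: str
    depth: float
    phase_deg: float
    states: tuple[str, ...]


@dataclass
class GroundTruth:
    """Everything needed to predict the analyzers' ideal output."""

    duration: float
    seed: int
    states: dict[str, IntervalSet]
    motor: dict[str, IntervalSet]
    hvs: list[PlantedHvs]
    rears: list[PlantedRear]
    couplings: list[Coupling] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            dict(
                duration=self.duration,
                seed=self.seed,
                states={k: v.intervals.tolist() for k, v in self.states.items()},
                motor={k: v.intervals.tolist() for k, v in self.motor.items()},
                hvs=[asdict(h) for h in self.hvs],
                rears=[asdict(r) for r in self.rears],
                couplings=[asdict(c) for c in self.couplings],
                params=self.params,
            )
        )

    @classmethod
    def from_json(cls, s: str) -> "GroundTruth":
        d = json.loads(s)
        return cls(
            duration=d["duration"],
            seed=d["seed"],
            states={k: IntervalSet(np.array(v).reshape(-1, 2), k) for k, v in d["states"].items()},
            motor={k: IntervalSet(np.array(v).reshape(-1, 2), k) for k, v in d["motor"].items()},
            hvs=[PlantedHvs(**h) for h in d["hvs"]],
            rears=[PlantedRear(**r) for r in d["rears"]],
            couplings=[Coupling(slow=c["slow"], fast=c["fast"], depth=c["depth"],
                                phase_deg=c["phase_deg"], states=tuple(c["states"]))
                       for c in d["couplings"]],
            params=d["params"],
        )


def _lognormal(rng, median, sigma, size, clip):
    x = median * np.exp(sigma * rng.standard_normal(size))
    return np.clip(x, *clip)


def _place_events(rng, blocks, counts, dur_fun, edge, gap_lo, gap_hi):
    """Place ``counts[i]`` events inside each block, sequential with jittered gaps."""
    onsets, durs = [], []
    for (b0, b1), cnt in zip(blocks, counts):
        cursor = b0 + edge
        for _ in range(cnt):
            d = dur_fun()
            if cursor + d > b1 - edge:
                raise RuntimeError("event scheduling overflowed its block")
            onsets.append(cursor)
            durs.append(d)
            cursor += d + rng.uniform(gap_lo, gap_hi)
    return np.array(onsets), np.array(durs)


def _allocate(capacities: np.ndarray, total: int) -> np.ndarray:
    """Deterministic round-robin allocation of ``total`` events, capped per block."""
    if capacities.sum() < total:
        raise ValueError("not enough block capacity for the requested event count")
    counts = np.zeros(capacities.size, dtype=int)
    while counts.sum() < total:
        for i in range(capacities.size):
            if counts.sum() >= total:
                break
            if counts[i] < capacities[i]:
                counts[i] += 1
    return counts


DEFAULT_COUPLINGS = (
    Coupling("isa", "theta", 0.8, 340.0, ("REM",)),
    Coupling("isa", "spindle", 0.6, 180.0, ("SWS",)),
    Coupling("theta", "high_gamma", 0.6, 0.0, ("REM",)),
)


def generate_states(
    duration: float = DAY,
    seed: int = 0,
    n_rem: int = 44,
    n_hvs_imm: int = 566,
    n_hvs_rem: int = 92,
    hvs_dur_median: float = 5.0,
    hvs_dur_sigma: float = 0.25,
    hvs_freq_imm: float = 8.5,
    hvs_freq_rem: float = 7.5,
    n_rears: int = 163,
    rear_height_mean: float = 250.6,
    rear_height_sd: float = 20.0,
    rear_dur_mean: float = 5.7,
    rear_dur_sd: float = 2.8,
    n_cycles: int = 72,
    rem_dur_median: float = 110.0,
    rem_dur_sigma: float = 0.25,
    sws_dur_median: float = 240.0,
    sws_dur_sigma: float = 0.3,
    imm_dur_median: float = 260.0,
    imm_dur_sigma: float = 0.3,
    awt_dur_median: float = 150.0,
    awt_dur_sigma: float = 0.3,
    couplings: tuple[Coupling, ...] = DEFAULT_COUPLINGS,
) -> GroundTruth:
    """Build a state schedule with exact event counts and full ground truth.

    The schedule cycles through wake (AwNT-active, AwT), alert immobility,
    SWS and (in ``n_rem`` randomly chosen cycles) REM, so REM is reachable
    only from SWS.  HVS events are planted deterministically inside IMM and
    REM with log-normal durations (median ``hvs_dur_median``); rears inside
    active wake.  Durations are log-normal with the given medians; the
    flexible AwNT-active blocks absorb whatever time remains, so the blocks
    tile ``duration`` exactly.
    """
    rng = np.random.default_rng(seed)
    if n_rem > n_cycles:
        raise ValueError("n_rem cannot exceed n_cycles")

    rem_durs = _lognormal(rng, rem_dur_median, rem_dur_sigma, n_rem, (70.0, 240.0))
    sws_durs = _lognormal(rng, sws_dur_median, sws_dur_sigma, n_cycles, (120.0, 700.0))
    awt_durs = _lognormal(rng, awt_dur_median, awt_dur_sigma, n_cycles, (60.0, 400.0))

    # IMM blocks must have the capacity for the scheduled HVS load
    hvs_dur_max, hvs_gap = 9.5, (11.0, 15.0)
    footprint = hvs_dur_max + hvs_gap[1]
    edge = 14.0
    imm_durs = _lognormal(rng, imm_dur_median, imm_dur_sigma, n_cycles, (120.0, 700.0))
    for _ in range(6):
        caps = np.floor((imm_durs - 2 * edge) / footprint).astype(int)
        if caps.sum() >= n_hvs_imm:
            break
        imm_durs = imm_durs * 1.2
    else:
        raise ValueError("IMM schedule cannot host the requested HVS count")

    rem_cycles = np.sort(rng.choice(n_cycles, size=n_rem, replace=False))
    fixed = rem_durs.sum() + sws_durs.sum() + awt_durs.sum() + imm_durs.sum()
    n_slots = 2 * n_cycles
    min_awnt = 20.0
    remaining = duration - fixed
    if remaining < min_awnt * n_slots:
        raise ValueError(
            f"schedule does not fit in {duration:.0f}s (fixed blocks {fixed:.0f}s)"
        )
    w = rng.dirichlet(np.full(n_slots, 5.0))
    awnt_durs = min_awnt + w * (remaining - min_awnt * n_slots)

    labels: dict[str, list] = {k: [] for k in ("SWS", "REM", "AwT", "AwNT_active", "IMM")}
    cursor = 0.0
    rem_iter = iter(rem_durs)
    for i in range(n_cycles):
        seq = [
            ("AwNT_active", awnt_durs[2 * i]),
            ("AwT", awt_durs[i]),
            ("AwNT_active", awnt_durs[2 * i + 1]),
            ("IMM", imm_durs[i]),
            ("SWS", sws_durs[i]),
        ]
        if i in rem_cycles:
            seq.append(("REM", next(rem_iter)))
        for name, dur in seq:
            labels[name].append((cursor, cursor + dur))
            cursor += dur

    states = {k: IntervalSet(np.array(v).reshape(-1, 2), k) for k, v in labels.items()}
    states["AwNT"] = states["AwNT_active"].union(states["IMM"]).relabel("AwNT")
    active = states["AwNT_active"].union(states["AwT"]).relabel("active")
    inactive = active.complement((0.0, duration)).relabel("inactive")

    def hvs_dur():
        return float(np.clip(hvs_dur_median * np.exp(hvs_dur_sigma * rng.standard_normal()), 2.5, hvs_dur_max))

    imm_blocks = [tuple(iv) for iv in states["IMM"].intervals]
    caps = np.floor((np.diff(states["IMM"].intervals, axis=1).ravel() - 2 * edge) / footprint).astype(int)
    counts = _allocate(caps, n_hvs_imm)
    on_i, du_i = _place_events(rng, imm_blocks, counts, hvs_dur, edge, *hvs_gap)

    rem_blocks = [tuple(iv) for iv in states["REM"].intervals]
    rem_edge = 10.0
    caps_r = np.floor((np.diff(states["REM"].intervals, axis=1).ravel() - 2 * rem_edge) / footprint).astype(int)
    counts_r = _allocate(caps_r, n_hvs_rem)
    on_r, du_r = _place_events(rng, rem_blocks, counts_r, hvs_dur, rem_edge, *hvs_gap)

    hvs = [PlantedHvs(float(o), float(d), hvs_freq_imm, "IMM") for o, d in zip(on_i, du_i)]
    hvs += [PlantedHvs(float(o), float(d), hvs_freq_rem, "REM") for o, d in zip(on_r, du_r)]
    hvs.sort(key=lambda h: h.onset)

    act_iv = active.intervals
    big = act_iv[np.diff(act_iv, axis=1).ravel() >= 40.0]
    rear_footprint = 14.0 + 8.0
    caps_a = np.floor((np.diff(big, axis=1).ravel() - 12.0) / rear_footprint).astype(int)
    counts_a = _allocate(caps_a, n_rears)

    def rear_dur():
        return float(np.clip(rng.normal(rear_dur_mean, rear_dur_sd), 1.5, 14.0))

    on_a, du_a = _place_events(rng, [tuple(iv) for iv in big], counts_a, rear_dur, 6.0, 4.0, 8.0)
    heights = np.clip(rng.normal(rear_height_mean, rear_height_sd, n_rears), 225.0, 320.0)
    rears = sorted(
        (PlantedRear(float(o), float(d), float(h)) for o, d, h in zip(on_a, du_a, heights)),
        key=lambda r: r.onset,
    )

    return GroundTruth(
        duration=duration,
        seed=seed,
        states={k: states[k] for k in ("SWS", "REM", "AwT", "AwNT", "AwNT_active", "IMM")},
        motor={"active": active, "inactive": inactive},
        hvs=hvs,
        rears=list(rears),
        couplings=list(couplings),
        params=dict(
            hvs_dur_median=hvs_dur_median,
            hvs_freq_imm=hvs_freq_imm,
            hvs_freq_rem=hvs_freq_rem,
            n_rem=n_rem,
            n_hvs_imm=n_hvs_imm,
            n_hvs_rem=n_hvs_rem,
            n_rears=n_rears,
        ),
    )


# ---------------------------------------------------------------------------
# LFP synthesis
# ---------------------------------------------------------------------------


@dataclass
class LfpParams:
    """Amplitudes (volts) and bands of the planted LFP components.

    Absolute epicortical amplitudes are order-of-magnitude realistic for
    rat ECoG (tens to hundreds of microvolts); infra-slow and HVS DC
    amplitudes in particular are plausible guesses, not measured values.
    """

    pink_rms: float = 30e-6
    white_rms: float = 3e-6
    delta_rms: float = 200e-6
    delta_band: tuple[float, float] = (1.0, 4.0)
    spindle_rms: float = 80e-6
    spindle_band: tuple[float, float] = (10.0, 14.0)
    theta_amp: float = 100e-6
    theta_freq: float = 7.5
    hvs_amp: float = 300e-6
    hvs_max_harm_freq: float = 50.0
    hvs_ramp: float = 0.5
    isa_freq: float = 0.08
    isa_amp_sws: float = 100e-6
    isa_amp_rem: float = 300e-6
    isa_amp_wake: float = 50e-6
    gamma_rms: float = 15e-6
    gamma_band: tuple[float, float] = (60.0, 70.0)
    high_gamma_rms: float = 20e-6
    high_gamma_band: tuple[float, float] | None = None  # (90, min(200, 0.45 fs))
    rear_suppression: float = 0.5
    hvs_dc_amp: float = 200e-6
    state_ramp: float = 0.5
    coupling_ap_gradient: tuple[float, float] | None = None


def _band_noise(n, fs, lo, hi, rng, edge_frac=0.1):
    """Unit-rms Gaussian noise band-limited to [lo, hi] Hz (soft edges)."""
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    w = hi - lo
    e = max(edge_frac * w, f[1])
    g = np.zeros_like(f)
    core = (f >= lo) & (f <= hi)
    g[core] = 1.0
    rise = (f >= lo - e) & (f < lo)
    g[rise] = 0.5 * (1 - np.cos(np.pi * (f[rise] - (lo - e)) / e))
    fall = (f > hi) & (f <= hi + e)
    g[fall] = 0.5 * (1 + np.cos(np.pi * (f[fall] - hi) / e))
    y = np.fft.irfft(X * g, n=n)
    s = y.std()
    return y / s if s > 0 else y


def _pink_noise(n, fs, rng, f_knee=0.5):
    """Unit-rms 1/f noise (flat below ``f_knee`` to bound the DC region)."""
    x = rng.standard_normal(n)
    X = np.fft.rfft(x)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    g = 1.0 / np.sqrt(np.maximum(f, f_knee))
    g[0] = 0.0
    y = np.fft.irfft(X * g, n=n)
    return y / y.std()


def _envelope(iv: IntervalSet, n, fs, ramp=0.5):
    """0/1 occupancy of an interval set, smoothed with a ``ramp``-s boxcar."""
    env = np.zeros(n, dtype=np.float32)
    for s, e in iv:
        i0, i1 = max(int(round(s * fs)), 0), min(int(round(e * fs)), n)
        env[i0:i1] = 1.0
    size = int(round(ramp * fs))
    if size > 1:
        env = uniform_filter1d(env, size, mode="nearest")
    return env


def _hvs_ramp_env(tau, dur, r):
    """Amplitude envelope whose *power* is half-maximal exactly at the
    nominal onset/offset (plateau inside, sin ramps of half-width r)."""
    env = np.ones_like(tau)
    rise = tau < r
    env[rise] = np.sin(np.pi * (tau[rise] + r) / (4 * r))
    fall = tau > dur - r
    env[fall] = np.sin(np.pi * ((dur + r - tau[fall])) / (4 * r))
    env[(tau < -r) | (tau > dur + r)] = 0.0
    return np.clip(env, 0.0, 1.0)


def _coupling_factor(coupl, phase_rad, env_states):
    """sqrt(1 + depth*cos(phi - phi0)) blended in over the coupling's states."""
    mod = np.sqrt(np.maximum(1.0 + coupl.depth * np.cos(phase_rad - np.radians(coupl.phase_deg)), 0.0))
    env = np.zeros_like(mod, dtype=np.float32)
    for s in coupl.states:
        env = np.maximum(env, env_states[s])
    return 1.0 + env * (mod - 1.0)


def generate_lfp(
    truth: GroundTruth,
    fs: float = 250.0,
    n_channels: int = 1,
    params: LfpParams | None = None,
    seed: int | None = None,
    geometry: ArrayGeometry | None = None,
) -> np.ndarray:
    """Render per-channel gate-voltage traces (V) from the state schedule.

    Channels share the event/state timing but carry independent noise.  The
    per-event infra-slow DC transient reverses sign along the
    anterio-posterior axis (coefficient +1 at AP position 0 to -1 at 1).
    """
    p = params or LfpParams()
    seed = truth.seed if seed is None else seed
    n = int(round(truth.duration * fs))
    t = np.arange(n) / fs

    env = {
        "SWS": _envelope(truth.states["SWS"], n, fs, p.state_ramp),
        "REM": _envelope(truth.states["REM"], n, fs, p.state_ramp),
        "AwT": _envelope(truth.states["AwT"], n, fs, p.state_ramp),
    }
    env["wake"] = np.clip(1.0 - env["SWS"] - env["REM"], 0.0, 1.0)
    rear_iv = IntervalSet(np.array([[r.onset, r.offset] for r in truth.rears]).reshape(-1, 2))
    env_rear = _envelope(rear_iv, n, fs, 0.25) if len(rear_iv) else np.zeros(n, dtype=np.float32)

    master = np.random.default_rng(seed)
    phi_isa = float(master.uniform(0, 2 * np.pi))
    phi_theta = float(master.uniform(0, 2 * np.pi))
    isa_phase = 2 * np.pi * p.isa_freq * t + phi_isa
    theta_phase = 2 * np.pi * p.theta_freq * t + phi_theta

    cpl = {(c.slow, c.fast): c for c in truth.couplings}

    # shared deterministic components -------------------------------------
    theta_env = env["REM"].astype(np.float64) + env["AwT"]
    if ("isa", "theta") in cpl:
        theta_env = theta_env * _coupling_factor(cpl[("isa", "theta")], isa_phase, env)
    theta_sig = p.theta_amp * theta_env * np.cos(theta_phase)

    isa_amp = (
        p.isa_amp_sws * env["SWS"] + p.isa_amp_rem * env["REM"] + p.isa_amp_wake * env["wake"]
    )
    isa_sig = isa_amp * np.cos(isa_phase)

    hvs_sig = np.zeros(n)
    hvs_bump = np.zeros(n)  # per-event infra-slow transient (unit AP coefficient)
    for ev in truth.hvs:
        r = p.hvs_ramp / 2
        i0 = max(int((ev.onset - r) * fs), 0)
        i1 = min(int((ev.offset + r) * fs) + 1, n)
        tau = t[i0:i1] - ev.onset
        envw = _hvs_ramp_env(tau, ev.duration, r)
        n_harm = max(int(p.hvs_max_harm_freq // ev.freq), 1)
        n_harm = min(n_harm, int((0.45 * fs) // ev.freq))
        wav = np.zeros(i1 - i0)
        for k in range(1, n_harm + 1):
            wav += (p.hvs_amp / k) * np.cos(2 * np.pi * k * ev.freq * tau)
        hvs_sig[i0:i1] += envw * wav
        hvs_bump[i0:i1] += p.hvs_dc_amp * np.sin(np.pi * np.clip(tau / ev.duration, 0, 1)) ** 2

    out = np.empty((n_channels, n))
    for ch in range(n_channels):
        rng = np.random.default_rng([seed, 7919, ch])
        if geometry is not None:
            ap = geometry.ap_position(ch)
        else:
            ap = ch / max(n_channels - 1, 1)
        ap_coef = 1.0 - 2.0 * ap  # +1 posterior, -1 frontal

        x = p.pink_rms * _pink_noise(n, fs, rng)
        x += p.white_rms * rng.standard_normal(n)
        x += p.delta_rms * env["SWS"] * _band_noise(n, fs, *p.delta_band, rng)

        sp_env = env["SWS"].astype(np.float64)
        if ("isa", "spindle") in cpl:
            sp_env = sp_env * _coupling_factor(cpl[("isa", "spindle")], isa_phase, env)
        x += p.spindle_rms * sp_env * _band_noise(n, fs, *p.spindle_band, rng)

        x += p.gamma_rms * _band_noise(n, fs, *p.gamma_band, rng)
        hg_band = p.high_gamma_band or (90.0, min(200.0, 0.45 * fs))
        hg_env = 1.0 - (1.0 - p.rear_suppression) * env_rear
        if ("theta", "high_gamma") in cpl:
            hg_env = hg_env * _coupling_factor(cpl[("theta", "high_gamma")], theta_phase, env)
        x += p.high_gamma_rms * hg_env * _band_noise(n, fs, *hg_band, rng)

        depth_scale = 1.0
        if p.coupling_ap_gradient is not None:
            lo, hi = p.coupling_ap_gradient
            depth_scale = lo + (hi - lo) * ap
            x += depth_scale * theta_sig + (1 - depth_scale) * p.theta_amp * (
                env["REM"] + env["AwT"]
            ) * np.cos(theta_phase)
        else:
            x += theta_sig
        x += isa_sig + hvs_sig + ap_coef * hvs_bump
        out[ch] = x
    return out


# ---------------------------------------------------------------------------
# Motion synthesis
# ---------------------------------------------------------------------------


def _fold(p, lo, hi):
    period = 2 * (hi - lo)
    q = np.mod(p - lo, period)
    return lo + np.minimum(q, period - q)


def generate_motion(
    truth: GroundTruth,
    fs: float = 120.0,
    seed: int | None = None,
    arena: float = 1000.0,
    base_z: float = 40.0,
    speed_mean: float = 250.0,
    speed_sd: float = 45.0,
    speed_tau: float = 2.0,
    jitter_mm: float = 1.0,
) -> MotionTrack:
    """3D head trajectory consistent with the planted motor schedule.

    Active bouts follow a correlated random walk whose speed is an
    Ornstein-Uhlenbeck process around ``speed_mean`` mm/s (clipped well
    above the 100 mm/s threshold); inactive periods are stationary with
    low-passed millimetre jitter; rears are smooth z excursions with the
    planted peak heights, placed only inside active periods.
    """
    seed = truth.seed if seed is None else seed
    rng = np.random.default_rng([seed, 104729])
    n = int(round(truth.duration * fs))
    dt = 1.0 / fs
    t = np.arange(n) * dt

    act = _envelope(truth.motor["active"], n, fs, ramp=1.0)

    a = np.exp(-dt / speed_tau)
    innov = rng.standard_normal(n) * speed_sd * np.sqrt(1 - a * a)
    speed = lfilter([1.0], [1.0, -a], innov) + speed_mean
    speed = np.clip(speed, 120.0, None)
    heading = np.cumsum(rng.standard_normal(n) * 1.5 * np.sqrt(dt))
    vx = speed * np.cos(heading) * act
    vy = speed * np.sin(heading) * act

    x = arena / 2 + np.cumsum(vx) * dt
    y = arena / 2 + np.cumsum(vy) * dt
    x = _fold(x, 30.0, arena - 30.0)
    y = _fold(y, 30.0, arena - 30.0)

    x += jitter_mm * _band_noise(n, fs, 0.02, 1.0, rng)
    y += jitter_mm * _band_noise(n, fs, 0.02, 1.0, rng)
    z = base_z + 5.0 * _band_noise(n, fs, 0.02, 1.0, rng)

    for r in truth.rears:
        i0 = max(int(r.onset * fs), 0)
        i1 = min(int(r.offset * fs) + 1, n)
        tau = t[i0:i1] - r.onset
        z[i0:i1] += (r.peak_height - base_z) * np.sin(np.pi * np.clip(tau / r.duration, 0, 1)) ** 2
    z = np.maximum(z, 0.0)

    return MotionTrack(t=t, xyz=np.c_[x, y, z], fs=fs)


# ---------------------------------------------------------------------------
# Transistor + headstage forward model
# ---------------------------------------------------------------------------


@dataclass
class SensorModel:
    """Transfer-curve shape, noise and headstage parameters.

    The stationary curve is a smooth symmetric V around the CNP:
    I(V) = I_min + V_ds*g_sat*w*[sp(u) + sp(-u) - 2 sp(0)], u = (V-CNP)/w,
    with softplus sp, so the transconductance saturates at +-V_ds*g_sat.
    The CNP drifts as a saturating exponential (50 mV total over ~24 h,
    ~20 mV/h initial rate).  The headstage offers a wideband DC path with
    coarse quantisation and an AC path high-passed at 0.15 Hz with finer
    quantisation.
    """

    v_cnp0: float = 0.3
    width: float = 0.05
    g_sat: float = 2e-3  # S/V; median in-vitro transconductance scale
    i_min: float = 50e-6
    v_ds: float = 0.05
    v_gs_bias: float = 0.2  # 100 mV on the hole branch
    pink_ids_rms: float = 2e-10
    pink_knee: float = 0.01  # 1/f holds down to this frequency
    white_ids_rms: float = 2e-11
    drift_total: float = 0.05
    drift_tau: float = 9000.0  # s; total/tau ~ 20 mV/h initial rate
    ac_highpass: float = 0.15
    lsb_dc: float = 2e-10
    lsb_ac: float = 2e-11
    include_drift: bool = True

    def ids(self, vgs, t: float = 0.0):
        u = (np.asarray(vgs, dtype=float) - self.v_cnp(t)) / self.width
        sp = np.logaddexp(0.0, u) + np.logaddexp(0.0, -u) - 2 * np.log(2.0)
        return self.i_min + self.v_ds * self.g_sat * self.width * sp

    def v_cnp(self, t):
        if not self.include_drift:
            return self.v_cnp0
        return self.v_cnp0 + self.drift_total * (1 - np.exp(-np.asarray(t) / self.drift_tau))

    def Gm(self, vgs, t: float = 0.0):
        u = (np.asarray(vgs, dtype=float) - self.v_cnp(t)) / self.width
        return self.v_ds * self.g_sat * np.tanh(u / 2)

    def sweep(self, t: float, rng=None, n_points: int = 61, span: tuple[float, float] = (0.0, 0.6)):
        vgs = np.linspace(*span, n_points)
        ids = self.ids(vgs, t)
        if rng is not None:
            ids = ids + 2e-9 * rng.standard_normal(n_points)
        return vgs, ids


def _quantize(x, lsb):
    return np.round(x / lsb) * lsb


def sensor_forward(
    gate_traces: np.ndarray,
    fs: float,
    model: SensorModel | None = None,
    seed: int = 0,
    sweep_times: tuple[float, ...] = (0.0,),
    dc_channels: np.ndarray | None = None,
    motion: MotionTrack | None = None,
    geometry: ArrayGeometry | None = None,
    truth: GroundTruth | None = None,
) -> Session:
    """Transduce gate-voltage traces through the transistor + headstage.

    I_ds(t) = curve(V_bias + V_sig(t) + drift(t)) + 1/f + white current
    noise; DC channels keep the full band with coarse quantisation, AC
    channels pass a causal first-order 0.15 Hz high-pass with finer
    quantisation.  Transfer sweeps are emitted at ``sweep_times``.
    """
    model = model or SensorModel()
    gate = np.atleast_2d(np.asarray(gate_traces, dtype=float))
    n_ch, n = gate.shape
    t = np.arange(n) / fs
    drift = model.v_cnp(t) - model.v_cnp0 if model.include_drift else 0.0
    if dc_channels is None:
        mask = np.zeros(n_ch, dtype=bool)
        mask[: min(8, n_ch)] = True
    else:
        mask = np.asarray(dc_channels, dtype=bool)
    b, a = butter(1, model.ac_highpass, btype="highpass", fs=fs)
    traces = np.empty_like(gate)
    sweeps = []
    for ch in range(n_ch):
        rng = np.random.default_rng([seed, 15485863, ch])
        # CNP drift moves the curve, i.e. the operating point slides by -drift
        v = model.v_gs_bias + gate[ch] - drift
        ids = model.ids(v)  # stationary curve at the initial CNP
        ids = ids + model.pink_ids_rms * _pink_noise(n, fs, rng, f_knee=model.pink_knee)
        ids = ids + model.white_ids_rms * rng.standard_normal(n)
        if mask[ch]:
            traces[ch] = _quantize(ids, model.lsb_dc)
        else:
            traces[ch] = _quantize(lfilter(b, a, ids - ids[0]), model.lsb_ac)
        for st in sweep_times:
            vgs, isw = model.sweep(st, rng)
            sweeps.append(TransferSweep(channel=ch, timestamp=float(st), vgs=vgs, ids=isw))
    if geometry is None and n_ch in (64,):
        geometry = ArrayGeometry.grid(8, 8)
    return Session(
        ids_traces=traces,
        fs_ephys=fs,
        bias=(model.v_ds, model.v_gs_bias),
        dc_channel_mask=mask,
        sweeps=sweeps,
        motion=motion,
        geometry=geometry,
        truth_json=truth.to_json() if truth is not None else None,
    )


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


def generate_session(
    duration: float = 1800.0,
    seed: int = 0,
    fs: float = 250.0,
    fs_motion: float = 120.0,
    n_channels: int = 64,
    n_dc: int = 8,
    state_kwargs: dict | None = None,
    lfp_params: LfpParams | None = None,
    sensor: SensorModel | None = None,
    sweep_times: tuple[float, ...] = (0.0,),
) -> tuple[Session, GroundTruth]:
    """Full synthetic session: schedule -> LFP -> sensor -> container."""
    kw = dict(state_kwargs or {})
    if duration < DAY and "n_cycles" not in kw:
        # scale the schedule down proportionally for short test sessions
        scale = duration / DAY
        kw.setdefault("n_cycles", max(2, int(round(72 * scale))))
        for key, full in (
            ("n_rem", 44), ("n_hvs_imm", 566), ("n_hvs_rem", 92), ("n_rears", 163)
        ):
            kw.setdefault(key, max(2, int(round(full * scale))))
        kw["n_rem"] = min(kw["n_rem"], kw["n_cycles"])
    truth = generate_states(duration=duration, seed=seed, **kw)
    geometry = ArrayGeometry.grid(8, 8) if n_channels == 64 else None
    gate = generate_lfp(truth, fs=fs, n_channels=n_channels, params=lfp_params, geometry=geometry)
    motion = generate_motion(truth, fs=fs_motion)
    dc = np.zeros(n_channels, dtype=bool)
    dc[:n_dc] = True
    session = sensor_forward(
        gate, fs, model=sensor, seed=seed, sweep_times=sweep_times,
        dc_channels=dc, motion=motion, geometry=geometry, truth=truth,
    )
    return session, truth


def reference_day(seed: int = 0, duration: float = DAY, fs: float = 250.0, fs_motion: float = 120.0):
    """The reference 24-h fixture at desk scale: one LFP reference channel
    (serving as both the theta and the HVS channel) plus the motion track.

    Returns ``(lfp, fs, motion, truth)`` with ``lfp`` of shape (1, n) in
    volts.  The schedule defaults plant the reference event totals.
    """
    truth = generate_states(duration=duration, seed=seed)
    lfp = generate_lfp(truth, fs=fs, n_channels=1)
    motion = generate_motion(truth, fs=fs_motion)
    return lfp, fs, motion, truth
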