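"""Session container and versioned HDF5 reader/writer.

A :class:`Session` holds everything one recording needs downstream:
drain-source current traces per transistor channel, the transfer-curve
sweeps used for calibration, bias settings, the DC-coupled channel mask,
the optional 3D head-motion track and the array geometry.

HDF5 layout (schema version 1):

    /ephys/ids        (n_channels, n_samples) drain-source current [A]
    /ephys/fs         scalar sampling rate [Hz]
    /calib/sweeps/<k> group per sweep: vgs [V], ids [A]; attrs channel, timestamp [s]
    /bias             (v_ds, v_gs) [V]
    /dc_mask          boolean per channel
    /motion/txyz      (n, 4) columns t [s], x, y, z [mm]; attr fs [Hz]
    /geometry         channel_rc (n_channels, 2); attrs n_rows, n_cols, ap_axis
    /truth/...        optional ground-truth payload (opaque JSON string)

All numeric fields are stored losslessly at their native dtype.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .behavior import MotionTrack

__all__ = [
    "SCHEMA_VERSION",
    "SchemaError",
    "SessionValidationError",
    "ArrayGeometry",
    "TransferSweep",
    "Session",
    "read_session",
    "write_session",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class SchemaError(Exception):
    """A required dataset or attribute is missing from the file."""


class SessionValidationError(Exception):
    """The session content violates an invariant."""


@dataclass(frozen=True)
class ArrayGeometry:
    """Grid placement of the transistor channels (8x8 in the reference design).

    ``channel_rc[c]`` gives (row, col) of channel ``c``; the map must be a
    bijection onto occupied grid cells.  ``ap_axis`` says which grid axis
    runs anterior-to-posterior ('rows' or 'cols').
    """

    n_rows: int
    n_cols: int
    channel_rc: np.ndarray
    ap_axis: str = "rows"

    def __post_init__(self):
        rc = np.asarray(self.channel_rc, dtype=int)
        object.__setattr__(self, "channel_rc", rc)
        if rc.ndim != 2 or rc.shape[1] != 2:
            raise SessionValidationError("channel_rc must have shape (n_channels, 2)")
        if rc.min() < 0 or rc[:, 0].max() >= self.n_rows or rc[:, 1].max() >= self.n_cols:
            raise SessionValidationError("channel placed outside the grid")
        cells = {tuple(x) for x in rc}
        if len(cells) != rc.shape[0]:
            raise SessionValidationError("channel->cell map is not injective")
        if self.ap_axis not in ("rows", "cols"):
            raise SessionValidationError("ap_axis must be 'rows' or 'cols'")

    @property
    def n_channels(self) -> int:
        return self.channel_rc.shape[0]

    @classmethod
    def grid(cls, n_rows: int = 8, n_cols: int = 8, ap_axis: str = "rows") -> "ArrayGeometry":
        """Dense row-major grid: channel c at (c // n_cols, c % n_cols)."""
        ch = np.arange(n_rows * n_cols)
        rc = np.c_[ch // n_cols, ch % n_cols]
        return cls(n_rows, n_cols, rc, ap_axis)

    def ap_position(self, channel: int) -> float:
        """Anterio-posterior coordinate of a channel, normalised to [0, 1]."""
        r, c = self.channel_rc[channel]
        if self.ap_axis == "rows":
            return r / max(self.n_rows - 1, 1)
        return c / max(self.n_cols - 1, 1)

    def to_grid(self, values, fill=np.nan) -> np.ndarray:
        """Scatter one value per channel onto the physical grid."""
        values = np.asarray(values, dtype=float)
        if values.size != self.n_channels:
            raise SessionValidationError(
                f"got {values.size} values for {self.n_channels} channels"
            )
        out = np.full((self.n_rows, self.n_cols), fill, dtype=float)
        out[self.channel_rc[:, 0], self.channel_rc[:, 1]] = values
        return out


@dataclass
class TransferSweep:
    """One stationary I_ds-V_gs sweep of one channel, with its timestamp."""

    channel: int
    timestamp: float
    vgs: np.ndarray
    ids: np.ndarray

    def __post_init__(self):
        self.vgs = np.asarray(self.vgs, dtype=float)
        self.ids = np.asarray(self.ids, dtype=float)
        if self.vgs.size != self.ids.size:
            raise SessionValidationError("sweep vgs and ids lengths differ")


@dataclass
class Session:
    """One recording session (SI units internally: A, V, s, Hz; motion in mm)."""

    ids_traces: np.ndarray  # (n_channels, n_samples), drain-source current [A]
    fs_ephys: float
    bias: tuple[float, float]  # (V_ds, V_gs)
    dc_channel_mask: np.ndarray
    sweeps: list[TransferSweep] = field(default_factory=list)
    motion: MotionTrack | None = None
    geometry: ArrayGeometry | None = None
    n_dc_declared: int | None = None
    truth_json: str | None = None

    def __post_init__(self):
        self.ids_traces = np.asarray(self.ids_traces)
        if self.ids_traces.ndim != 2:
            raise SessionValidationError("ids_traces must be 2D (channels, samples)")
        if self.fs_ephys <= 0:
            raise SessionValidationError("fs_ephys must be positive")
        self.dc_channel_mask = np.asarray(self.dc_channel_mask, dtype=bool)
        if self.dc_channel_mask.size != self.n_channels:
            raise SessionValidationError("dc_channel_mask length != n_channels")
        if self.n_dc_declared is None:
            self.n_dc_declared = int(self.dc_channel_mask.sum())
        elif int(self.dc_channel_mask.sum()) != self.n_dc_declared:
            raise SessionValidationError(
                f"dc_channel_mask has {int(self.dc_channel_mask.sum())} DC channels, "
                f"metadata declares {self.n_dc_declared}"
            )
        if self.geometry is not None and self.geometry.n_channels != self.n_channels:
            raise SessionValidationError("geometry channel count != n_channels")

    @property
    def n_channels(self) -> int:
        return self.ids_traces.shape[0]

    @property
    def duration(self) -> float:
        return self.ids_traces.shape[1] / self.fs_ephys


def write_session(session: Session, path) -> None:
    """Write a session to HDF5, losslessly for all numeric fields."""
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["n_dc_declared"] = session.n_dc_declared
        g = f.create_group("ephys")
        d = g.create_dataset("ids", data=session.ids_traces)
        d.attrs["units"] = "A"
        g.create_dataset("fs", data=float(session.fs_ephys)).attrs["units"] = "Hz"
        f.create_dataset("bias", data=np.asarray(session.bias, dtype=float)).attrs[
            "units"
        ] = "V"
        f.create_dataset("dc_mask", data=session.dc_channel_mask)
        calib = f.create_group("calib/sweeps")
        for k, sw in enumerate(session.sweeps):
            sg = calib.create_group(str(k))
            sg.create_dataset("vgs", data=sw.vgs).attrs["units"] = "V"
            sg.create_dataset("ids", data=sw.ids).attrs["units"] = "A"
            sg.attrs["channel"] = sw.channel
            sg.attrs["timestamp"] = sw.timestamp
        if session.motion is not None:
            m = session.motion
            txyz = np.c_[m.t, m.xyz]
            mg = f.create_group("motion")
            md = mg.create_dataset("txyz", data=txyz)
            md.attrs["units"] = "s,mm,mm,mm"
            md.attrs["fs"] = m.fs
            mg.create_dataset("gap_mask", data=m.gap_mask)
        if session.geometry is not None:
            geo = session.geometry
            gg = f.create_group("geometry")
            gg.create_dataset("channel_rc", data=geo.channel_rc)
            gg.attrs["n_rows"] = geo.n_rows
            gg.attrs["n_cols"] = geo.n_cols
            gg.attrs["ap_axis"] = geo.ap_axis
        if session.truth_json is not None:
            f.create_dataset("truth/json", data=session.truth_json)


def _require(f, name):
    if name not in f:
        raise SchemaError(f"missing required dataset or group: {name}")
    return f[name]


def read_session(path) -> Session:
    """Read an HDF5 session written by :func:`write_session`."""
    with h5py.File(path, "r") as f:
        if "schema_version" not in f.attrs:
            raise SchemaError("file does not declare a schema_version")
        ids = _require(f, "ephys/ids")[()]
        fs = float(_require(f, "ephys/fs")[()])
        if fs <= 0:
            raise SessionValidationError("fs_ephys must be positive")
        bias = tuple(_require(f, "bias")[()])
        dc_mask = _require(f, "dc_mask")[()].astype(bool)
        sweeps = []
        if "calib/sweeps" in f:
            grp = f["calib/sweeps"]
            for k in sorted(grp, key=int):
                sg = grp[k]
                sweeps.append(
                    TransferSweep(
                        channel=int(sg.attrs["channel"]),
                        timestamp=float(sg.attrs["timestamp"]),
                        vgs=sg["vgs"][()],
                        ids=sg["ids"][()],
                    )
                )
        motion = None
        if "motion" in f:
            txyz = f["motion/txyz"][()]
            gap = f["motion/gap_mask"][()].astype(bool) if "motion/gap_mask" in f else None
            if txyz.shape[0] > 0:
                motion = MotionTrack(
                    t=txyz[:, 0],
                    xyz=txyz[:, 1:4],
                    fs=float(f["motion/txyz"].attrs["fs"]),
                    gap_mask=gap,
                )
            else:
                log.warning("motion group present but empty in %s", path)
        else:
            log.warning("session %s has no motion group", path)
        geometry = None
        if "geometry" in f:
            gg = f["geometry"]
            geometry = ArrayGeometry(
                n_rows=int(gg.attrs["n_rows"]),
                n_cols=int(gg.attrs["n_cols"]),
                channel_rc=gg["channel_rc"][()],
                ap_axis=str(gg.attrs["ap_axis"]),
            )
        truth = f["truth/json"][()].decode() if "truth/json" in f else None
        n_dc = int(f.attrs["n_dc_declared"]) if "n_dc_declared" in f.attrs else None
    return Session(
        ids_traces=ids,
        fs_ephys=fs,
        bias=bias,
        dc_channel_mask=dc_mask,
        sweeps=sweeps,
        motion=motion,
        geometry=geometry,
        n_dc_declared=n_dc,
        truth_json=truth,
    )
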