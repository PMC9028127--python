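"""Session and maneuver containers, file schema, and grid normalization.

A *maneuver* is one forced expiration: a uniform time grid (canonically
0.01 s), cumulative exhaled volume (L, BTPS), and expiratory flow (L/s,
positive during expiration, negative during inspiration).  A *session*
groups the one-to-several maneuvers of a single test occasion.

The on-disk schema is a structured JSON document, one session per file::

    {
      "session_id": "s001",
      "subject_age": 54,            // optional, years
      "maneuvers": [
        {
          "maneuver_id": "m1",
          "sample_interval": 0.01,
          "volume": [0.0, 0.05, ...],   // liters, cumulative
          "flow":   [5.0, 5.0,  ...]    // L/s, optional
        }
      ]
    }

Time is implicit (``i * sample_interval``, starting at 0).  This schema is
a vendor-neutral reconstruction of the numeric intermediate form that
spirometer reports reduce to; no vendor PDF or binary format is parsed
here.  A two-column CSV import (time, volume) per maneuver is also
provided, resampled onto the canonical grid.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.ndimage import uniform_filter1d

from .errors import InputError, ParseError, SchemaError

#: canonical sampling interval, seconds
SAMPLE_INTERVAL = 0.01
#: tolerance on grid uniformity, seconds
GRID_TOL = 1e-9


def smooth(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge replication."""
    if window <= 1:
        return np.asarray(x, dtype=float)
    return uniform_filter1d(np.asarray(x, dtype=float), size=int(window),
                            mode="nearest")


@dataclass
class Maneuver:
    """One forced-expiration recording on a uniform time grid."""

    maneuver_id: str
    t: np.ndarray
    volume: np.ndarray
    flow: np.ndarray
    sample_interval: float = SAMPLE_INTERVAL

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.volume = np.asarray(self.volume, dtype=float)
        self.flow = np.asarray(self.flow, dtype=float)

    @property
    def duration(self) -> float:
        """Record length from first to last sample, seconds."""
        return float(self.t[-1] - self.t[0])

    def validate(self, flow_tol: float = 0.05, warn_only: bool = True) -> None:
        """Check the container invariants; raise :class:`SchemaError`.

        The flow-vs-dV/dt consistency check only warns by default: when a
        device exports both channels the flow channel wins, and finite
        differencing of volume amplifies noise.
        """
        n = len(self.t)
        if not (n == len(self.volume) == len(self.flow)):
            raise SchemaError(
                f"maneuver {self.maneuver_id!r}: t/volume/flow lengths differ "
                f"({n}/{len(self.volume)}/{len(self.flow)})")
        if n < 2:
            raise SchemaError(
                f"maneuver {self.maneuver_id!r}: needs >= 2 samples, got {n}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise SchemaError(
                f"maneuver {self.maneuver_id!r}: field t is not strictly "
                "increasing")
        if np.max(np.abs(dt - self.sample_interval)) > GRID_TOL:
            raise SchemaError(
                f"maneuver {self.maneuver_id!r}: field t is not a uniform "
                f"grid at sample_interval={self.sample_interval}")
        if self.volume[0] < 0:
            raise SchemaError(
                f"maneuver {self.maneuver_id!r}: field volume starts below 0")
        dv = np.gradient(self.volume, self.sample_interval)
        diff = np.abs(smooth(self.flow, 5) - smooth(dv, 5))
        # boundary samples use one-sided differences and are biased on any
        # curved record; judge consistency on the interior only
        core = diff[5:-5] if n > 12 else diff
        mismatch = float(np.max(core)) if len(core) else 0.0
        if mismatch > flow_tol:
            msg = (f"maneuver {self.maneuver_id!r}: flow deviates from dV/dt "
                   f"by up to {mismatch:.3f} L/s (tolerance {flow_tol})")
            if warn_only:
                warnings.warn(msg, stacklevel=2)
            else:
                raise SchemaError(msg)


@dataclass
class Session:
    """An ordered collection of maneuvers from one test occasion."""

    session_id: str
    maneuvers: list = field(default_factory=list)
    subject_age: Optional[float] = None

    def validate(self) -> None:
        if not self.maneuvers:
            raise SchemaError(
                f"session {self.session_id!r}: field maneuvers is empty")
        ids = [m.maneuver_id for m in self.maneuvers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise SchemaError(
                f"session {self.session_id!r}: duplicated maneuver_id {dup}")
        for m in self.maneuvers:
            m.validate()


def resample_to_grid(t: Sequence[float], volume: Sequence[float],
                     maneuver_id: str = "m",
                     sample_interval: float = SAMPLE_INTERVAL) -> Maneuver:
    """Interpolate a (time, volume) series onto the canonical grid.

    Monotone cubic (PCHIP) interpolation is used: it is shape-preserving on
    monotone volume data and accurate enough that coarsely sampled smooth
    curves (e.g. 0.05-s exports) land within ~1e-4 L of the underlying
    curve, where linear interpolation would err by several mL.  Flow is the
    centered finite difference of the resampled volume (one-sided at the
    boundaries).  Input already on the canonical grid passes through
    unchanged (the interpolant reproduces its nodes).
    """
    t = np.asarray(t, dtype=float)
    volume = np.asarray(volume, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise InputError("resample_to_grid: need >= 2 (t, volume) points")
    if len(t) != len(volume):
        raise InputError("resample_to_grid: t and volume lengths differ")
    if np.any(np.diff(t) <= 0):
        raise InputError("resample_to_grid: t must be strictly increasing")
    n = int(np.floor((t[-1] - t[0]) / sample_interval + GRID_TOL)) + 1
    grid = t[0] + sample_interval * np.arange(n)
    on_grid = (len(t) == n
               and np.max(np.abs(t - grid)) <= GRID_TOL)
    if on_grid:
        vol = volume.copy()
    else:
        vol = PchipInterpolator(t, volume)(grid)
    flow = np.gradient(vol, sample_interval)
    return Maneuver(maneuver_id=maneuver_id, t=grid, volume=vol, flow=flow,
                    sample_interval=sample_interval)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def _require(doc: dict, field_name: str, ctx: str):
    if field_name not in doc:
        raise ParseError(f"{ctx}: missing required field {field_name!r}")
    return doc[field_name]


def _maneuver_from_doc(doc: dict, ctx: str) -> Maneuver:
    mid = _require(doc, "maneuver_id", ctx)
    dt = float(doc.get("sample_interval", SAMPLE_INTERVAL))
    if dt <= 0:
        raise ParseError(f"{ctx}: field sample_interval must be > 0")
    volume = _require(doc, "volume", f"{ctx} maneuver {mid!r}")
    try:
        volume = np.asarray(volume, dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(
            f"{ctx} maneuver {mid!r}: field volume is not numeric") from exc
    if volume.ndim != 1 or len(volume) < 2:
        raise ParseError(
            f"{ctx} maneuver {mid!r}: field volume needs >= 2 samples")
    t = dt * np.arange(len(volume))
    if "flow" in doc and doc["flow"] is not None:
        try:
            flow = np.asarray(doc["flow"], dtype=float)
        except (TypeError, ValueError) as exc:
            raise ParseError(
                f"{ctx} maneuver {mid!r}: field flow is not numeric") from exc
        if len(flow) != len(volume):
            raise ParseError(
                f"{ctx} maneuver {mid!r}: fields flow and volume have "
                "different lengths")
    else:
        # reconstruct the flow channel by differentiation
        flow = np.gradient(volume, dt)
    return Maneuver(maneuver_id=str(mid), t=t, volume=volume, flow=flow,
                    sample_interval=dt)


def read_session(path) -> Session:
    """Read and validate one session document (JSON schema above)."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: not a valid JSON document ({exc})") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: top level must be an object")
    sid = str(_require(doc, "session_id", str(path)))
    age = doc.get("subject_age")
    if age is not None:
        age = float(age)
    mans = _require(doc, "maneuvers", str(path))
    if not isinstance(mans, list):
        raise ParseError(f"{path}: field maneuvers must be a list")
    session = Session(
        session_id=sid,
        subject_age=age,
        maneuvers=[_maneuver_from_doc(m, str(path)) for m in mans],
    )
    session.validate()
    return session


def write_session(session: Session, path) -> None:
    """Write a session document; round-trips losslessly through JSON floats."""
    session.validate()
    doc = {
        "session_id": session.session_id,
        "subject_age": session.subject_age,
        "maneuvers": [
            {
                "maneuver_id": m.maneuver_id,
                "sample_interval": m.sample_interval,
                "volume": [float(v) for v in m.volume],
                "flow": [float(f) for f in m.flow],
            }
            for m in session.maneuvers
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True)
        fh.write("\n")


def read_maneuver_csv(path, maneuver_id: Optional[str] = None) -> Maneuver:
    """Import one maneuver from a two-column (time, volume) CSV file.

    A single header row is tolerated; the series is resampled onto the
    canonical 0.01-s grid and flow is reconstructed by differentiation.
    """
    t, v = [], []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip():
                continue
            try:
                ti, vi = float(row[0]), float(row[1])
            except (ValueError, IndexError):
                if not t:
                    continue  # header row
                raise ParseError(f"{path}: malformed CSV row {row!r}")
            t.append(ti)
            v.append(vi)
    if len(t) < 2:
        raise ParseError(f"{path}: need >= 2 data rows")
    mid = maneuver_id if maneuver_id is not None else "m1"
    return resample_to_grid(t, v, maneuver_id=mid)
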