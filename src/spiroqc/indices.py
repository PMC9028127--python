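"""Quantitative spirometric indices.

Implements the numeric primitives behind the ATS/ERS 2019 acceptability
rules: back-extrapolated time zero and volume (BEV), FEV1, FVC, PEF, time
to peak flow, forced expiratory time, the end-of-test volume plateau, and
the three-way end-of-forced-expiration (EOFE) rule.

Conventions
-----------
* Time zero of the maneuver (t0) is found by extending the tangent with
  the maximal smoothed slope of the volume-time curve down to V = 0; BEV
  is the volume already exhaled at t0.
* FEV1 is the volume exhaled between t0 and t0 + 1 s (linear
  interpolation on the 0.01-s grid); it is ``None`` when the record ends
  before t0 + 1 s.
* End of expiration (for FET) is the last sample whose smoothed flow
  exceeds a zero-flow floor, before any sustained inspiratory segment; the
  floor avoids FET inflation by sensor drift.
* The plateau test examines trailing 1-s volume changes over the recorded
  expiration (up to a sustained inspiration, if any), not just up to the
  flow floor: a subject may hold a true plateau at near-zero flow well
  past the floor crossing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .config import DEFAULT_CONFIG, QCConfig
from .errors import DegenerateManeuverError, InputError
from .session import Maneuver, smooth


@dataclass
class SpirometryIndices:
    """Derived per-maneuver quantities (times absolute on the record grid)."""

    t0: float                      #: back-extrapolated time zero, s
    bev: float                     #: back-extrapolated volume, L
    fev1: Optional[float]          #: L; None if record ends before t0 + 1 s
    fvc: float                     #: L
    pef: float                     #: L/s
    tpef: float                    #: s from t0 to peak flow
    fet: float                     #: s from t0 to end of expiration
    t_end: float                   #: absolute end-of-expiration time, s
    plateau: bool
    plateau_onset: Optional[float]  #: absolute time, s; None if no plateau
    eofe_met: bool                 #: plateau or long-FET branch (session
    #: repeatability branch is resolved later by the qc module)
    duration: float                #: record length, s


def _expiration_cutoff(m: Maneuver, config: QCConfig) -> int:
    """Index of the last sample before any sustained inspiratory segment."""
    fs = smooth(m.flow, config.smooth_window)
    i_peak = int(np.argmax(m.flow))
    neg = fs < -config.zero_flow_floor
    n_sustain = max(1, int(round(config.neg_sustain / m.sample_interval)))
    run = 0
    for i in range(i_peak, len(fs)):
        run = run + 1 if neg[i] else 0
        if run >= n_sustain:
            return i - n_sustain  # last index before the inspiration began
    return len(fs) - 1


def back_extrapolate(m: Maneuver,
                     config: QCConfig = DEFAULT_CONFIG
                     ) -> Tuple[float, float]:
    """Back-extrapolated time zero and volume.

    The tangent at the point of maximal smoothed volume slope is extended
    to V = 0; its time intercept is t0 (clamped to the record start) and
    the measured volume at t0 is the BEV.
    """
    dv = np.gradient(m.volume, m.sample_interval)
    s = smooth(dv, config.smooth_window)
    k = int(np.argmax(s))
    smax = float(s[k])
    if smax <= 0:
        raise DegenerateManeuverError(
            f"maneuver {m.maneuver_id!r}: no positive volume slope")
    t0 = float(m.t[k] - m.volume[k] / smax)
    t0 = max(t0, float(m.t[0]))
    bev = float(np.interp(t0, m.t, m.volume))
    return t0, bev


def detect_plateau(m: Maneuver,
                   config: QCConfig = DEFAULT_CONFIG
                   ) -> Tuple[bool, Optional[float]]:
    """End-of-test volume plateau.

    plateau is True iff the exhaled volume changes by at most
    ``plateau_dv`` (default 0.025 L) over the final ``plateau_window``
    (default 1 s) of the recorded expiration.  The onset is the earliest
    time from which every trailing window change stays within the
    threshold; onset times refer to the *end* of the trailing window.
    Records shorter than the window return (False, None).
    """
    dt = m.sample_interval
    i_cut = _expiration_cutoff(m, config)
    k = int(round(config.plateau_window / dt))
    if i_cut < k:
        return False, None
    v = m.volume[: i_cut + 1]
    d = v[k:] - v[:-k]            # trailing-window change ending at i >= k
    thr = config.plateau_dv + 1e-12
    if d[-1] > thr:
        return False, None
    # earliest suffix where all trailing-window changes comply
    bad = np.nonzero(d > thr)[0]
    first_ok = (bad[-1] + 1) if len(bad) else 0
    return True, float(m.t[first_ok + k])


def compute_indices(m: Maneuver,
                    config: QCConfig = DEFAULT_CONFIG) -> SpirometryIndices:
    """Compute all per-maneuver indices. See the module docstring."""
    m.validate()
    t0, bev = back_extrapolate(m, config)
    dt = m.sample_interval
    fs = smooth(m.flow, config.smooth_window)
    i_cut = _expiration_cutoff(m, config)

    # end of expiration: last sample above the zero-flow floor
    above = np.nonzero(fs[: i_cut + 1] > config.zero_flow_floor)[0]
    if len(above) == 0:
        raise DegenerateManeuverError(
            f"maneuver {m.maneuver_id!r}: flow never exceeds the zero-flow "
            "floor")
    t_end = float(m.t[above[-1]])
    fet = t_end - t0
    if fet < dt:
        raise DegenerateManeuverError(
            f"maneuver {m.maneuver_id!r}: FET below one sample interval")

    vol0 = float(np.interp(t0, m.t, m.volume))
    fvc = float(np.max(m.volume[: i_cut + 1])) - vol0
    in_exp = (m.t >= t0 - 1e-12) & (m.t <= t_end + 1e-12)
    flow_exp = np.where(in_exp, m.flow, -np.inf)
    i_pef = int(np.argmax(flow_exp))
    pef = float(m.flow[i_pef])
    tpef = float(m.t[i_pef]) - t0

    if t0 + 1.0 <= m.t[-1] + 1e-9:
        fev1 = float(np.interp(t0 + 1.0, m.t, m.volume)) - vol0
    else:
        fev1 = None

    plateau, onset = detect_plateau(m, config)
    return SpirometryIndices(
        t0=t0, bev=bev, fev1=fev1, fvc=fvc, pef=pef, tpef=tpef, fet=fet,
        t_end=t_end, plateau=plateau, plateau_onset=onset,
        eofe_met=plateau or fet >= config.fet_long,
        duration=float(m.t[-1]),
    )


def eofe_met(indices: SpirometryIndices,
             best_fvc_delta: Optional[float] = None,
             config: QCConfig = DEFAULT_CONFIG) -> bool:
    """Three-way end-of-forced-expiration rule.

    True iff a plateau was reached, or FET >= ``fet_long`` (default 15 s),
    or the maneuver's FVC is within ``fvc_repeat_tol`` (default 0.150 L)
    of the session's best FVC (``best_fvc_delta``, supplied by the caller
    when session context exists).
    """
    if indices.plateau or indices.fet >= config.fet_long:
        return True
    return (best_fvc_delta is not None
            and best_fvc_delta <= config.fvc_repeat_tol + 1e-12)


def repeatability_delta(values: Sequence[float]) -> float:
    """Difference between the two largest values; 0.0 for a single value."""
    vals = [float(v) for v in values]
    if not vals:
        raise InputError("repeatability_delta: empty value list")
    if len(vals) == 1:
        return 0.0
    top = sorted(vals, reverse=True)[:2]
    return top[0] - top[1]
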