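"""Deterministic artifact detectors on flow-volume / volume-time curves.

Each detector classifies and localizes one class of maneuver anomaly from
the numeric series alone: cough (transient flow dip-and-rebound), glottic
closure (abrupt flow cessation), flutter (sustained 5-15 Hz oscillation
from an obstructed mouthpiece or device fault), early termination, extra
breath (inspiration followed by resumed expiration), and the start-of-test
problems hesitant start (excess back-extrapolated volume) and variable
flow (late peak flow).

All thresholds are fractions of a *local flow envelope* -- a running
median of the flow signal -- so detection is scale-free across subjects.
Each finding carries a unitless score in [0, 1]: the observed amplitude
expressed as a multiple of its detection threshold, mapped by
``min(1, ratio / 2)``.  The score is a documented monotone surrogate for
confidence, not a calibrated probability.

Detectors are pure functions of the input series: reproducible
bit-for-bit, and invariant to time-translation of the maneuver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d
from scipy.signal import butter, filtfilt

from .config import DEFAULT_CONFIG, QCConfig
from .indices import SpirometryIndices
from .session import Maneuver, smooth

ARTIFACT_KINDS = (
    "cough",
    "glottic_closure",
    "flutter_obstruction",
    "early_termination",
    "extra_breath",
    "hesitant_start",
    "variable_flow",
)


@dataclass(frozen=True)
class ArtifactFinding:
    """A detected anomaly with its interval on the time axis."""

    kind: str
    t_start: float
    t_end: float
    v_at_onset: float  #: exhaled volume at t_start, L (localizes the finding
    #: on the flow-volume representation)
    score: float       #: unitless confidence surrogate in [0, 1]

    def __post_init__(self):
        if self.kind not in ARTIFACT_KINDS:
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if not self.t_start < self.t_end:
            raise ValueError("finding interval must satisfy t_start < t_end")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")

    def overlaps(self, lo: float, hi: float) -> bool:
        return self.t_start < hi and self.t_end > lo


def _score(ratio: float) -> float:
    return float(min(1.0, max(0.0, ratio) / 2.0))


def _runs(mask: np.ndarray) -> List[Tuple[int, int]]:
    """Contiguous True runs as (start, stop) index pairs, stop inclusive."""
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        return []
    brk = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([idx[0]], idx[brk + 1]))
    stops = np.concatenate((idx[brk], [idx[-1]]))
    return list(zip(starts.tolist(), stops.tolist()))


def _envelope(flow_s: np.ndarray, dt: float, config: QCConfig) -> np.ndarray:
    size = max(3, int(round(config.envelope_window / dt)) | 1)  # odd
    return median_filter(flow_s, size=size, mode="nearest")


def _vol_at(m: Maneuver, t: float) -> float:
    return float(np.interp(t, m.t, m.volume))


def detect_cough(m: Maneuver, indices: SpirometryIndices,
                 config: QCConfig = DEFAULT_CONFIG) -> List[ArtifactFinding]:
    """Transient flow dips with fast rebound during expiration.

    A cough shows as an up-and-down flow spike: smoothed flow drops by at
    least ``cough_drop_frac`` of the local reference level and recovers by
    at least ``cough_recover_frac`` of it within ``cough_window``.

    The reference here is a short *trailing maximum* of the smoothed flow
    rather than the running median used elsewhere: on a steeply decaying
    expiration a median window long enough to bridge the dip is dragged
    down both by the dip itself and by the decay, hiding the transient.
    A trailing maximum over just over half a transient cannot be captured
    by the dip, never looks ahead (so a rising flow is never below its
    own reference), and the mandatory rebound check rejects the mild
    apparent "dips" it creates on clean monotone decay.
    """
    dt = m.sample_interval
    fs = smooth(m.flow, config.smooth_window)
    w_env = max(2, int(round(config.cough_env_window / dt)))
    padded = np.concatenate([np.full(w_env - 1, fs[0]), fs])
    env = np.max(np.lib.stride_tricks.sliding_window_view(padded, w_env),
                 axis=1)
    i0 = int(np.searchsorted(m.t, indices.t0))
    i1 = int(np.searchsorted(m.t, indices.t_end, side="right")) - 1
    depth = env - fs
    mask = np.zeros(len(fs), dtype=bool)
    mask[i0:i1 + 1] = (
        (depth[i0:i1 + 1] >= config.cough_drop_frac * env[i0:i1 + 1])
        & (env[i0:i1 + 1] >= config.cough_min_env)
    )
    w = max(1, int(round(config.cough_window / dt)))
    findings = []
    for a, b in _runs(mask):
        if (b - a) * dt > config.cough_window:
            continue  # sustained, not a transient: flutter territory
        seg = fs[a:b + 1]
        im = a + int(np.argmin(seg))
        j_hi = min(im + w, i1)
        if j_hi <= im:
            continue
        reb = fs[im:j_hi + 1]
        j_max = im + int(np.argmax(reb))
        if fs[j_max] - fs[im] < config.cough_recover_frac * env[im]:
            continue  # no rebound: not a cough
        ratio = depth[im] / (config.cough_drop_frac * env[im])
        # the run starts where the drop crosses threshold; the transient
        # itself starts up to one reference lookback earlier
        t_start = max(float(m.t[0]), float(m.t[a]) - config.cough_env_window)
        findings.append(ArtifactFinding(
            kind="cough",
            t_start=t_start,
            t_end=float(m.t[j_max]) if m.t[j_max] > t_start
                  else float(m.t[b] + dt),
            v_at_onset=_vol_at(m, t_start),
            score=_score(ratio),
        ))
    return findings


def detect_glottic_closure(m: Maneuver, indices: SpirometryIndices,
                           config: QCConfig = DEFAULT_CONFIG
                           ) -> List[ArtifactFinding]:
    """Abrupt flow cessation before a natural end of expiration.

    Flow falls from above ``gc_high_frac * PEF`` to below the zero-flow
    floor within ``gc_drop_window`` and stays there for at least
    ``gc_hold`` (or to the end of the record), with no plateau already
    established beforehand.  At most one finding is reported.
    """
    dt = m.sample_interval
    fs = smooth(m.flow, config.gc_smooth_window)
    floor = config.zero_flow_floor
    i_peak = int(np.argmax(m.flow))
    below = fs <= floor
    below[:i_peak + 1] = False
    w_drop = max(1, int(round(config.gc_drop_window / dt)))
    n_hold = max(1, int(round(config.gc_hold / dt)))
    high = config.gc_high_frac * indices.pef
    for a, b in _runs(below):
        if (b - a + 1) < n_hold and b < len(fs) - 1:
            continue  # too brief to be a cessation
        pre = fs[max(0, a - w_drop):a]
        if len(pre) == 0 or float(np.max(pre)) < high:
            continue  # gradual decay, not an abrupt drop
        if (indices.plateau and indices.plateau_onset is not None
                and indices.plateau_onset <= m.t[a]):
            continue  # expiration had already plateaued naturally
        # sharpen the onset on the raw flow channel
        a_raw = a
        while a_raw > i_peak and m.flow[a_raw - 1] <= floor:
            a_raw -= 1
        pre_flow = float(np.max(pre))
        return [ArtifactFinding(
            kind="glottic_closure",
            t_start=float(m.t[a_raw]),
            t_end=float(m.t[b]),
            v_at_onset=_vol_at(m, float(m.t[a_raw])),
            score=_score(pre_flow / high),
        )]
    return []


def detect_flutter(m: Maneuver, indices: SpirometryIndices,
                   config: QCConfig = DEFAULT_CONFIG
                   ) -> List[ArtifactFinding]:
    """Sustained band-limited (default 5-15 Hz) flow oscillation.

    The flow signal is band-passed; its oscillation amplitude (RMS tracker
    scaled to peak) must reach ``flutter_frac`` of the local envelope for
    at least ``flutter_min_dur`` seconds.
    """
    dt = m.sample_interval
    fs_nyq = 0.5 / dt
    if len(m.flow) < 30 or config.flutter_band_hi >= fs_nyq:
        return []
    b, a = butter(3, [config.flutter_band_lo / fs_nyq,
                      config.flutter_band_hi / fs_nyq], btype="bandpass")
    bp = filtfilt(b, a, m.flow)
    w_rms = max(1, int(round(config.flutter_rms_window / dt)))
    ms = np.maximum(uniform_filter1d(bp ** 2, size=w_rms, mode="nearest"),
                    0.0)
    amp = np.sqrt(2.0 * ms)
    env = _envelope(smooth(m.flow, config.smooth_window), dt, config)
    i0 = int(np.searchsorted(m.t, indices.t0))
    i1 = int(np.searchsorted(m.t, indices.t_end, side="right")) - 1
    mask = np.zeros(len(amp), dtype=bool)
    mask[i0:i1 + 1] = (
        (amp[i0:i1 + 1] >= config.flutter_frac * env[i0:i1 + 1])
        & (env[i0:i1 + 1] >= config.flutter_min_flow)
    )
    n_min = int(round(config.flutter_min_dur / dt))
    findings = []
    for a_, b_ in _runs(mask):
        if (b_ - a_ + 1) < n_min:
            continue
        ratio = float(np.mean(amp[a_:b_ + 1]
                              / (config.flutter_frac * env[a_:b_ + 1])))
        findings.append(ArtifactFinding(
            kind="flutter_obstruction",
            t_start=float(m.t[a_]),
            t_end=float(m.t[b_]),
            v_at_onset=_vol_at(m, float(m.t[a_])),
            score=_score(ratio),
        ))
    return findings


def detect_extra_breath(m: Maneuver,
                        config: QCConfig = DEFAULT_CONFIG
                        ) -> List[ArtifactFinding]:
    """Inspiratory segments followed by resumed expiration.

    Flow below ``-eb_flow`` for at least ``eb_dur`` counts as an extra
    breath only if expiratory flow later resumes (otherwise the recording
    simply ends on an inspiration).
    """
    dt = m.sample_interval
    fs = smooth(m.flow, config.smooth_window)
    mask = fs < -config.eb_flow
    n_min = max(1, int(round(config.eb_dur / dt)))
    n_resume = max(1, int(round(config.eb_resume_dur / dt)))
    resumed_from = np.zeros(len(fs), dtype=bool)
    pos = (fs >= config.eb_resume_flow).astype(int)
    # resumed_from[i]: an expiratory run of >= n_resume exists at or after i
    run = 0
    ok = np.zeros(len(fs), dtype=bool)
    for i in range(len(fs) - 1, -1, -1):
        run = run + 1 if pos[i] else 0
        ok[i] = run >= n_resume
        resumed_from[i] = ok[i] or (resumed_from[i + 1] if i + 1 < len(fs)
                                    else False)
    findings = []
    for a, b in _runs(mask):
        if (b - a + 1) < n_min:
            continue
        if b + 1 >= len(fs) or not resumed_from[b + 1]:
            continue
        ratio = float(np.max(-fs[a:b + 1])) / config.eb_flow
        findings.append(ArtifactFinding(
            kind="extra_breath",
            t_start=float(m.t[a]),
            t_end=float(m.t[b]),
            v_at_onset=_vol_at(m, float(m.t[a])),
            score=_score(ratio),
        ))
    return findings


def detect_early_termination(m: Maneuver, indices: SpirometryIndices,
                             config: QCConfig = DEFAULT_CONFIG
                             ) -> List[ArtifactFinding]:
    """Expiration stopped before any end-of-forced-expiration indicator.

    Fires when neither the plateau nor the long-FET branch of the EOFE
    rule holds (the session-level FVC-repeatability branch is resolved by
    the qc module) and no glottic closure explains the stop.  The interval
    is the final 1-s window of the expiration.
    """
    if indices.plateau or indices.fet >= config.fet_long:
        return []
    if detect_glottic_closure(m, indices, config):
        return []
    t_hi = indices.t_end
    t_lo = max(indices.t0, t_hi - 1.0, float(m.t[0]))
    if not t_lo < t_hi:
        t_lo = float(m.t[0])
    k = max(1, int(round(config.plateau_window / m.sample_interval)))
    d_last = float(m.volume[-1] - m.volume[max(0, len(m.volume) - 1 - k)])
    return [ArtifactFinding(
        kind="early_termination",
        t_start=t_lo,
        t_end=t_hi,
        v_at_onset=_vol_at(m, t_lo),
        score=_score(d_last / config.plateau_dv),
    )]


def detect_start_quality(indices: SpirometryIndices,
                         config: QCConfig = DEFAULT_CONFIG
                         ) -> List[ArtifactFinding]:
    """Start-of-test problems: hesitant start (BEV) and variable flow (tPEF).

    A hesitant start is flagged when BEV exceeds
    ``max(bev_abs, bev_frac * FVC)``; otherwise a late peak flow
    (tPEF > ``tpef_max``) is flagged as variable flow.
    """
    dt_min = 0.01
    bev_limit = max(config.bev_abs, config.bev_frac * indices.fvc)
    t_hi = indices.t0 + max(indices.tpef, dt_min)
    if indices.bev > bev_limit:
        return [ArtifactFinding(
            kind="hesitant_start",
            t_start=indices.t0,
            t_end=t_hi,
            v_at_onset=indices.bev,
            score=_score(indices.bev / bev_limit),
        )]
    if indices.tpef > config.tpef_max:
        return [ArtifactFinding(
            kind="variable_flow",
            t_start=indices.t0,
            t_end=t_hi,
            v_at_onset=indices.bev,
            score=_score(indices.tpef / config.tpef_max),
        )]
    return []


def scan_artifacts(m: Maneuver, indices: SpirometryIndices,
                   config: QCConfig = DEFAULT_CONFIG
                   ) -> List[ArtifactFinding]:
    """Union of all detectors, sorted by onset.

    Where a cough and a flutter finding overlap (a vigorous flutter can
    masquerade as repeated dips and vice versa), only the higher-scoring
    finding is kept; ties favor the cough (the briefer explanation).
    """
    coughs = detect_cough(m, indices, config)
    flutters = detect_flutter(m, indices, config)
    keep_c, keep_f = [], []
    for c in coughs:
        drop = any(f.overlaps(c.t_start, c.t_end) and f.score > c.score
                   for f in flutters)
        if not drop:
            keep_c.append(c)
    for f in flutters:
        drop = any(c.overlaps(f.t_start, f.t_end) and c.score >= f.score
                   for c in coughs)
        if not drop:
            keep_f.append(f)
    findings = (keep_c + keep_f
                + detect_glottic_closure(m, indices, config)
                + detect_extra_breath(m, config)
                + detect_early_termination(m, indices, config)
                + detect_start_quality(indices, config))
    return sorted(findings, key=lambda f: (f.t_start, f.kind))
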