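"""Physiologically shaped forced-expiration simulator with ground truth.

The clean maneuver template is two-phase: expiratory flow rises to the
target peak flow over ``rise_time`` (a smoothed ramp, ``sin^2`` shaped,
so the junction carries no slope discontinuity that a real pneumotach
would never record), then decays exponentially toward zero while the
exhaled volume approaches the target FVC::

    flow(t) = pef * sin^2(pi t / (2 rise_time))         t <= t_j
    V(t)    = fvc - (fvc - V_j) * exp(-(t - t_j)/tau')  t  > t_j

with the decay constant tau' = (fvc - V_j)/pef fixed by flow continuity
at the junction t_j (an explicit ``tau`` overrides it, in which case the
realized FVC follows from continuity as V_j + pef * tau).  This template
is not a respiratory-mechanics model; it exists to exercise every QC
criterion while keeping closed forms available as oracles.

Artifacts are injected by kind-specific transforms of the flow channel
(applied in onset order), after which volume is the running integral of
flow -- the two channels stay consistent by construction:

========================  ====================================================
kind                      transform (magnitude semantics)
========================  ====================================================
cough                     multiplicative dip ``1 - m sin^2`` (fraction of flow)
glottic_closure           flow -> 0 from onset; short flat tail then stop
flutter_obstruction       flow *= 1 + m sin(2 pi f t) over the window
extra_breath              inspiratory bump inhaling ``m`` liters, then decay
hesitant_start            low-slope prefix exhaling ``m`` liters
early_termination         record truncated at onset
========================  ====================================================

Gaussian flow noise (``noise_sd``) is added last from a seed-determined
stream; one cohort seed fans out to per-maneuver substreams by stable
hashing of (session_id, maneuver_id), so the dataset is bit-identical for
a fixed seed regardless of generation order.

Ground truth carries, per maneuver, the injected (kind, onset) labels,
noise-free expected index values, and the QC flags the injections are
*intended* to produce; expected session grades come from the grading
decision table applied to those intended flags.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import qc as qc_mod
from .config import DEFAULT_CONFIG, QCConfig
from .errors import SimulationSpecError
from .session import SAMPLE_INTERVAL, Maneuver, Session

INJECTABLE_KINDS = ("cough", "glottic_closure", "flutter_obstruction",
                    "early_termination", "extra_breath", "hesitant_start")

_DEFAULT_DURATION = {"cough": 0.12, "flutter_obstruction": 1.0,
                     "extra_breath": 0.30, "hesitant_start": 0.50}
#: oscillation frequency of the injected flutter, Hz (mid detector band)
FLUTTER_HZ = 10.0
#: flow level at which the clean tail is considered finished, L/s
_TAIL_FLOW = 0.005
#: extra recording kept beyond the tail crossing, s
_TAIL_PAD = 1.0
#: recording kept after an injected glottic closure, s
_GC_TAIL = 1.2
#: hard cap on simulated record length, s
_MAX_T = 25.0


@dataclass(frozen=True)
class ArtifactSpec:
    """One injected anomaly; magnitude semantics are kind-specific."""

    kind: str
    onset: float
    magnitude: float = 0.0
    duration: Optional[float] = None

    def __post_init__(self):
        if self.kind not in INJECTABLE_KINDS:
            raise SimulationSpecError(
                f"kind {self.kind!r} is not injectable")
        if self.onset < 0:
            raise SimulationSpecError("artifact onset must be >= 0")
        dur = self.resolved_duration
        if self.kind in _DEFAULT_DURATION and dur <= 0:
            raise SimulationSpecError("artifact duration must be > 0")

    @property
    def resolved_duration(self) -> float:
        if self.duration is not None:
            return self.duration
        return _DEFAULT_DURATION.get(self.kind, 0.0)


@dataclass(frozen=True)
class ManeuverSpec:
    """Parameters of one simulated forced expiration."""

    fvc_true: float = 4.0
    pef_true: float = 8.0
    tau: Optional[float] = None   #: decay constant; None = from continuity
    rise_time: float = 0.08
    noise_sd: float = 0.02
    artifacts: Tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.fvc_true <= 0 or self.pef_true <= 0:
            raise SimulationSpecError("fvc_true and pef_true must be > 0")
        if self.tau is not None and self.tau <= 0:
            raise SimulationSpecError("tau must be > 0")
        if self.rise_time < 0 or self.noise_sd < 0:
            raise SimulationSpecError(
                "rise_time and noise_sd must be >= 0")
        object.__setattr__(self, "artifacts", tuple(self.artifacts))


@dataclass
class ManeuverTruth:
    """Ground truth attached to one simulated maneuver."""

    maneuver_id: str
    artifacts: List[Tuple[str, float]]     #: injected (kind, onset)
    fev1: Optional[float]                  #: noise-free expected value, L
    fvc: float                             #: noise-free expected value, L
    pef: float
    bev: float
    t0: float
    flags: Dict[str, bool]                 #: intended QC flags


@dataclass
class SessionTruth:
    session_id: str
    maneuvers: List[ManeuverTruth]
    fev1_grade: str
    fvc_grade: str


@dataclass
class LabeledDataset:
    sessions: List[Session]
    truth: List[SessionTruth]


# ---------------------------------------------------------------------------
# single maneuver
# ---------------------------------------------------------------------------

def _clean_flow(spec: ManeuverSpec, dt: float) -> Tuple[np.ndarray, float]:
    """Noise-free template flow on the full grid; returns (flow, t_junction)."""
    t_j = spec.rise_time
    v_j = spec.pef_true * t_j / 2.0
    if spec.tau is not None:
        tau_eff = spec.tau
    else:
        if spec.fvc_true <= v_j:
            raise SimulationSpecError(
                "fvc_true must exceed the volume exhaled during the rise")
        tau_eff = (spec.fvc_true - v_j) / spec.pef_true
    t_tail = t_j + tau_eff * np.log(spec.pef_true / _TAIL_FLOW)
    t_max = min(t_tail + _TAIL_PAD, _MAX_T)
    n = int(np.floor(t_max / dt)) + 1
    t = dt * np.arange(n)
    # sin^2 ramp: same junction volume as a linear rise (pef * t_j / 2)
    # but continuous slope, matching what a flow sensor records
    rise = (np.sin(np.pi * t / (2 * t_j)) ** 2 if t_j > 0
            else np.ones_like(t))
    flow = np.where(
        t <= t_j,
        spec.pef_true * rise,
        spec.pef_true * np.exp(-(np.maximum(t - t_j, 0.0)) / tau_eff),
    )
    if t_j == 0:
        flow[0] = spec.pef_true
    return flow, t_j


def _inject(flow: np.ndarray, dt: float, art: ArtifactSpec,
            shift: float) -> Tuple[np.ndarray, float]:
    """Apply one artifact; returns (flow, additional time shift).

    ``shift`` is the accumulated prefix length from earlier hesitant-start
    injections: onsets are interpreted on the original (unshifted) clock
    and moved accordingly.
    """
    onset = art.onset + shift
    i0 = int(round(onset / dt))
    n = len(flow)
    if i0 >= n:
        raise SimulationSpecError(
            f"artifact {art.kind!r} onset {art.onset:.2f}s lies beyond the "
            f"curve end {(n - 1) * dt:.2f}s")
    dur = art.resolved_duration
    k = art.kind
    if k == "cough":
        i1 = min(n, i0 + int(round(dur / dt)) + 1)
        ph = np.pi * (np.arange(i1 - i0) * dt) / dur
        flow[i0:i1] *= 1.0 - art.magnitude * np.sin(ph) ** 2
        return flow, 0.0
    if k == "flutter_obstruction":
        i1 = min(n, i0 + int(round(dur / dt)) + 1)
        tt = np.arange(i1 - i0) * dt
        flow[i0:i1] *= 1.0 + art.magnitude * np.sin(
            2 * np.pi * FLUTTER_HZ * tt)
        return flow, 0.0
    if k == "glottic_closure":
        i1 = min(n, i0 + int(round(_GC_TAIL / dt)) + 1)
        flow = flow[:i1].copy()
        flow[i0:] = 0.0
        return flow, 0.0
    if k == "extra_breath":
        i1 = min(n, i0 + int(round(dur / dt)) + 1)
        amp = 2.0 * art.magnitude / dur  # peak inspiratory flow, L/s
        ph = np.pi * (np.arange(i1 - i0) * dt) / dur
        flow[i0:i1] = -amp * np.sin(ph) ** 2
        return flow, 0.0
    if k == "hesitant_start":
        n_pre = int(round(dur / dt))
        pre = np.full(n_pre, art.magnitude / dur)
        return np.concatenate([pre, flow]), n_pre * dt
    if k == "early_termination":
        if i0 < 2:
            raise SimulationSpecError(
                "early_termination onset leaves no recording")
        return flow[:i0 + 1].copy(), 0.0
    raise SimulationSpecError(f"unhandled artifact kind {k!r}")


def _expected_t0(spec: ManeuverSpec, shift: float) -> float:
    """Analytic back-extrapolated time zero of the injected template."""
    t_j = shift + spec.rise_time
    v_j = spec.pef_true * spec.rise_time / 2.0
    if shift > 0:
        # hesitant prefix volume accumulates before the rise
        pre = sum(a.magnitude for a in spec.artifacts
                  if a.kind == "hesitant_start")
        v_j += pre
    return t_j - v_j / spec.pef_true


def _intended_flags(spec: ManeuverSpec, t0: float) -> Dict[str, bool]:
    """QC flags the injected artifact set is designed to produce."""
    flags = {"fev1_acceptable": True, "fev1_usable": True,
             "fvc_acceptable": True, "fvc_usable": True}
    clean = True
    for a in spec.artifacts:
        clean = False
        onset = a.onset
        in_first = onset < t0 + 1.0
        if a.kind == "cough" and in_first:
            flags["fev1_usable"] = False
        elif a.kind == "glottic_closure":
            flags["fvc_acceptable"] = False
            if in_first:
                flags["fev1_usable"] = False
        elif a.kind == "flutter_obstruction":
            flags["fvc_usable"] = False
            if onset < t0 + 1.0 + a.resolved_duration:
                # window overlap with [t0, t0+1]
                if onset < t0 + 1.0:
                    flags["fev1_usable"] = False
        elif a.kind == "extra_breath":
            flags["fvc_usable"] = False
            if in_first:
                flags["fev1_acceptable"] = False
        elif a.kind == "hesitant_start":
            flags["fev1_usable"] = False
            flags["fvc_usable"] = False
        elif a.kind == "early_termination":
            flags["fvc_acceptable"] = False
    flags["fev1_acceptable"] &= flags["fev1_usable"]
    flags["fvc_acceptable"] &= flags["fvc_usable"]
    del clean
    return flags


def generate_maneuver(spec: ManeuverSpec, maneuver_id: str = "m1",
                      dt: float = SAMPLE_INTERVAL
                      ) -> Tuple[Maneuver, ManeuverTruth]:
    """Simulate one maneuver; returns the recording and its ground truth."""
    flow, _ = _clean_flow(spec, dt)
    shift = 0.0
    arts = sorted(spec.artifacts, key=lambda a: a.onset)
    # hesitant starts first: they shift every later onset
    arts = ([a for a in arts if a.kind == "hesitant_start"]
            + [a for a in arts if a.kind != "hesitant_start"])
    for a in arts:
        flow, extra = _inject(flow, dt, a, shift)
        shift += extra

    n = len(flow)
    t = dt * np.arange(n)
    vol_nf = np.concatenate(
        ([0.0], np.cumsum((flow[1:] + flow[:-1]) * dt / 2.0)))

    # ground truth from the noise-free series
    t0 = max(0.0, _expected_t0(spec, shift))
    v0 = float(np.interp(t0, t, vol_nf))
    fvc = float(np.max(vol_nf)) - v0
    fev1 = (float(np.interp(t0 + 1.0, t, vol_nf)) - v0
            if t0 + 1.0 <= t[-1] else None)
    truth = ManeuverTruth(
        maneuver_id=maneuver_id,
        artifacts=[(a.kind, a.onset) for a in spec.artifacts],
        fev1=fev1, fvc=fvc, pef=float(np.max(flow)),
        bev=v0, t0=t0,
        flags=_intended_flags(spec, t0),
    )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.normal(0.0, spec.noise_sd, n)
        flow = flow + noise
        vol = vol_nf + np.concatenate(
            ([0.0], np.cumsum((noise[1:] + noise[:-1]) * dt / 2.0)))
    else:
        vol = vol_nf
    man = Maneuver(maneuver_id=maneuver_id, t=t, volume=vol, flow=flow,
                   sample_interval=dt)
    return man, truth


# ---------------------------------------------------------------------------
# sessions and cohorts
# ---------------------------------------------------------------------------

def _substream_seed(global_seed: int, session_id: str,
                    maneuver_id: str) -> int:
    """Stable per-maneuver seed, independent of generation order."""
    h = zlib.crc32(f"{session_id}/{maneuver_id}".encode())
    return int((np.uint64(global_seed) * np.uint64(2654435761)
                + np.uint64(h)) % np.uint64(2 ** 31))


def generate_session(specs: Sequence[ManeuverSpec], session_id: str = "s1",
                     subject_age: Optional[float] = None,
                     config: QCConfig = DEFAULT_CONFIG
                     ) -> Tuple[Session, SessionTruth]:
    """Assemble a session; truth includes the expected grades.

    Expected grades apply the grading decision table to the *intended*
    per-maneuver flags and noise-free values -- not to anything measured
    by the analysis pipeline.
    """
    if not specs:
        raise SimulationSpecError("generate_session: need >= 1 spec")
    mans, truths = [], []
    for i, spec in enumerate(specs):
        mid = f"m{i + 1}"
        man, tr = generate_maneuver(spec, maneuver_id=mid)
        mans.append(man)
        truths.append(tr)
    session = Session(session_id=session_id, maneuvers=mans,
                      subject_age=subject_age)
    qcs = [
        qc_mod.ManeuverQC(
            fev1_acceptable=tr.flags["fev1_acceptable"],
            fev1_usable=tr.flags["fev1_usable"],
            fvc_acceptable=tr.flags["fvc_acceptable"],
            fvc_usable=tr.flags["fvc_usable"],
            reasons=[("intended", all(tr.flags.values()), "injected truth")],
        )
        for tr in truths
    ]
    grade = qc_mod.grade_session(
        qcs, [tr.fev1 for tr in truths], [tr.fvc for tr in truths],
        subject_age=subject_age, config=config)
    truth = SessionTruth(session_id=session_id, maneuvers=truths,
                         fev1_grade=grade.fev1_grade,
                         fvc_grade=grade.fvc_grade)
    return session, truth


#: per-kind (pef/fvc ratio, onset, magnitude builder) in the strong regime;
#: slower decays give closure/extra-breath/termination injections room to
#: satisfy their timing constraints without touching the first second
def _strong_artifact(kind: str, fvc: float) -> Tuple[float, ArtifactSpec]:
    if kind == "cough":
        return 2.2, ArtifactSpec("cough", onset=0.5, magnitude=0.4)
    if kind == "flutter_obstruction":
        return 2.2, ArtifactSpec("flutter_obstruction", onset=0.5,
                                 magnitude=0.25, duration=1.0)
    if kind == "hesitant_start":
        return 2.2, ArtifactSpec("hesitant_start", onset=0.0,
                                 magnitude=0.1 * fvc, duration=0.5)
    if kind == "glottic_closure":
        return 1.3, ArtifactSpec("glottic_closure", onset=1.3)
    if kind == "extra_breath":
        return 1.3, ArtifactSpec("extra_breath", onset=2.0, magnitude=0.2,
                                 duration=0.3)
    if kind == "early_termination":
        # truncate at ~88% of FVC: confirms neither plateau nor repeatability
        return 1.6, ArtifactSpec("early_termination", onset=1.28)
    raise SimulationSpecError(f"no strong regime for kind {kind!r}")


def generate_cohort(n_sessions: int,
                    artifact_mix: Optional[Dict[str, float]] = None,
                    quality_profile: float = 0.7,
                    seed: int = 0,
                    noise_sd: float = 0.02,
                    config: QCConfig = DEFAULT_CONFIG) -> LabeledDataset:
    """Reproducible labeled cohort of simulated sessions.

    A fraction ``quality_profile`` of sessions (in expectation) is
    violation-free (three clean maneuvers); the rest carry one artifact
    maneuver with the kind drawn from ``artifact_mix`` (default uniform
    over the six injectable kinds) at its documented strong-regime
    strength, plus two clean maneuvers.
    """
    if n_sessions < 1:
        raise SimulationSpecError("n_sessions must be >= 1")
    if not 0.0 <= quality_profile <= 1.0:
        raise SimulationSpecError("quality_profile must lie in [0, 1]")
    if artifact_mix is None:
        artifact_mix = {k: 1.0 / len(INJECTABLE_KINDS)
                        for k in INJECTABLE_KINDS}
    kinds = sorted(artifact_mix)
    probs = np.array([artifact_mix[k] for k in kinds], dtype=float)
    if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise SimulationSpecError("artifact_mix must be a distribution")
    unknown = set(kinds) - set(INJECTABLE_KINDS)
    if unknown:
        raise SimulationSpecError(f"artifact_mix has unknown kinds {unknown}")

    top = np.random.default_rng(seed)
    sessions, truths = [], []
    for i in range(n_sessions):
        sid = f"sim{i + 1:04d}"
        fvc = float(top.uniform(2.5, 5.5))
        clean_sess = bool(top.random() < quality_profile)
        kind = kinds[int(top.choice(len(kinds), p=probs))]
        jitter = top.uniform(-0.02, 0.02, size=3)

        specs = []
        for j in range(3):
            fvc_j = fvc + float(jitter[j])
            pef_ratio, art = (2.2, None)
            if not clean_sess and j == 2:
                pef_ratio, art = _strong_artifact(kind, fvc_j)
            specs.append(ManeuverSpec(
                fvc_true=fvc_j,
                pef_true=pef_ratio * fvc_j,
                rise_time=0.08,
                noise_sd=noise_sd,
                artifacts=(art,) if art is not None else (),
                seed=_substream_seed(seed, sid, f"m{j + 1}"),
            ))
        sess, truth = generate_session(specs, session_id=sid, config=config)
        sessions.append(sess)
        truths.append(truth)
    return LabeledDataset(sessions=sessions, truth=truths)


# ---------------------------------------------------------------------------
# truth (de)serialization for the CLI sidecar
# ---------------------------------------------------------------------------

def truth_to_dict(dataset: LabeledDataset) -> dict:
    return {
        "sessions": [
            {
                "session_id": st.session_id,
                "fev1_grade": st.fev1_grade,
                "fvc_grade": st.fvc_grade,
                "maneuvers": [
                    {
                        "maneuver_id": mt.maneuver_id,
                        "artifacts": [list(a) for a in mt.artifacts],
                        "fev1": mt.fev1, "fvc": mt.fvc, "pef": mt.pef,
                        "bev": mt.bev, "t0": mt.t0,
                        "flags": mt.flags,
                    }
                    for mt in st.maneuvers
                ],
            }
            for st in dataset.truth
        ]
    }


def truth_from_dict(doc: dict) -> List[SessionTruth]:
    out = []
    for s in doc["sessions"]:
        out.append(SessionTruth(
            session_id=s["session_id"],
            fev1_grade=s["fev1_grade"],
            fvc_grade=s["fvc_grade"],
            maneuvers=[
                ManeuverTruth(
                    maneuver_id=m["maneuver_id"],
                    artifacts=[tuple(a) for a in m["artifacts"]],
                    fev1=m["fev1"], fvc=m["fvc"], pef=m["pef"],
                    bev=m["bev"], t0=m["t0"],
                    flags=dict(m["flags"]),
                )
                for m in s["maneuvers"]
            ],
        ))
    return out
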