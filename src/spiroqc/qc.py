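"""Acceptability, usability, session grading, and operator messaging.

Rule-check results (quantitative indices) and artifact findings are
combined with a union-of-failures policy: any failed criterion from either
source voids the affected verdict.  Per ATS/ERS 2019 the two indices are
judged separately -- a cough in the first second voids FEV1 but not FVC;
a missing end-of-test plateau voids FVC acceptability but not FEV1.

The decision table (criterion id -> affected index, phase window,
acceptability-vs-usability effect) and the warning/guidance message
catalog ship as JSON data files so they can be corrected without code
changes.

Session grades per index::

    A: >= 3 acceptable maneuvers, top-two delta <= 0.150 L
    B: exactly 2 acceptable,      delta <= 0.150 L
    C: >= 2 acceptable,           delta <= 0.200 L
    D: >= 2 acceptable,           delta <= 0.250 L
    E: >= 2 acceptable with delta > 0.250 L, or exactly 1 acceptable
    U: 0 acceptable but >= 1 usable
    F: 0 acceptable, 0 usable

(Pediatric tiers, subject age <= 6 years: 0.100 / 0.150 / 0.200 L.)
Grades A-C count as "good quality".  The EOFE rule's session-relative
FVC-repeatability branch requires a two-pass design: maneuvers are first
assessed without session context to find the best usable FVC, then
re-assessed with each maneuver's distance to it.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from typing import List, Optional, Sequence, Tuple

from .artifacts import ArtifactFinding, scan_artifacts
from .config import DEFAULT_CONFIG, QCConfig
from .errors import InputError
from .indices import SpirometryIndices, compute_indices, eofe_met, \
    repeatability_delta
from .session import Session

GRADES = ("A", "B", "C", "D", "E", "U", "F")
GOOD_GRADES = frozenset({"A", "B", "C"})


def _load_data(name: str) -> dict:
    with resources.files("spiroqc.data").joinpath(name).open(
            "r", encoding="utf-8") as fh:
        return json.load(fh)


DECISION_TABLE: List[dict] = _load_data("decision_table.json")["criteria"]
MESSAGE_CATALOG: dict = _load_data("messages.json")["catalog"]
_EFFECTS = {row["id"]: row for row in DECISION_TABLE}


@dataclass
class ManeuverQC:
    """Per-maneuver acceptability/usability verdicts with reasons."""

    fev1_acceptable: bool
    fev1_usable: bool
    fvc_acceptable: bool
    fvc_usable: bool
    #: (criterion-id, passed, detail) for every criterion evaluated
    reasons: List[Tuple[str, bool, str]] = field(default_factory=list)

    def __post_init__(self):
        if self.fev1_acceptable and not self.fev1_usable:
            raise ValueError("fev1_acceptable implies fev1_usable")
        if self.fvc_acceptable and not self.fvc_usable:
            raise ValueError("fvc_acceptable implies fvc_usable")

    def failed_ids(self) -> List[str]:
        return [cid for cid, passed, _ in self.reasons if not passed]


@dataclass
class SessionGrade:
    """Session-level quality rating per index, with messaging."""

    fev1_grade: str
    fvc_grade: str
    fev1_delta: float
    fvc_delta: float
    n_fev1_acceptable: int
    n_fev1_usable: int
    n_fvc_acceptable: int
    n_fvc_usable: int
    messages: List[str] = field(default_factory=list)
    guidance: List[str] = field(default_factory=list)

    def good_quality(self, index: str) -> bool:
        grade = self.fev1_grade if index == "fev1" else self.fvc_grade
        return grade in GOOD_GRADES


def assess_maneuver(indices: SpirometryIndices,
                    findings: Sequence[ArtifactFinding],
                    best_fvc_delta: Optional[float] = None,
                    config: QCConfig = DEFAULT_CONFIG) -> ManeuverQC:
    """Apply the decision table to one maneuver's indices and findings.

    ``best_fvc_delta`` is the absolute FVC difference to the best *other*
    usable maneuver of the session (None without session context); it
    feeds the EOFE repeatability branch only.
    """
    for f in findings:
        if f.t_start < -1e-9 or f.t_end > indices.duration + 1e-9:
            raise InputError(
                f"finding {f.kind!r} [{f.t_start:.2f}, {f.t_end:.2f}] lies "
                f"outside the maneuver span [0, {indices.duration:.2f}]")

    t0 = indices.t0
    first_second = (t0, t0 + 1.0)
    by_kind = {}
    for f in findings:
        by_kind.setdefault(f.kind, []).append(f)

    def _any(kind: str, window: Optional[Tuple[float, float]] = None) -> bool:
        fs = by_kind.get(kind, [])
        if window is None:
            return bool(fs)
        return any(f.overlaps(*window) for f in fs)

    bev_limit = max(config.bev_abs, config.bev_frac * indices.fvc)
    eofe = eofe_met(indices, best_fvc_delta, config)
    et_unexplained = _any("early_termination") and not eofe

    checks = [
        ("bev_limit", indices.bev <= bev_limit + 1e-12,
         f"BEV {indices.bev:.3f} L vs limit {bev_limit:.3f} L"),
        ("fev1_measurable", indices.fev1 is not None,
         "FEV1 measurable" if indices.fev1 is not None
         else "record ends before t0 + 1 s"),
        ("cough_first_second", not _any("cough", first_second),
         "cough overlapping the first second"),
        ("glottic_closure_first_second",
         not _any("glottic_closure", first_second),
         "glottic closure overlapping the first second"),
        ("glottic_closure_any", not _any("glottic_closure"),
         "glottic closure during expiration"),
        ("flutter_first_second",
         not _any("flutter_obstruction", first_second),
         "flutter overlapping the first second"),
        ("flutter_any", not _any("flutter_obstruction"),
         "flutter during the maneuver"),
        ("extra_breath_first_second",
         not _any("extra_breath", first_second),
         "extra breath in the first second"),
        ("extra_breath_any", not _any("extra_breath"),
         "extra breath during the maneuver"),
        ("hesitant_start", not _any("hesitant_start"),
         f"BEV {indices.bev:.3f} L vs limit {bev_limit:.3f} L"),
        ("variable_flow", not _any("variable_flow"),
         f"tPEF {indices.tpef:.2f} s vs limit {config.tpef_max:.2f} s"),
        ("eofe", eofe,
         f"plateau={indices.plateau}, FET={indices.fet:.1f} s, "
         f"best-FVC delta="
         + (f"{best_fvc_delta:.3f} L" if best_fvc_delta is not None
            else "n/a")),
        # an early-termination finding only fails FVC acceptability when the
        # EOFE rule (including the session repeatability branch) is unmet;
        # otherwise the repeatability branch could never rescue a maneuver
        ("early_termination", not et_unexplained,
         "expiration terminated before an EOFE indicator"),
    ]

    flags = {"fev1": {"acceptability": True, "usability": True},
             "fvc": {"acceptability": True, "usability": True}}
    reasons = []
    for cid, passed, detail in checks:
        reasons.append((cid, bool(passed), detail))
        if passed:
            continue
        row = _EFFECTS[cid]
        for index in ("fev1", "fvc"):
            effect = row[index]
            if effect == "none":
                continue
            flags[index]["acceptability"] = False
            if effect == "usability":
                flags[index]["usability"] = False
    return ManeuverQC(
        fev1_acceptable=flags["fev1"]["acceptability"],
        fev1_usable=flags["fev1"]["usability"],
        fvc_acceptable=flags["fvc"]["acceptability"],
        fvc_usable=flags["fvc"]["usability"],
        reasons=reasons,
    )


def _tiers(subject_age: Optional[float],
           config: QCConfig) -> Tuple[float, float, float]:
    if subject_age is not None and subject_age <= config.ped_age_max:
        return config.ped_tier_ab, config.ped_tier_c, config.ped_tier_d
    return config.tier_ab, config.tier_c, config.tier_d


def _grade_one(n_acc: int, n_usable: int, delta: float,
               tiers: Tuple[float, float, float]) -> str:
    t_ab, t_c, t_d = tiers
    eps = 1e-12
    if n_acc == 0:
        return "U" if n_usable > 0 else "F"
    if n_acc == 1:
        return "E"
    if n_acc >= 3 and delta <= t_ab + eps:
        return "A"
    if n_acc == 2 and delta <= t_ab + eps:
        return "B"
    if delta <= t_c + eps:
        return "C"
    if delta <= t_d + eps:
        return "D"
    return "E"


def grade_session(qcs: Sequence[ManeuverQC],
                  fev1_values: Sequence[Optional[float]],
                  fvc_values: Sequence[float],
                  subject_age: Optional[float] = None,
                  config: QCConfig = DEFAULT_CONFIG) -> SessionGrade:
    """Grade a session per index from aligned QC verdicts and values.

    Repeatability deltas are taken over the values of *acceptable*
    maneuvers only.  Messages are left empty; use
    :func:`generate_messages` (or :func:`assess_session`) to fill them.
    """
    if not qcs:
        raise InputError("grade_session: empty maneuver list")
    if not (len(qcs) == len(fev1_values) == len(fvc_values)):
        raise InputError("grade_session: misaligned inputs")
    tiers = _tiers(subject_age, config)

    def _one(acc_flags, usable_flags, values):
        acc_vals = [v for a, v in zip(acc_flags, values)
                    if a and v is not None]
        n_acc = sum(bool(a) for a in acc_flags)
        n_usable = sum(bool(u) for u in usable_flags)
        delta = repeatability_delta(acc_vals) if acc_vals else 0.0
        return n_acc, n_usable, delta, _grade_one(n_acc, n_usable, delta,
                                                  tiers)

    na1, nu1, d1, g1 = _one([q.fev1_acceptable for q in qcs],
                            [q.fev1_usable for q in qcs], fev1_values)
    na2, nu2, d2, g2 = _one([q.fvc_acceptable for q in qcs],
                            [q.fvc_usable for q in qcs], fvc_values)
    return SessionGrade(
        fev1_grade=g1, fvc_grade=g2, fev1_delta=d1, fvc_delta=d2,
        n_fev1_acceptable=na1, n_fev1_usable=nu1,
        n_fvc_acceptable=na2, n_fvc_usable=nu2,
    )


def generate_messages(qcs: Sequence[ManeuverQC],
                      grade: SessionGrade) -> Tuple[List[str], List[str]]:
    """Operator warnings and patient guidance for a graded session.

    One message per distinct failed criterion id across all maneuvers
    (deterministic criterion-id ordering), plus a repeat-maneuver prompt
    when either index grades below C.  A pure function of the *set* of
    failed ids, hence invariant to maneuver order.
    """
    failed = sorted({cid for q in qcs for cid in q.failed_ids()})
    messages = [MESSAGE_CATALOG[cid]["operator"] for cid in failed]
    guidance = [MESSAGE_CATALOG[cid]["patient"] for cid in failed]
    if grade.fev1_grade not in GOOD_GRADES or \
            grade.fvc_grade not in GOOD_GRADES:
        messages.append(MESSAGE_CATALOG["repeat_maneuver"]["operator"])
        guidance.append(MESSAGE_CATALOG["repeat_maneuver"]["patient"])
    return messages, guidance


# ---------------------------------------------------------------------------
# session-level pipeline
# ---------------------------------------------------------------------------

@dataclass
class ManeuverReport:
    maneuver_id: str
    indices: SpirometryIndices
    findings: List[ArtifactFinding]
    qc: ManeuverQC


@dataclass
class SessionReport:
    session_id: str
    maneuvers: List[ManeuverReport]
    grade: SessionGrade


def assess_session(session: Session,
                   config: QCConfig = DEFAULT_CONFIG) -> SessionReport:
    """Full per-session QC: indices, artifact scan, two-pass verdicts, grade."""
    session.validate()
    per = []
    for m in session.maneuvers:
        idx = compute_indices(m, config)
        findings = scan_artifacts(m, idx, config)
        per.append((m, idx, findings))

    # pass 1: verdicts without session context, to find the best usable FVC
    pass1 = [assess_maneuver(idx, fnd, None, config)
             for _, idx, fnd in per]
    usable_fvcs = [idx.fvc for (_, idx, _), q in zip(per, pass1)
                   if q.fvc_usable]

    # pass 2: re-assess with each maneuver's distance to the best OTHER
    # usable FVC (self-comparison would trivially satisfy the branch)
    reports = []
    for (m, idx, fnd), q1 in zip(per, pass1):
        others = list(usable_fvcs)
        if q1.fvc_usable:
            others.remove(idx.fvc)
        delta = abs(max(others) - idx.fvc) if others else None
        qc = assess_maneuver(idx, fnd, delta, config)
        reports.append(ManeuverReport(m.maneuver_id, idx, fnd, qc))

    grade = grade_session(
        [r.qc for r in reports],
        [r.indices.fev1 for r in reports],
        [r.indices.fvc for r in reports],
        subject_age=session.subject_age, config=config)
    grade.messages, grade.guidance = generate_messages(
        [r.qc for r in reports], grade)
    return SessionReport(session.session_id, reports, grade)


def report_to_dict(report: SessionReport) -> dict:
    """Serializable form of a session report (deterministic key order)."""
    return {
        "session_id": report.session_id,
        "maneuvers": [
            {
                "maneuver_id": r.maneuver_id,
                "indices": {
                    "t0": r.indices.t0, "bev": r.indices.bev,
                    "fev1": r.indices.fev1, "fvc": r.indices.fvc,
                    "pef": r.indices.pef, "tpef": r.indices.tpef,
                    "fet": r.indices.fet, "plateau": r.indices.plateau,
                    "plateau_onset": r.indices.plateau_onset,
                },
                "findings": [
                    {"kind": f.kind, "t_start": f.t_start, "t_end": f.t_end,
                     "v_at_onset": f.v_at_onset, "score": f.score}
                    for f in r.findings
                ],
                "qc": {
                    "fev1_acceptable": r.qc.fev1_acceptable,
                    "fev1_usable": r.qc.fev1_usable,
                    "fvc_acceptable": r.qc.fvc_acceptable,
                    "fvc_usable": r.qc.fvc_usable,
                    "reasons": [list(x) for x in r.qc.reasons],
                },
            }
            for r in report.maneuvers
        ],
        "grade": {
            "fev1_grade": report.grade.fev1_grade,
            "fvc_grade": report.grade.fvc_grade,
            "fev1_delta": report.grade.fev1_delta,
            "fvc_delta": report.grade.fvc_delta,
            "n_fev1_acceptable": report.grade.n_fev1_acceptable,
            "n_fev1_usable": report.grade.n_fev1_usable,
            "n_fvc_acceptable": report.grade.n_fvc_acceptable,
            "n_fvc_usable": report.grade.n_fvc_usable,
            "messages": report.grade.messages,
            "guidance": report.grade.guidance,
        },
    }


def write_report_json(report: SessionReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_to_dict(report), fh, indent=1, sort_keys=True)
        fh.write("\n")


CSV_FIELDS = ["session_id", "maneuver_id", "fev1", "fvc", "pef", "bev",
              "fet", "plateau", "fev1_acceptable", "fev1_usable",
              "fvc_acceptable", "fvc_usable", "fev1_grade", "fvc_grade",
              "findings"]


def write_reports_csv(reports: Sequence[SessionReport], path) -> None:
    """Flat one-row-per-maneuver CSV for batch audits."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
        w.writeheader()
        for rep in reports:
            for r in rep.maneuvers:
                w.writerow({
                    "session_id": rep.session_id,
                    "maneuver_id": r.maneuver_id,
                    "fev1": "" if r.indices.fev1 is None
                            else f"{r.indices.fev1:.3f}",
                    "fvc": f"{r.indices.fvc:.3f}",
                    "pef": f"{r.indices.pef:.2f}",
                    "bev": f"{r.indices.bev:.3f}",
                    "fet": f"{r.indices.fet:.2f}",
                    "plateau": int(r.indices.plateau),
                    "fev1_acceptable": int(r.qc.fev1_acceptable),
                    "fev1_usable": int(r.qc.fev1_usable),
                    "fvc_acceptable": int(r.qc.fvc_acceptable),
                    "fvc_usable": int(r.qc.fvc_usable),
                    "fev1_grade": rep.grade.fev1_grade,
                    "fvc_grade": rep.grade.fvc_grade,
                    "findings": ";".join(
                        f"{f.kind}@{f.t_start:.2f}" for f in r.findings),
                })
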