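"""Evaluation statistics and batch assessment.

Classification of maneuvers/sessions against ground truth is summarized
with five metrics -- balanced accuracy, sensitivity, specificity, PPV and
NPV -- plus exact-match accuracy for the seven-letter quality grades, and
a chi-squared comparison of per-group quality proportions (e.g. monthly
batches of a primary-care quality programme).

Display values are rounded half-up to one decimal (the convention of
clinical tables); raw values are retained on every result object.
Undefined ratios (zero denominator) are reported as ``None`` and listed
in ``undefined`` rather than silently coerced to 0, since class imbalance
otherwise masquerades as poor performance.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import chi2_contingency

from .config import DEFAULT_CONFIG, QCConfig
from .errors import InputError, SpiroQCError
from .qc import GRADES, SessionReport, assess_session, \
    write_report_json, write_reports_csv
from .session import read_session
from .synthetic import SessionTruth

logger = logging.getLogger("spiroqc")


def round_half_up(x: float, decimals: int = 1) -> float:
    """Half-up decimal rounding (4.25 -> 4.3), as clinical tables print."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class EvalMetrics:
    """Confusion counts and the five classification metrics (percent)."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    balanced_accuracy: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    #: names of metrics whose denominator was zero
    undefined: Tuple[str, ...] = ()

    def display(self) -> Dict[str, str]:
        out = {}
        for name in ("balanced_accuracy", "sensitivity", "specificity",
                     "ppv", "npv"):
            v = getattr(self, name)
            out[name] = "undefined" if v is None else \
                f"{round_half_up(v):.1f}"
        return out


def confusion_metrics(truth: Sequence[bool],
                      pred: Sequence[bool]) -> EvalMetrics:
    """Five-metric summary of a binary classification."""
    truth = np.asarray(truth, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if truth.shape != pred.shape:
        raise InputError("confusion_metrics: truth/pred length mismatch")
    if truth.size == 0:
        raise InputError("confusion_metrics: empty input")
    tp = int(np.sum(truth & pred))
    fn = int(np.sum(truth & ~pred))
    tn = int(np.sum(~truth & ~pred))
    fp = int(np.sum(~truth & pred))

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    bal = (sens + spec) / 2.0 if sens is not None and spec is not None \
        else None
    undefined = tuple(name for name, v in
                      [("sensitivity", sens), ("specificity", spec),
                       ("balanced_accuracy", bal), ("ppv", ppv),
                       ("npv", npv)] if v is None)
    return EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn, sensitivity=sens,
                       specificity=spec, balanced_accuracy=bal, ppv=ppv,
                       npv=npv, undefined=undefined)


def grade_accuracy(truth_grades: Sequence[str],
                   pred_grades: Sequence[str]) -> float:
    """Exact-match accuracy of A-F/U grades, percent."""
    if len(truth_grades) != len(pred_grades):
        raise InputError("grade_accuracy: length mismatch")
    if not truth_grades:
        raise InputError("grade_accuracy: empty input")
    for g in list(truth_grades) + list(pred_grades):
        if g not in GRADES:
            raise InputError(f"grade_accuracy: invalid grade letter {g!r}")
    hits = sum(a == b for a, b in zip(truth_grades, pred_grades))
    return 100.0 * hits / len(truth_grades)


@dataclass
class TrendResult:
    """Per-group proportions with a chi-squared homogeneity test."""

    labels: List[str]
    numerators: List[int]
    denominators: List[int]
    percents: List[float]          #: raw, 100 * num / den
    chi2: float
    p_value: float

    @property
    def percent_display(self) -> List[float]:
        return [round_half_up(p) for p in self.percents]

    @property
    def p_display(self) -> str:
        return "< .0001" if self.p_value < 1e-4 else f"{self.p_value:.4f}"


def monthly_quality_comparison(
        groups: Sequence[Tuple[str, int, int]]) -> TrendResult:
    """Chi-squared homogeneity test on k groups of (label, num, den).

    Pearson's test without continuity correction on the k x 2 table of
    (passing, failing) counts.
    """
    if len(groups) < 2:
        raise InputError("monthly_quality_comparison: need >= 2 groups")
    labels, nums, dens = [], [], []
    for label, num, den in groups:
        if den <= 0:
            raise InputError(
                f"monthly_quality_comparison: group {label!r} has zero "
                "denominator")
        if not 0 <= num <= den:
            raise InputError(
                f"monthly_quality_comparison: group {label!r} counts invalid")
        labels.append(str(label))
        nums.append(int(num))
        dens.append(int(den))
    table = np.array([[n, d - n] for n, d in zip(nums, dens)])
    if np.all(table[:, 0] == 0) or np.all(table[:, 1] == 0):
        chi2, p = 0.0, 1.0  # degenerate homogeneous table
    else:
        chi2, p, _, _ = chi2_contingency(table, correction=False)
    return TrendResult(
        labels=labels, numerators=nums, denominators=dens,
        percents=[100.0 * n / d for n, d in zip(nums, dens)],
        chi2=float(chi2), p_value=float(p),
    )


# ---------------------------------------------------------------------------
# detection benchmark
# ---------------------------------------------------------------------------

def detection_benchmark(n_maneuvers: int = 200, seed: int = 0,
                        noise_sd: float = 0.02,
                        config: QCConfig = DEFAULT_CONFIG) -> dict:
    """Seeded recall/false-positive benchmark of the artifact detectors.

    Simulates ``n_maneuvers`` single-artifact maneuvers (kinds cycled,
    strong-regime strengths, subject size drawn per maneuver) plus one
    clean mate each, runs the full scan, and reports per-kind recall and
    the clean-curve false-positive rate.  This is the package's stand-in
    for image-based detection accuracy: deterministic detectors measured
    on labeled synthetic curves.
    """
    from .artifacts import scan_artifacts
    from .indices import compute_indices
    from .synthetic import (INJECTABLE_KINDS, ManeuverSpec,
                            _strong_artifact, _substream_seed,
                            generate_maneuver)
    rng = np.random.default_rng(seed)
    recall_hit = {k: 0 for k in INJECTABLE_KINDS}
    recall_n = {k: 0 for k in INJECTABLE_KINDS}
    clean_fp = 0
    for i in range(n_maneuvers):
        kind = INJECTABLE_KINDS[i % len(INJECTABLE_KINDS)]
        fvc = float(rng.uniform(2.5, 5.5))
        pef_ratio, art = _strong_artifact(kind, fvc)
        spec = ManeuverSpec(
            fvc_true=fvc, pef_true=pef_ratio * fvc, rise_time=0.08,
            noise_sd=noise_sd, artifacts=(art,),
            seed=_substream_seed(seed, "bench", f"a{i}"))
        man, _ = generate_maneuver(spec, maneuver_id=f"a{i}")
        idx = compute_indices(man, config)
        found = {f.kind for f in scan_artifacts(man, idx, config)}
        recall_n[kind] += 1
        recall_hit[kind] += int(kind in found)

        mate = ManeuverSpec(
            fvc_true=fvc, pef_true=2.2 * fvc, rise_time=0.08,
            noise_sd=noise_sd,
            seed=_substream_seed(seed, "bench", f"c{i}"))
        man_c, _ = generate_maneuver(mate, maneuver_id=f"c{i}")
        idx_c = compute_indices(man_c, config)
        clean_fp += int(bool(scan_artifacts(man_c, idx_c, config)))
    recall = {k: recall_hit[k] / recall_n[k] for k in INJECTABLE_KINDS
              if recall_n[k]}
    return {
        "recall": recall,
        "min_recall": min(recall.values()),
        "clean_false_positive_rate": clean_fp / n_maneuvers,
        "n_artifact": n_maneuvers,
        "n_clean": n_maneuvers,
    }


# ---------------------------------------------------------------------------
# batch assessment
# ---------------------------------------------------------------------------

FLAG_NAMES = ("fev1_acceptable", "fev1_usable", "fvc_acceptable",
              "fvc_usable")


@dataclass
class BatchResult:
    reports: List[SessionReport]
    skipped: List[Tuple[str, str]] = field(default_factory=list)
    #: flag name -> EvalMetrics (only when truth was supplied)
    flag_metrics: Dict[str, EvalMetrics] = field(default_factory=dict)
    fev1_grade_accuracy: Optional[float] = None
    fvc_grade_accuracy: Optional[float] = None

    @property
    def ok(self) -> bool:
        return not self.skipped


def evaluate_against_truth(reports: Sequence[SessionReport],
                           truths: Sequence[SessionTruth],
                           result: Optional[BatchResult] = None
                           ) -> BatchResult:
    """Per-flag confusion metrics and grade accuracy vs ground truth.

    Truth convention: the positive class is "flag holds" (acceptable /
    usable), matching how acceptability tables are laid out.
    """
    if result is None:
        result = BatchResult(reports=list(reports))
    by_id = {t.session_id: t for t in truths}
    t_flags = {k: [] for k in FLAG_NAMES}
    p_flags = {k: [] for k in FLAG_NAMES}
    tg1, pg1, tg2, pg2 = [], [], [], []
    for rep in reports:
        tr = by_id.get(rep.session_id)
        if tr is None:
            raise InputError(
                f"evaluate: no truth for session {rep.session_id!r}")
        tg1.append(tr.fev1_grade)
        pg1.append(rep.grade.fev1_grade)
        tg2.append(tr.fvc_grade)
        pg2.append(rep.grade.fvc_grade)
        t_by_id = {mt.maneuver_id: mt for mt in tr.maneuvers}
        for r in rep.maneuvers:
            mt = t_by_id.get(r.maneuver_id)
            if mt is None:
                raise InputError(
                    f"evaluate: no truth for maneuver {r.maneuver_id!r} in "
                    f"session {rep.session_id!r}")
            for k in FLAG_NAMES:
                t_flags[k].append(mt.flags[k])
                p_flags[k].append(getattr(r.qc, k))
    result.flag_metrics = {
        k: confusion_metrics(t_flags[k], p_flags[k]) for k in FLAG_NAMES}
    result.fev1_grade_accuracy = grade_accuracy(tg1, pg1)
    result.fvc_grade_accuracy = grade_accuracy(tg2, pg2)
    return result


def run_batch(session_paths: Sequence,
              truth_path=None,
              report_dir=None,
              config: QCConfig = DEFAULT_CONFIG,
              fmt: str = "json") -> BatchResult:
    """Assess a batch of session files; optionally score against truth.

    Unreadable or malformed session files are logged and skipped; their
    paths land in ``result.skipped`` (so a caller can exit nonzero).
    Output is deterministic for fixed inputs and config.
    """
    reports, skipped = [], []
    for path in session_paths:
        try:
            session = read_session(path)
            reports.append(assess_session(session, config))
        except (SpiroQCError, OSError) as exc:
            logger.warning("skipping %s: %s", path, exc)
            skipped.append((str(path), str(exc)))
    result = BatchResult(reports=reports, skipped=skipped)

    if truth_path is not None:
        from .synthetic import truth_from_dict
        with open(truth_path, "r", encoding="utf-8") as fh:
            truths = truth_from_dict(json.load(fh))
        evaluate_against_truth(reports, truths, result)

    if report_dir is not None:
        report_dir = Path(report_dir)
        report_dir.mkdir(parents=True, exist_ok=True)
        if fmt == "csv":
            write_reports_csv(reports, report_dir / "reports.csv")
        else:
            for rep in reports:
                write_report_json(rep, report_dir / f"{rep.session_id}.json")
        summary = {
            "n_sessions": len(reports),
            "skipped": [list(s) for s in skipped],
        }
        if result.flag_metrics:
            summary["flag_metrics"] = {
                k: {"tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
                    **m.display()}
                for k, m in result.flag_metrics.items()
            }
            summary["fev1_grade_accuracy"] = result.fev1_grade_accuracy
            summary["fvc_grade_accuracy"] = result.fvc_grade_accuracy
        with open(report_dir / "summary.json", "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return result
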