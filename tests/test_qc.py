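"""Acceptability/usability decision table, grading, and messaging."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from spiroqc import (ArtifactFinding, InputError, ManeuverQC,
                     assess_maneuver, generate_messages, grade_session)
from spiroqc.indices import SpirometryIndices
from spiroqc.qc import MESSAGE_CATALOG


def _idx(**kw):
    base = dict(t0=0.0, bev=0.0, fev1=3.6, fvc=4.0, pef=8.0, tpef=0.05,
                fet=6.0, t_end=6.0, plateau=True, plateau_onset=4.0,
                eofe_met=True, duration=8.0)
    base.update(kw)
    return SpirometryIndices(**base)


def _find(kind, lo, hi, vol=1.0, score=0.8):
    return ArtifactFinding(kind=kind, t_start=lo, t_end=hi, v_at_onset=vol,
                           score=score)


def _qc(fev1=True, fvc=True, fev1_us=None, fvc_us=None, fail=()):
    fev1_us = True if fev1_us is None else fev1_us
    fvc_us = True if fvc_us is None else fvc_us
    reasons = [(cid, False, "injected failure") for cid in fail]
    return ManeuverQC(fev1_acceptable=fev1, fev1_usable=fev1_us,
                      fvc_acceptable=fvc, fvc_usable=fvc_us,
                      reasons=reasons)


class TestAssessManeuver:
    def test_clean_maneuver_all_pass(self):
        qc = assess_maneuver(_idx(), [])
        assert (qc.fev1_acceptable and qc.fev1_usable
                and qc.fvc_acceptable and qc.fvc_usable)
        assert all(passed for _, passed, _ in qc.reasons)

    def test_cough_in_first_second_voids_fev1_only(self):
        qc = assess_maneuver(_idx(), [_find("cough", 0.5, 0.8)])
        assert not qc.fev1_usable and not qc.fev1_acceptable
        assert qc.fvc_acceptable and qc.fvc_usable

    def test_late_glottic_closure_voids_fvc_acceptability(self):
        qc = assess_maneuver(_idx(plateau=False, plateau_onset=None,
                                  eofe_met=False),
                             [_find("glottic_closure", 2.5, 3.0)])
        assert qc.fev1_acceptable and qc.fev1_usable
        assert not qc.fvc_acceptable and qc.fvc_usable

    def test_every_failed_criterion_lands_in_reasons(self):
        qc = assess_maneuver(_idx(bev=0.5), [_find("hesitant_start", 0, 0.2)])
        failed = qc.failed_ids()
        assert "bev_limit" in failed and "hesitant_start" in failed

    def test_finding_outside_span_rejected(self):
        with pytest.raises(InputError):
            assess_maneuver(_idx(duration=5.0), [_find("cough", 5.5, 6.0)])

    def test_unmeasurable_fev1_not_usable(self):
        qc = assess_maneuver(_idx(fev1=None), [])
        assert not qc.fev1_usable
        assert qc.fvc_usable

    def test_early_termination_excused_by_repeatability(self):
        idx = _idx(plateau=False, plateau_onset=None, eofe_met=False,
                   fet=4.0)
        finding = [_find("early_termination", 3.0, 4.0)]
        qc_excused = assess_maneuver(idx, finding, best_fvc_delta=0.05)
        assert qc_excused.fvc_acceptable
        qc_unmet = assess_maneuver(idx, finding, best_fvc_delta=0.40)
        assert not qc_unmet.fvc_acceptable

    @settings(max_examples=60, derandomize=True)
    @given(st.sets(st.sampled_from(
        ["cough", "glottic_closure", "flutter_obstruction", "extra_breath",
         "hesitant_start", "variable_flow", "early_termination"])),
        st.floats(min_value=0.1, max_value=5.0))
    def test_acceptable_implies_usable(self, kinds, t_lo):
        findings = [_find(k, t_lo, min(t_lo + 0.5, 7.9)) for k in kinds]
        qc = assess_maneuver(_idx(), findings)
        assert qc.fev1_usable or not qc.fev1_acceptable
        assert qc.fvc_usable or not qc.fvc_acceptable


# independently transcribed tier table (the oracle for grade_session)
def _grade_oracle(n_acc, n_usable, delta, t_ab=0.150, t_c=0.200, t_d=0.250):
    if n_acc == 0:
        return "U" if n_usable > 0 else "F"
    if n_acc == 1:
        return "E"
    if n_acc >= 3 and delta <= t_ab:
        return "A"
    if n_acc == 2 and delta <= t_ab:
        return "B"
    if delta <= t_c:
        return "C"
    if delta <= t_d:
        return "D"
    return "E"


def _session_for(n_acc, n_usable, delta, n_total=4):
    """Construct QCs and FVC values realizing the given bucket."""
    qcs, values = [], []
    for i in range(n_total):
        if i < n_acc:
            qcs.append(_qc())
        elif i < n_usable:
            qcs.append(_qc(fev1=False, fvc=False))
        else:
            qcs.append(_qc(fev1=False, fvc=False, fev1_us=False,
                           fvc_us=False))
        # top-two delta among acceptable values equals `delta`
        values.append(4.0 - delta * min(i, 1) - 0.5 * max(0, i - 1))
    return qcs, values


class TestGradeSession:
    @pytest.mark.parametrize("fvcs,n_acc,expected", [
        ([4.10, 4.05, 3.90], 3, "A"),
        ([3.30, 3.12], 2, "C"),
    ])
    def test_examples(self, fvcs, n_acc, expected):
        qcs = [_qc() for _ in fvcs]
        grade = grade_session(qcs, fvcs, fvcs)
        assert grade.fvc_grade == expected

    def test_no_acceptable_grades(self):
        qcs = [_qc(fev1=False, fvc=False), _qc(fev1=False, fvc=False)]
        g = grade_session(qcs, [3.0, 3.1], [3.5, 3.6])
        assert g.fvc_grade == "U" and g.fev1_grade == "U"
        qcs = [_qc(fev1=False, fvc=False, fev1_us=False, fvc_us=False)]
        g = grade_session(qcs, [3.0], [3.5])
        assert g.fvc_grade == "F" and g.fev1_grade == "F"

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            grade_session([], [], [])

    def test_enumeration_matches_oracle(self):
        for n_acc, delta in itertools.product(
                range(5), [0.05, 0.16, 0.21, 0.26]):
            for n_usable in range(n_acc, 5):
                qcs, values = _session_for(n_acc, n_usable, delta)
                g = grade_session(qcs, values, values)
                expected = _grade_oracle(n_acc, n_usable, delta)
                assert g.fvc_grade == expected, (n_acc, n_usable, delta)
                assert g.fev1_grade == expected

    def test_pediatric_tiers(self):
        qcs, values = _session_for(3, 3, 0.12, n_total=3)
        adult = grade_session(qcs, values, values, subject_age=35)
        child = grade_session(qcs, values, values, subject_age=5)
        assert adult.fvc_grade == "A"   # 0.12 <= 0.150
        assert child.fvc_grade == "C"   # 0.100 < 0.12 <= 0.150

    def test_restricted_monotonicity(self):
        # flipping a failed maneuver to acceptable, with its value no
        # larger than the current best, never worsens the grade
        order = {g: i for i, g in enumerate("ABCDEUF")}
        qcs = [_qc(), _qc(), _qc(fev1=False, fvc=False)]
        values = [4.0, 3.95, 3.90]
        before = grade_session(qcs, values, values)
        qcs2 = [_qc(), _qc(), _qc()]
        after = grade_session(qcs2, values, values)
        assert order[after.fvc_grade] <= order[before.fvc_grade]

    def test_monotonicity_counterexample_is_real(self):
        # the tier table is NOT monotone when the newly acceptable
        # maneuver carries a higher value: delta inflates, B -> E
        qcs = [_qc(), _qc(), _qc(fev1=False, fvc=False)]
        values = [4.0, 3.9, 4.5]
        assert grade_session(qcs, values, values).fvc_grade == "B"
        qcs2 = [_qc(), _qc(), _qc()]
        assert grade_session(qcs2, values, values).fvc_grade == "E"


class TestMessages:
    def test_all_pass_session_is_quiet(self):
        qcs = [_qc(), _qc(), _qc()]
        grade = grade_session(qcs, [4.0, 4.0, 4.0], [4.0, 4.0, 4.0])
        messages, guidance = generate_messages(qcs, grade)
        assert messages == [] and guidance == []

    def test_failed_criterion_deduplicated(self):
        qcs = [_qc(fev1=False, fev1_us=False, fail=["cough_first_second"]),
               _qc(fev1=False, fev1_us=False, fail=["cough_first_second"]),
               _qc()]
        grade = grade_session(qcs, [4.0] * 3, [4.0] * 3)
        messages, _ = generate_messages(qcs, grade)
        cough_msg = MESSAGE_CATALOG["cough_first_second"]["operator"]
        assert messages.count(cough_msg) == 1

    def test_low_grade_triggers_repeat_prompt(self):
        qcs, values = _session_for(2, 2, 0.22, n_total=2)  # grade D
        grade = grade_session(qcs, values, values)
        assert grade.fvc_grade == "D"
        messages, guidance = generate_messages(qcs, grade)
        assert MESSAGE_CATALOG["repeat_maneuver"]["operator"] in messages
        assert MESSAGE_CATALOG["repeat_maneuver"]["patient"] in guidance

    def test_permutation_invariance(self):
        a = _qc(fev1=False, fev1_us=False, fail=["cough_first_second"])
        b = _qc(fvc=False, fail=["eofe"])
        c = _qc()
        vals = [4.0, 4.0, 4.0]
        g1 = grade_session([a, b, c], vals, vals)
        g2 = grade_session([c, b, a], vals, vals)
        assert generate_messages([a, b, c], g1) == \
            generate_messages([c, b, a], g2)


class TestManeuverQCInvariant:
    def test_acceptable_without_usable_rejected(self):
        with pytest.raises(ValueError):
            ManeuverQC(fev1_acceptable=True, fev1_usable=False,
                       fvc_acceptable=True, fvc_usable=True)
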