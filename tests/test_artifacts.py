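"""Artifact detectors against injector ground truth."""

import numpy as np
import pytest

from spiroqc import (ArtifactSpec, Maneuver, ManeuverSpec, compute_indices,
                     detect_cough, detect_early_termination,
                     detect_extra_breath, detect_flutter,
                     detect_glottic_closure, detect_start_quality,
                     generate_maneuver, scan_artifacts)
from spiroqc.indices import SpirometryIndices

from conftest import ramp_maneuver


def _sim(artifacts=(), fvc=4.0, pef=8.8, noise=0.0, seed=0, rise=0.08):
    man, truth = generate_maneuver(
        ManeuverSpec(fvc_true=fvc, pef_true=pef, rise_time=rise,
                     noise_sd=noise, artifacts=tuple(artifacts), seed=seed))
    return man, compute_indices(man)


def _stub(**kw):
    base = dict(t0=0.0, bev=0.0, fev1=3.5, fvc=4.0, pef=8.0, tpef=0.05,
                fet=6.0, t_end=6.0, plateau=True, plateau_onset=4.0,
                eofe_met=True, duration=8.0)
    base.update(kw)
    return SpirometryIndices(**base)


class TestCough:
    def test_clean_curve_is_silent(self, clean_exp):
        assert detect_cough(clean_exp, compute_indices(clean_exp)) == []

    def test_single_injected_cough_recovered(self):
        man, idx = _sim([ArtifactSpec("cough", onset=0.6, magnitude=0.4)])
        findings = detect_cough(man, idx)
        assert len(findings) == 1
        f = findings[0]
        assert f.t_start <= 0.6 <= f.t_end
        assert 0.0 <= f.score <= 1.0

    def test_two_coughs_disjoint_and_ordered(self):
        man, idx = _sim([ArtifactSpec("cough", 0.5, 0.4),
                         ArtifactSpec("cough", 2.0, 0.4)],
                        pef=5.2)  # slow decay keeps flow up at 2 s
        findings = detect_cough(man, idx)
        assert len(findings) == 2
        assert findings[0].t_end <= findings[1].t_start
        assert findings[0].t_start <= 0.5 and findings[1].t_start <= 2.0

    @pytest.mark.parametrize("fvc", [2.5, 4.0, 5.5])
    def test_amplitude_monotonicity(self, fvc):
        # within the injector's strong regime (>= 0.35) a larger cough
        # never converts a detection into a miss
        detected_prev = False
        for mag in np.linspace(0.35, 0.7, 8):
            man, idx = _sim([ArtifactSpec("cough", 0.5, float(mag))],
                            fvc=fvc, pef=2.2 * fvc, noise=0.02, seed=5)
            detected = len(detect_cough(man, idx)) > 0
            assert detected or not detected_prev
            detected_prev = detected
        assert detected_prev


class TestGlotticClosure:
    def test_natural_decay_is_silent(self, clean_exp):
        assert detect_glottic_closure(
            clean_exp, compute_indices(clean_exp)) == []

    def test_closure_localized(self):
        man, idx = _sim([ArtifactSpec("glottic_closure", 1.8)], pef=4.4)
        findings = detect_glottic_closure(man, idx)
        assert len(findings) == 1
        assert abs(findings[0].t_start - 1.8) <= 0.05

    def test_closure_before_one_second(self):
        man, idx = _sim([ArtifactSpec("glottic_closure", 0.7)])
        findings = detect_glottic_closure(man, idx)
        assert len(findings) == 1
        assert findings[0].t_start < 1.0


class TestFlutter:
    def test_clean_curve_is_silent(self, clean_exp):
        assert detect_flutter(clean_exp, compute_indices(clean_exp)) == []

    def test_injected_flutter_coverage(self):
        man, idx = _sim(
            [ArtifactSpec("flutter_obstruction", 1.0, 0.25, 1.0)], pef=4.0)
        findings = detect_flutter(man, idx)
        assert len(findings) == 1
        f = findings[0]
        covered = min(f.t_end, 2.0) - max(f.t_start, 1.0)
        assert covered >= 0.8

    def test_below_threshold_amplitude_silent(self):
        man, idx = _sim(
            [ArtifactSpec("flutter_obstruction", 1.0, 0.05, 1.0)], pef=4.0)
        assert detect_flutter(man, idx) == []


class TestEarlyTermination:
    def test_truncated_ramp_flagged_over_final_window(self):
        man = ramp_maneuver()
        idx = compute_indices(man)
        findings = detect_early_termination(man, idx)
        assert len(findings) == 1
        assert findings[0].t_start == pytest.approx(max(0.0, idx.fet - 1.0),
                                                    abs=0.05)
        assert findings[0].t_end == pytest.approx(idx.t_end, abs=0.02)

    def test_full_exponential_silent(self, clean_exp):
        assert detect_early_termination(
            clean_exp, compute_indices(clean_exp)) == []

    def test_long_slow_maneuver_satisfies_fet_branch(self):
        t = 0.01 * np.arange(1551)  # 15.5 s at constant low flow
        man = Maneuver("slow", t, 0.3 * t, np.full_like(t, 0.3))
        idx = compute_indices(man)
        assert not idx.plateau
        assert detect_early_termination(man, idx) == []


class TestExtraBreath:
    def test_monotone_exhalation_silent(self, clean_exp):
        assert detect_extra_breath(clean_exp) == []

    def test_injected_inspiration_with_resumption(self):
        man, _ = _sim([ArtifactSpec("extra_breath", 3.0, 0.2, 0.3)], pef=3.2)
        findings = detect_extra_breath(man)
        assert len(findings) == 1
        assert findings[0].t_start <= 3.05 <= findings[0].t_end + 0.3

    def test_terminal_inspiration_not_flagged(self):
        # inspiration at the very end, never resumed: recording just ends
        t = 0.01 * np.arange(301)
        flow = np.where(t < 2.5, 2.0 * np.exp(-t / 0.8), -0.8)
        vol = np.concatenate(
            ([0.0], np.cumsum((flow[1:] + flow[:-1]) * 0.005)))
        man = Maneuver("ti", t, vol, flow)
        assert detect_extra_breath(man) == []


class TestStartQuality:
    def test_clean_start(self):
        assert detect_start_quality(_stub(bev=0.0, tpef=0.0)) == []

    def test_hesitant_start_threshold_arithmetic(self):
        findings = detect_start_quality(_stub(bev=0.25, fvc=4.0))
        assert [f.kind for f in findings] == ["hesitant_start"]

    def test_bev_within_fractional_limit(self):
        assert detect_start_quality(_stub(bev=0.15, fvc=4.0,
                                          tpef=0.05)) == []

    def test_variable_flow_without_hesitant_start(self):
        findings = detect_start_quality(_stub(bev=0.05, tpef=0.3))
        assert [f.kind for f in findings] == ["variable_flow"]


class TestScan:
    def test_clean_maneuver(self, clean_exp):
        assert scan_artifacts(clean_exp, compute_indices(clean_exp)) == []

    def test_cough_then_closure_ordered(self):
        man, idx = _sim([ArtifactSpec("cough", 0.6, 0.4),
                         ArtifactSpec("glottic_closure", 2.5)], pef=3.2)
        findings = scan_artifacts(man, idx)
        kinds = [f.kind for f in findings]
        assert "cough" in kinds and "glottic_closure" in kinds
        assert kinds.index("cough") < kinds.index("glottic_closure")
        assert findings == sorted(findings, key=lambda f: f.t_start)

    def test_findings_lie_within_record(self):
        man, idx = _sim([ArtifactSpec("cough", 0.5, 0.4),
                         ArtifactSpec("extra_breath", 2.0, 0.2, 0.3)],
                        pef=5.2, noise=0.02, seed=3)
        for f in scan_artifacts(man, idx):
            assert 0.0 <= f.t_start < f.t_end <= man.t[-1] + 1e-9

    def test_deterministic(self):
        man, idx = _sim([ArtifactSpec("cough", 0.6, 0.4)], noise=0.02,
                        seed=9)
        a = scan_artifacts(man, idx)
        b = scan_artifacts(man, idx)
        assert a == b

    def test_translation_invariance(self):
        man, idx = _sim([ArtifactSpec("cough", 0.6, 0.4)])
        base = scan_artifacts(man, idx)
        n_pre = 25  # 0.25 s of quiet baseline
        dt = man.sample_interval
        t = dt * np.arange(len(man.t) + n_pre)
        vol = np.concatenate([np.zeros(n_pre), man.volume])
        flow = np.concatenate([np.zeros(n_pre), man.flow])
        man2 = Maneuver("shift", t, vol, flow)
        shifted = scan_artifacts(man2, compute_indices(man2))
        assert [f.kind for f in shifted] == [f.kind for f in base]
        for f0, f1 in zip(base, shifted):
            assert f1.t_start - f0.t_start == pytest.approx(0.25, abs=0.05)
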