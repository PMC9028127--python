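"""Threshold configuration for the QC pipeline.

Every quantitative criterion used by the rule checks, the artifact
detectors, and the grading tiers lives here so that a site can override it
without touching code.  Defaults follow the ATS/ERS 2019 technical standard
for the acceptability/usability/grading quantities (back-extrapolated
volume, plateau, FET, repeatability tiers); detector thresholds are this
package's documented surrogates for visual inspection (see docs/methods.md).

Units: volumes in liters, flows in liters/second, times in seconds.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass(frozen=True)
class QCConfig:
    # --- start of test ---------------------------------------------------
    #: absolute back-extrapolated volume limit (L)
    bev_abs: float = 0.100
    #: fractional BEV limit as a fraction of FVC
    bev_frac: float = 0.05
    #: maximum acceptable time to peak flow (s) before variable_flow is flagged
    tpef_max: float = 0.15
    #: samples in the moving-average smoother used for slopes and detectors
    smooth_window: int = 5

    # --- end of forced expiration ----------------------------------------
    #: maximum volume change over the trailing plateau window (L)
    plateau_dv: float = 0.025
    #: trailing window length for the plateau test (s)
    plateau_window: float = 1.0
    #: FET at or above which EOFE is met regardless of plateau (s)
    fet_long: float = 15.0
    #: flow floor below which expiration is considered ended (L/s)
    zero_flow_floor: float = 0.025
    #: session FVC repeatability tolerance for the EOFE branch (L)
    fvc_repeat_tol: float = 0.150
    #: minimum duration of a negative-flow segment treated as inspiration (s)
    neg_sustain: float = 0.20

    # --- session grading tiers (adult, then age <= ped_age_max) -----------
    tier_ab: float = 0.150
    tier_c: float = 0.200
    tier_d: float = 0.250
    ped_age_max: float = 6.0
    ped_tier_ab: float = 0.100
    ped_tier_c: float = 0.150
    ped_tier_d: float = 0.200

    # --- artifact detectors ----------------------------------------------
    #: running-median window defining the local flow envelope (s)
    envelope_window: float = 0.3
    #: trailing-maximum window for the cough reference level (s); must just
    #: exceed half a cough transient so the dip cannot drag its own reference
    cough_env_window: float = 0.08
    cough_drop_frac: float = 0.25
    cough_recover_frac: float = 0.15
    cough_window: float = 0.5
    #: minimum envelope flow for a cough candidate (L/s); guards the tail
    cough_min_env: float = 0.25
    gc_high_frac: float = 0.10
    gc_drop_window: float = 0.1
    gc_hold: float = 0.25
    #: heavier smoother for the below-floor test of the closure detector
    gc_smooth_window: int = 11
    flutter_band_lo: float = 5.0
    flutter_band_hi: float = 15.0
    flutter_frac: float = 0.15
    flutter_min_dur: float = 0.3
    #: minimum envelope flow for flutter assessment (L/s)
    flutter_min_flow: float = 0.30
    #: window of the RMS oscillation-amplitude tracker (s)
    flutter_rms_window: float = 0.2
    eb_flow: float = 0.05
    eb_dur: float = 0.15
    #: flow level counting as resumed expiration after an extra breath (L/s)
    eb_resume_flow: float = 0.10
    eb_resume_dur: float = 0.10

    # --- raw-data consistency --------------------------------------------
    #: tolerated |flow - dV/dt| after smoothing before a warning is issued
    flow_consistency_tol: float = 0.05

    def with_overrides(self, **overrides: float) -> "QCConfig":
        """Return a copy with the given keys replaced."""
        unknown = set(overrides) - {f.name for f in dataclasses.fields(self)}
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "QCConfig":
        return cls().with_overrides(**d)

    @classmethod
    def from_file(cls, path) -> "QCConfig":
        """Load overrides from a JSON config file."""
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))


DEFAULT_CONFIG = QCConfig()
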