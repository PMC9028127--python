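"""Shared fixtures: canonical closed-form maneuvers and simulated sessions."""

import numpy as np
import pytest

from spiroqc import Maneuver, ManeuverSpec, QCConfig, generate_maneuver


@pytest.fixture(autouse=True)
def _quiet_flow_warnings():
    """Idealized closed-form fixtures have sharp starts; the flow/dV-dt
    consistency warning is expected noise here."""
    import warnings
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message=".*flow deviates from dV/dt.*")
        yield


@pytest.fixture
def config():
    return QCConfig()


def exp_maneuver(fvc=4.0, tau=0.4, t_max=12.0, dt=0.01, mid="exp"):
    """V(t) = fvc (1 - e^{-t/tau}) with the exact flow channel."""
    t = dt * np.arange(int(round(t_max / dt)) + 1)
    vol = fvc * (1.0 - np.exp(-t / tau))
    flow = (fvc / tau) * np.exp(-t / tau)
    return Maneuver(maneuver_id=mid, t=t, volume=vol, flow=flow,
                    sample_interval=dt)


def ramp_maneuver(slope=2.0, t_max=1.0, dt=0.01, shift=0.0, mid="ramp"):
    """V(t) = slope * max(0, t - shift), truncated at t_max."""
    t = dt * np.arange(int(round(t_max / dt)) + 1)
    vol = slope * np.maximum(0.0, t - shift)
    flow = np.where(t >= shift, slope, 0.0)
    return Maneuver(maneuver_id=mid, t=t, volume=vol, flow=flow,
                    sample_interval=dt)


@pytest.fixture
def clean_exp():
    return exp_maneuver()


@pytest.fixture
def clean_sim():
    """Noise-free simulated clean maneuver matching V=4(1-e^{-t/0.4})."""
    man, truth = generate_maneuver(
        ManeuverSpec(fvc_true=4.0, pef_true=10.0, tau=0.4, rise_time=0.0,
                     noise_sd=0.0))
    return man, truth
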