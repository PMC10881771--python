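import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import mitrasim as ms

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def quiet_config() -> ms.RigConfig:
    """Default rig, noise off, short run — the workhorse for exact checks."""
    return ms.RigConfig(noise_sd_mmhg=0.0, noise_sd_ml_s=0.0, duration_s=10.0)


@pytest.fixture(scope="session")
def quiet_run(quiet_config):
    """(stream, truth) of the competent noise-free default rig."""
    return ms.simulate(quiet_config)


@pytest.fixture(scope="session")
def noisy_run():
    """(stream, truth) of the default rig with sensor noise, seed 1."""
    return ms.simulate(ms.RigConfig(duration_s=10.0, seed=1))


def synthetic_stream(
    n_periods: float = 3.0,
    fs: float = 150.0,
    hr: float = 80.0,
    sbp: float = 100.0,
    p_atm: float = 760.0,
    la_gauge: float = 20.0,
    tmg: float = 2.0,
    q_peak: float = 300.0,
) -> ms.SensorStream:
    """Analytic stream with a rectangular-ish systole for unit tests.

    Systole occupies the first 35 % of each cycle: LV pressure rises as a
    half-sine to ``sbp`` gauge while LA stays at its baseline; in diastole
    LV sits ``tmg`` below LA.  Aortic flow is a half-sine during systole.
    """
    period = 60.0 / hr
    n = int(round(n_periods * period * fs)) + 1
    t = np.arange(n) / fs
    phase = (t % period) / period
    in_sys = phase < 0.35
    p_la = np.full(n, p_atm + la_gauge)
    p_lv = np.where(
        in_sys,
        p_atm + la_gauge + (sbp - la_gauge) * np.sin(np.pi * phase / 0.35),
        p_atm + la_gauge - tmg,
    )
    q = np.where(in_sys, q_peak * np.sin(np.pi * phase / 0.35), 0.0)
    return ms.SensorStream(
        t=t, p_la_abs=p_la, p_lv_abs=p_lv, q_aortic=q, fs_hz=fs, meta={"synthetic": True}
    )
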