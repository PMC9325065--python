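import numpy as np
import pandas as pd
import pytest

import shootflux as sf


@pytest.fixture(scope="session")
def chamber() -> sf.ChamberSpec:
    return sf.ChamberSpec()


@pytest.fixture(scope="session")
def quiet_truth() -> sf.TruthParams:
    """Noise-free, leak-free truth: the self-consistency limit."""
    return sf.TruthParams(noise_sd_ch4=0.0, noise_sd_co2=0.0, noise_sd_h2o=0.0)


@pytest.fixture(scope="session")
def pine_shoot() -> sf.ShootBiomass:
    return sf.ShootBiomass("pine1", "pine", m_y1=20.0, m_y0_final=3.0)


@pytest.fixture(scope="session")
def midday_met() -> dict:
    return {"par": 800.0, "global_radiation": 380.0, "air_temp": 12.0}


def make_linear_closure(
    slope_ppm_s: float = 1e-5,
    duration: float = 480.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 2.0,
    temp_k: float = 293.15,
) -> sf.ClosureSeries:
    """Minimal synthetic closure with a known linear CH4 trend."""
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0)
    ch4 = intercept + slope_ppm_s * t
    if noise_sd:
        ch4 = ch4 + rng.normal(0, noise_sd, len(t))
    data = pd.DataFrame(
        {
            "t": t,
            "ch4_dry_raw": ch4,
            "co2": np.full_like(t, 420.0),
            "h2o": np.full_like(t, 9000.0),
            "sample_temp": np.full_like(t, temp_k),
        }
    )
    return sf.ClosureSeries("CH1", "pine1", "pine", data)


@pytest.fixture(scope="session")
def small_noisefree_campaign(quiet_truth):
    cfg = sf.CampaignConfig(n_weeks=2, truth=quiet_truth)
    return sf.gen_campaign(cfg, seed=42)


@pytest.fixture(scope="session")
def default_campaign():
    """Default-noise four-week campaign shared across statistics tests."""
    return sf.gen_campaign(sf.CampaignConfig(n_weeks=4), seed=7)


@pytest.fixture(scope="session")
def default_processed(default_campaign):
    return sf.process_campaign(default_campaign)
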