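"""The synthetic campaign generator: determinism, structure, self-consistency."""

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

import shootflux as sf


# --- meteorology ------------------------------------------------------------


def _quiet_meteo_params(**overrides):
    base = dict(cloudiness=0.0, temp_noise_sd=0.0, gr_noise_frac=0.0,
                par_temp_coupling=0.0, rain_prob=0.0)
    base.update(overrides)
    return sf.MeteoParams(**base)


def test_noiseless_meteo_is_exact_sinusoid():
    m = sf.gen_meteo(2, _quiet_meteo_params(par_seasonal_start_frac=1.0), seed=0)
    midnight = m[m["timestamp"].dt.hour == 0]
    assert (midnight["par"] == 0.0).all()
    noon = m[(m["timestamp"].dt.hour == 12) & (m["timestamp"].dt.minute == 0)]
    assert noon["par"].iloc[0] == pytest.approx(1400.0)


def test_global_radiation_collinear_with_par():
    m = sf.gen_meteo(90, seed=1)
    day = m[m["par"] > 0]
    ols = sm.OLS(day["global_radiation"], sm.add_constant(day["par"])).fit()
    assert ols.rsquared > 0.97


def test_zero_coupling_decorrelates_daily_par_and_temp():
    p = sf.MeteoParams(par_temp_coupling=0.0, par_seasonal_start_frac=1.0,
                       temp_start=8.0, temp_end=8.0)
    m = sf.gen_meteo(90, p, seed=2)
    daily = m.set_index("timestamp").resample("1D").mean()
    r = np.corrcoef(daily["par"], daily["air_temp"])[0, 1]
    assert abs(r) < 0.1


def test_positive_coupling_induces_covariance():
    m = sf.gen_meteo(90, sf.MeteoParams(par_temp_coupling=6.0), seed=2)
    daily = m.set_index("timestamp").resample("1D").mean()
    assert np.corrcoef(daily["par"], daily["air_temp"])[0, 1] > 0.2


def test_nonpositive_duration_rejected():
    with pytest.raises(ValueError):
        sf.gen_meteo(0)


# --- single closures --------------------------------------------------------


def test_null_closure_is_constant(chamber):
    truth = sf.TruthParams(
        base_emission=0.0, par_slope_intercept=0.0, par_slope_temp_gain=0.0,
        background_mean=0.0, interference_f_true=0.0,
        noise_sd_ch4=0.0, noise_sd_co2=0.0, noise_sd_h2o=0.0,
    )
    met = {"par": 0.0, "global_radiation": 0.0, "air_temp": 10.0}
    series, flux = sf.gen_closure(truth, chamber, None, met, seed=0)
    assert flux == 0.0
    assert series.data["ch4_dry_raw"].nunique() == 1


def test_interference_shifts_reported_change_by_f_times_h2o(chamber, quiet_truth, pine_shoot, midday_met):
    """With f = -9.122e-7 and ~10 000 ppm of H2O rise, the reported CH4
    change over the closure is more negative than the true change by
    ~9.122e-3 ppm."""
    series, _ = sf.gen_closure(
        quiet_truth, chamber, pine_shoot, midday_met, needle_mass_g=22.0,
        h2o_start_ppm=6000.0, h2o_ceiling_ppm=16000.0, h2o_rate=0.02, seed=0,
    )
    d = series.data
    h2o_rise = d["h2o"].iloc[-1] - d["h2o"].iloc[0]
    assert h2o_rise == pytest.approx(10000.0, rel=0.001)
    raw_change = d["ch4_dry_raw"].iloc[-1] - d["ch4_dry_raw"].iloc[0]
    corr = sf.correct_h2o(series, quiet_truth.interference_f_true).data
    true_change = corr["ch4_dry_corr"].iloc[-1] - corr["ch4_dry_corr"].iloc[0]
    assert raw_change - true_change == pytest.approx(-9.122e-3, rel=0.001)


def test_round_trip_within_three_ses_at_default_noise(chamber, pine_shoot, midday_met):
    truth = sf.TruthParams(base_emission=10.0, par_slope_intercept=0.0,
                           par_slope_temp_gain=0.0, background_mean=0.0)
    series, true_flux = sf.gen_closure(
        truth, chamber, pine_shoot, midday_met, needle_mass_g=23.0, seed=17
    )
    assert true_flux == 10.0
    proc = sf.qc_closure(
        sf.trim_closure(sf.correct_h2o(series, truth.interference_f_true))
    )
    fit = sf.fit_linear_slope(proc)
    est = sf.slope_to_flux(
        fit.slope, chamber, "CH4", 23.0,
        float(proc.trimmed()["sample_temp"].mean()), slope_se=fit.slope_se,
    )
    se_dw = fit.slope_se / fit.slope * abs(est.dw_flux)
    assert abs(est.dw_flux - true_flux) <= 3 * se_dw


def test_leakage_attenuates_accumulation(chamber, pine_shoot, midday_met):
    quiet = dict(noise_sd_ch4=0.0, noise_sd_co2=0.0, noise_sd_h2o=0.0,
                 interference_f_true=0.0)
    tight, _ = sf.gen_closure(
        sf.TruthParams(leak_rate=0.0, **quiet), chamber, pine_shoot, midday_met,
        needle_mass_g=22.0, seed=0,
    )
    leaky, _ = sf.gen_closure(
        sf.TruthParams(leak_rate=0.005, **quiet), chamber, pine_shoot, midday_met,
        needle_mass_g=22.0, seed=0,
    )
    rise_tight = tight.data["ch4_dry_raw"].iloc[-1] - tight.data["ch4_dry_raw"].iloc[0]
    rise_leaky = leaky.data["ch4_dry_raw"].iloc[-1] - leaky.data["ch4_dry_raw"].iloc[0]
    assert 0 < rise_leaky < rise_tight


def test_invalid_truth_params_rejected():
    with pytest.raises(ValueError):
        sf.TruthParams(noise_sd_ch4=-1.0)
    with pytest.raises(ValueError):
        sf.TruthParams(leak_rate=0.5)


# --- campaigns --------------------------------------------------------------


def test_campaign_counts_match_schedule_arithmetic():
    cfg = sf.CampaignConfig(n_weeks=6)
    camp = sf.gen_campaign(cfg, seed=3)
    counts = camp.metadata.groupby("species").size()
    n_rounds = len(cfg.measurement_day_offsets()) * cfg.rounds_per_day
    assert counts["pine"] == cfg.n_pine * n_rounds
    assert counts["spruce"] == cfg.n_spruce * len(cfg.measurement_day_offsets())
    assert counts[sf.EMPTY] == n_rounds


def test_first_year_preset_counts_near_reported_study_sizes():
    """The first-year-style schedule lands within 10% of the 181 pine /
    53 spruce closure counts of the study it emulates."""
    camp = sf.gen_campaign(sf.CampaignConfig.campaign_2019(), seed=4)
    counts = camp.metadata.groupby("species").size()
    assert abs(counts["pine"] - 181) / 181 <= 0.10
    assert abs(counts["spruce"] - 53) / 53 <= 0.10


def test_empty_campaign_has_only_blank_closures():
    camp = sf.gen_campaign(sf.CampaignConfig(n_weeks=1, n_pine=0, n_spruce=0), seed=0)
    assert (camp.metadata["species"] == sf.EMPTY).all()
    assert len(camp.closures) > 0


def test_blank_closure_leads_every_round():
    camp = sf.gen_campaign(sf.CampaignConfig(n_weeks=1), seed=5)
    by_start = camp.metadata.sort_values("start_time")
    round_of = np.searchsorted([12, 15], by_start["start_time"].dt.hour, side="right")
    rounds = by_start.groupby([by_start["start_time"].dt.date, round_of])
    for _, grp in rounds:
        assert grp.iloc[0]["species"] == sf.EMPTY


def _tree_hash(root: Path) -> str:
    h = hashlib.sha256()
    for f in sorted(root.rglob("*")):
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()


def test_same_seed_gives_byte_identical_files(tmp_path):
    for sub in ("a", "b"):
        camp = sf.gen_campaign(sf.CampaignConfig(n_weeks=1), seed=9)
        sf.write_campaign(camp, tmp_path / sub)
    assert _tree_hash(tmp_path / "a") == _tree_hash(tmp_path / "b")


def test_different_seed_changes_output(tmp_path):
    sf.write_campaign(sf.gen_campaign(sf.CampaignConfig(n_weeks=1), seed=1), tmp_path / "a")
    sf.write_campaign(sf.gen_campaign(sf.CampaignConfig(n_weeks=1), seed=2), tmp_path / "b")
    assert _tree_hash(tmp_path / "a") != _tree_hash(tmp_path / "b")


def test_empty_chamber_apparent_fluxes_match_configured_background(chamber):
    """Mean of 50 processed blank closures tracks the configured background;
    their spread tracks the analyser-noise slope uncertainty."""
    truth = sf.TruthParams()
    met = {"par": 400.0, "global_radiation": 190.0, "air_temp": 10.0}
    rng = np.random.default_rng(33)
    fluxes = []
    for _ in range(50):
        series, _ = sf.gen_closure(truth, chamber, None, met, seed=rng)
        proc = sf.qc_closure(
            sf.trim_closure(sf.correct_h2o(series, truth.interference_f_true))
        )
        est = sf.flux_from_closure(proc, chamber, "CH4", None)
        fluxes.append(est.chamber_flux)
    fluxes = np.asarray(fluxes)
    # predicted SE of the fitted slope, propagated to flux units
    t = np.arange(30.0, 480.0)
    sigma_slope = truth.noise_sd_ch4 / np.sqrt(np.sum((t - t.mean()) ** 2))
    sigma_flux = sigma_slope * 1e-6 * chamber.air_moles(283.15) * 1.604e10 * 3600
    assert abs(fluxes.mean() - truth.background_mean) <= 4 * sigma_flux / np.sqrt(50)
    assert 0.6 * sigma_flux <= fluxes.std(ddof=1) <= 1.5 * sigma_flux
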