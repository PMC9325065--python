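"""Synthetic measurement campaigns with known ground truth.

Generates everything the processing pipeline consumes — meteorology,
shoot biomass and growth, analyser closure time series, and leading
empty-chamber blanks — from a configurable truth model:

* shoot CH4 emission (ng gDW^-1 h^-1) linear in PAR with a
  temperature-dependent slope: ``F = base + (a0 + a1 T) PAR + u_tree``,
  where ``u_tree`` is a per-tree random intercept drawn once per campaign;
* empty-chamber background either constant or linear in global radiation;
* CO2 drawn down exponentially toward a light-dependent asymptote;
* H2O rising toward a saturation ceiling, leaking into the reported dry
  CH4 channel through a spectral-interference coefficient ``f_true`` so
  that the standard correction with ``f = f_true`` recovers the truth;
* optional first-order chamber leakage toward ambient.

Everything is driven by one seed; identical configuration and seed give
byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .closures import EMPTY, ClosureSeries
from .fluxes import ChamberSpec, M_CH4_NG, M_CO2_MG, PPM
from .phenology import ShootBiomass, gdd_accumulate, relative_growth

CH4_AMBIENT_PPM = 1.97
CO2_AMBIENT_PPM = 420.0


@dataclass
class TruthParams:
    """Ground-truth process parameters for a simulated campaign.

    The PAR slope of the emission model at air temperature T is
    ``a0 + a1*T`` (ng gDW^-1 h^-1 per umol m^-2 s^-1); defaults put the
    slope at 10 C near 0.004, with a positive temperature gain so the
    light response steepens in warm conditions.
    """

    base_emission: float = 1.0  # ng gDW^-1 h^-1 at PAR = 0
    par_slope_intercept: float = 0.002  # a0
    par_slope_temp_gain: float = 0.0002  # a1, per degree C
    background_mode: str = "constant"  # "constant" | "radiation"
    background_mean: float = 11.76  # ng h^-1
    background_rad_slope: float = 0.06  # ng h^-1 per W m^-2
    interference_f_true: float = -9.122e-7  # ppm CH4 per ppm H2O
    leak_rate: float = 0.0  # fraction of headspace exchanged per s
    noise_sd_ch4: float = 0.0005  # ppm, 1-s analyser noise
    noise_sd_co2: float = 0.3  # ppm
    noise_sd_h2o: float = 5.0  # ppm
    random_intercept_sd: float = 1.0  # ng gDW^-1 h^-1 between trees
    mixing_transient_ppm: float = 0.0  # startup artefact amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.noise_sd_ch4, self.noise_sd_co2, self.noise_sd_h2o) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not 0.0 <= self.leak_rate <= 0.01:
            raise ValueError("leak_rate must lie in [0, 0.01]")

    def true_dw_flux(self, par: float, air_temp: float, tree_intercept: float = 0.0) -> float:
        """Shoot emission truth (ng gDW^-1 h^-1) at given PAR and temperature."""
        slope = self.par_slope_intercept + self.par_slope_temp_gain * air_temp
        return self.base_emission + slope * par + tree_intercept

    def background_flux(self, global_radiation: float) -> float:
        """Empty-chamber truth (ng h^-1)."""
        if self.background_mode == "radiation":
            return self.background_mean + self.background_rad_slope * (
                global_radiation - 150.0
            )
        return self.background_mean


@dataclass
class MeteoParams:
    """Diel + seasonal weather model for the campaign site."""

    start_date: str = "2020-03-06"
    averaging_window_s: int = 300
    par_max: float = 1400.0  # clear-sky midday PAR at campaign end
    par_seasonal_start_frac: float = 0.6  # midday PAR fraction on day 1
    cloudiness: float = 0.35  # SD of the daily attenuation draw
    temp_start: float = 2.0  # seasonal daily-mean ramp, deg C
    temp_end: float = 14.0
    temp_diel_amp: float = 4.0
    temp_noise_sd: float = 1.5  # day-to-day temperature noise
    par_temp_coupling: float = 6.0  # deg C per unit daily attenuation anomaly
    c_conv: float = 2.1  # umol J^-1, PAR per global radiation
    gr_noise_frac: float = 0.02  # sensor scatter between the two radiometers
    rain_prob: float = 0.25
    rain_mean_mm: float = 3.0


def gen_meteo(days: int, params: MeteoParams | None = None, seed: int = 0) -> pd.DataFrame:
    """Simulate the site weather record.

    Returns a frame with ``timestamp, par, global_radiation, air_temp,
    precipitation`` at the configured averaging window.  PAR is a clipped
    diel sinusoid scaled by a seasonal ramp and a per-day cloud attenuation;
    global radiation is PAR / c_conv with small sensor scatter, keeping the
    two collinear (R^2 > 0.97) as at a real station; air temperature is a
    seasonal ramp plus a diel cycle, day-to-day noise, and an optional
    coupling to the daily cloud anomaly that induces the PAR-temperature
    covariance the driver analysis must untangle.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    p = params or MeteoParams()
    rng = np.random.default_rng(seed)
    step = p.averaging_window_s
    times = pd.date_range(p.start_date, periods=days * 86400 // step, freq=f"{step}s")
    day_idx = ((times - times[0]).total_seconds() // 86400).astype(int)
    hod = times.hour + times.minute / 60.0 + times.second / 3600.0

    season = p.par_seasonal_start_frac + (1 - p.par_seasonal_start_frac) * day_idx / max(
        days - 1, 1
    )
    cloud_anom = rng.normal(0.0, p.cloudiness, size=days)
    atten = np.clip(1.0 - np.abs(cloud_anom), 0.05, 1.0)
    diel = np.maximum(0.0, np.sin(np.pi * (hod - 6.0) / 12.0))
    par = p.par_max * season * atten[day_idx] * diel

    t_season = p.temp_start + (p.temp_end - p.temp_start) * day_idx / max(days - 1, 1)
    t_diel = p.temp_diel_amp * -np.cos(2 * np.pi * (hod - 2.0) / 24.0)
    t_day_noise = rng.normal(0.0, p.temp_noise_sd, size=days)
    t_couple = p.par_temp_coupling * (atten - np.mean(atten)) if p.par_temp_coupling else np.zeros(days)
    air_temp = t_season + t_diel + (t_day_noise + t_couple)[day_idx]

    gr = par / p.c_conv
    if p.gr_noise_frac > 0:
        gr = gr * (1.0 + rng.normal(0.0, p.gr_noise_frac, size=len(gr)))
    rain_day = rng.binomial(1, p.rain_prob, size=days) * rng.exponential(
        p.rain_mean_mm, size=days
    )
    precipitation = np.where(
        (hod >= 12) & (hod < 12 + step / 3600.0), rain_day[day_idx], 0.0
    )
    return pd.DataFrame(
        {
            "timestamp": times,
            "par": par,
            "global_radiation": np.maximum(gr, 0.0),
            "air_temp": air_temp,
            "precipitation": precipitation,
        }
    )


def _dw_flux_to_slope_ppm_s(
    flux_ng_h: float, chamber: ChamberSpec, temp_k: float
) -> float:
    """Invert the flux equation: chamber flux (ng h^-1) -> CH4 slope (ppm/s)."""
    n_air = chamber.air_moles(temp_k)
    return flux_ng_h / (3600.0 * n_air * M_CH4_NG) / PPM


def gen_closure(
    truth: TruthParams,
    chamber: ChamberSpec,
    shoot: ShootBiomass | None,
    meteo_at_closure: dict,
    duration_s: float = 480.0,
    needle_mass_g: float | None = None,
    tree_intercept: float = 0.0,
    seed: int | np.random.Generator = 0,
    chamber_id: str = "CH1",
    closure_id: str = "",
    start_time: pd.Timestamp | None = None,
    co2_uptake_ppm_max: float = 60.0,
    co2_par_half: float = 300.0,
    co2_k: float = 0.004,
    h2o_start_ppm: float = 8000.0,
    h2o_ceiling_ppm: float = 16000.0,
    h2o_rate: float = 0.006,
) -> tuple[ClosureSeries, float]:
    """Simulate one chamber closure at 1 Hz.

    True dry CH4 accumulates linearly at the rate implied by the configured
    flux (with optional first-order leakage toward ambient); CO2 relaxes
    exponentially toward a PAR-dependent asymptote; H2O saturates toward a
    ceiling, and the *reported* dry CH4 adds ``f_true * H2O(t)`` so the
    downstream interference correction is exercised; Gaussian noise last.

    Returns the closure and the true shoot flux (ng gDW^-1 h^-1; for empty
    chambers the true chamber-level background flux in ng h^-1).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    par = float(meteo_at_closure["par"])
    gr = float(meteo_at_closure["global_radiation"])
    air_temp = float(meteo_at_closure["air_temp"])
    temp_k = air_temp + 273.15
    t = np.arange(0.0, duration_s, 1.0)

    background = truth.background_flux(gr)
    if shoot is None:
        chamber_flux = background
        true_flux = background
    else:
        if needle_mass_g is None:
            needle_mass_g = shoot.m_total_final
        true_flux = truth.true_dw_flux(par, air_temp, tree_intercept)
        chamber_flux = true_flux * needle_mass_g + background

    slope = _dw_flux_to_slope_ppm_s(chamber_flux, chamber, temp_k)
    lam = truth.leak_rate
    if lam > 0:  # dC/dt = S - lam (C - C_amb), C(0) = C_amb
        ch4_true = CH4_AMBIENT_PPM + (slope / lam) * (1.0 - np.exp(-lam * t))
    else:
        ch4_true = CH4_AMBIENT_PPM + slope * t

    clim = CO2_AMBIENT_PPM - co2_uptake_ppm_max * par / (par + co2_par_half)
    co2 = clim + (CO2_AMBIENT_PPM - clim) * np.exp(-co2_k * t)
    co2_slope0 = -co2_k * (CO2_AMBIENT_PPM - clim)  # ppm/s at sealing
    co2_chamber_flux = co2_slope0 * PPM * chamber.air_moles(temp_k) * M_CO2_MG * 3600.0
    h2o = h2o_ceiling_ppm - (h2o_ceiling_ppm - h2o_start_ppm) * np.exp(-h2o_rate * t)

    ch4_reported = ch4_true + truth.interference_f_true * h2o
    if truth.mixing_transient_ppm:
        ch4_reported = ch4_reported + truth.mixing_transient_ppm * np.exp(-t / 8.0)
    if truth.noise_sd_ch4:
        ch4_reported = ch4_reported + rng.normal(0, truth.noise_sd_ch4, len(t))
    if truth.noise_sd_co2:
        co2 = co2 + rng.normal(0, truth.noise_sd_co2, len(t))
    if truth.noise_sd_h2o:
        h2o = h2o + rng.normal(0, truth.noise_sd_h2o, len(t))

    data = pd.DataFrame(
        {
            "t": t,
            "ch4_dry_raw": ch4_reported,
            "co2": co2,
            "h2o": h2o,
            "sample_temp": np.full_like(t, temp_k),
        }
    )
    series = ClosureSeries(
        chamber_id=chamber_id,
        shoot_id=shoot.shoot_id if shoot is not None else EMPTY,
        species=shoot.species if shoot is not None else EMPTY,
        data=data,
        closure_id=closure_id,
        start_time=start_time,
        meta={
            "par": par,
            "global_radiation": gr,
            "air_temp": air_temp,
            "needle_mass_g": needle_mass_g,
            "true_co2_chamber_flux": co2_chamber_flux,
            "true_co2_dw_flux": (
                None if needle_mass_g is None else co2_chamber_flux / needle_mass_g
            ),
        },
    )
    return series, true_flux


def gen_injection_run(
    f_true: float = -9.122e-7,
    duration_s: float = 300.0,
    noise_sd_ch4: float = 0.0008,
    seed: int | np.random.Generator = 0,
) -> ClosureSeries:
    """Simulate one water-injection calibration run: actual dry CH4 constant
    while H2O rises from near-dry to saturation, with the interference
    leaking into the reported channel."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = np.arange(0.0, duration_s, 1.0)
    h2o = 25000.0 - (25000.0 - 500.0) * np.exp(-0.015 * t)
    ch4 = CH4_AMBIENT_PPM + f_true * h2o + rng.normal(0, noise_sd_ch4, len(t))
    data = pd.DataFrame(
        {
            "t": t,
            "ch4_dry_raw": ch4,
            "co2": np.full_like(t, CO2_AMBIENT_PPM),
            "h2o": h2o,
            "sample_temp": np.full_like(t, 295.15),
        }
    )
    return ClosureSeries(chamber_id="CAL", shoot_id=EMPTY, species=EMPTY, data=data)


@dataclass
class CampaignConfig:
    """Schedule and population of a simulated campaign.

    Defaults emulate the 2019-style design: four pine and three spruce
    saplings, three measurement days per week with three rounds per day,
    every pine shoot in every round, spruce in the first round of each day
    only, and a blank (empty-chamber) closure leading every round.
    """

    n_weeks: int = 6
    n_days: int | None = None  # overrides n_weeks when set (partial weeks)
    days_per_week: int = 3
    day_spacing: int = 2  # calendar days between measurement days in a week
    rounds_per_day: int = 3
    round_hours: tuple = (9.0, 12.0, 15.0)
    n_pine: int = 4
    n_spruce: int = 3
    spruce_rounds_per_day: int = 1
    closure_duration_s: float = 480.0
    closure_gap_s: float = 120.0
    truth: TruthParams = field(default_factory=TruthParams)
    meteo: MeteoParams = field(default_factory=MeteoParams)
    chamber: ChamberSpec = field(default_factory=ChamberSpec)
    # needle-mass population (g DW); pine numbers give ~23 g average shoots
    pine_m_y1: float = 21.0
    pine_m_y0_final: float = 4.0
    spruce_m_y1: float = 5.0
    spruce_m_y0_final: float = 1.0
    mass_cv: float = 0.15
    growth_g50: float = 150.0
    growth_steepness: float = 0.03

    def __post_init__(self) -> None:
        if self.n_weeks < 1 and not self.n_days:
            raise ValueError("campaign must span at least one week")
        if self.n_pine < 0 or self.n_spruce < 0:
            raise ValueError("tree counts must be >= 0")

    @property
    def span_days(self) -> int:
        return self.n_days if self.n_days else self.n_weeks * 7

    def measurement_day_offsets(self) -> list[int]:
        """Calendar-day offsets of the measurement days within the span."""
        offsets = []
        w = 0
        while True:
            week_start = w * 7
            if week_start >= self.span_days:
                break
            for d in range(self.days_per_week):
                off = week_start + d * self.day_spacing
                if off < self.span_days:
                    offsets.append(off)
            w += 1
        return offsets

    @classmethod
    def campaign_2019(cls, **overrides) -> "CampaignConfig":
        """Preset emulating the first-year design: four pine shoots in all
        three daily rounds, three spruce in the first round only, three
        measurement days a week over a five-week-and-change campaign."""
        defaults = dict(
            n_days=36,
            meteo=MeteoParams(start_date="2019-04-01", averaging_window_s=900,
                              temp_start=5.0, temp_end=14.0),
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class Campaign:
    """A fully generated campaign with its ground truth."""

    config: CampaignConfig
    meteo: pd.DataFrame
    biomass: list[ShootBiomass]
    closures: list[ClosureSeries]
    metadata: pd.DataFrame  # one row per closure
    truth_table: pd.DataFrame  # per-closure true fluxes and tree intercepts
    tree_intercepts: dict[str, float]


def _daily_means(meteo: pd.DataFrame) -> pd.Series:
    by_day = meteo.set_index("timestamp")["air_temp"].resample("1D").mean()
    return by_day


def campaign_mass_series(
    biomass: ShootBiomass, meteo: pd.DataFrame, g50: float, steepness: float
) -> pd.Series:
    """Daily needle-mass series for one shoot from the campaign GDD record."""
    daily = _daily_means(meteo)
    gdd = gdd_accumulate(daily)
    rel = relative_growth(gdd, g50=g50, steepness=steepness)
    return pd.Series(
        biomass.m_y1 + rel.to_numpy() * biomass.m_y0_final, index=rel.index
    )


def gen_campaign(config: CampaignConfig | None = None, seed: int = 0) -> Campaign:
    """Generate a complete campaign: weather, shoots, schedule, closures.

    Per-tree random intercepts are drawn once; a blank closure leads every
    round; closures on one chamber never overlap (the schedule is validated).
    """
    config = config or CampaignConfig()
    rng = np.random.default_rng(seed)
    meteo = gen_meteo(config.span_days, config.meteo, seed=int(rng.integers(2**31)))

    biomass: list[ShootBiomass] = []
    for i in range(config.n_pine):
        biomass.append(
            ShootBiomass(
                shoot_id=f"pine{i + 1}",
                species="pine",
                m_y1=config.pine_m_y1 * max(rng.normal(1.0, config.mass_cv), 0.3),
                m_y0_final=config.pine_m_y0_final * max(rng.normal(1.0, config.mass_cv), 0.3),
            )
        )
    for i in range(config.n_spruce):
        biomass.append(
            ShootBiomass(
                shoot_id=f"spruce{i + 1}",
                species="spruce",
                m_y1=config.spruce_m_y1 * max(rng.normal(1.0, config.mass_cv), 0.3),
                m_y0_final=config.spruce_m_y0_final * max(rng.normal(1.0, config.mass_cv), 0.3),
            )
        )
    intercepts = {
        b.shoot_id: float(rng.normal(0.0, config.truth.random_intercept_sd))
        for b in biomass
    }
    mass_series = {
        b.shoot_id: campaign_mass_series(
            b, meteo, config.growth_g50, config.growth_steepness
        )
        for b in biomass
    }

    meteo_idx = meteo.set_index("timestamp")
    t0 = meteo["timestamp"].iloc[0].normalize()
    closures: list[ClosureSeries] = []
    meta_rows, truth_rows = [], []
    slot = config.closure_duration_s + config.closure_gap_s
    counter = 0
    last_end: dict[str, pd.Timestamp] = {}
    for day_offset in config.measurement_day_offsets():
        day = t0 + pd.Timedelta(days=day_offset)
        for r in range(config.rounds_per_day):
            start = day + pd.Timedelta(hours=config.round_hours[r % len(config.round_hours)])
            roster: list[ShootBiomass | None] = [None]  # blank leads the round
            for b in biomass:
                if b.species == "spruce" and r >= config.spruce_rounds_per_day:
                    continue
                roster.append(b)
            for k, shoot in enumerate(roster):
                c_start = start + pd.Timedelta(seconds=k * slot)
                c_end = c_start + pd.Timedelta(seconds=config.closure_duration_s)
                cid = f"C{counter:04d}"
                counter += 1
                chamber_id = "CH0" if shoot is None else f"CH_{shoot.shoot_id}"
                if chamber_id in last_end and c_start < last_end[chamber_id]:
                    raise ValueError(f"overlapping closures on chamber {chamber_id}")
                last_end[chamber_id] = c_end
                window = meteo_idx.loc[c_start:c_end]
                if window.empty:
                    window = meteo_idx.iloc[
                        meteo_idx.index.get_indexer([c_start], method="nearest")
                    ]
                met = {
                    "par": float(window["par"].mean()),
                    "global_radiation": float(window["global_radiation"].mean()),
                    "air_temp": float(window["air_temp"].mean()),
                }
                mass = None
                if shoot is not None:
                    ms = mass_series[shoot.shoot_id]
                    mass = float(ms.asof(c_start.normalize()))
                series, true_flux = gen_closure(
                    config.truth,
                    config.chamber,
                    shoot,
                    met,
                    duration_s=config.closure_duration_s,
                    needle_mass_g=mass,
                    tree_intercept=0.0 if shoot is None else intercepts[shoot.shoot_id],
                    seed=rng,
                    chamber_id=chamber_id,
                    closure_id=cid,
                    start_time=c_start,
                )
                closures.append(series)
                meta_rows.append(
                    {
                        "closure_id": cid,
                        "chamber_id": chamber_id,
                        "shoot_id": EMPTY if shoot is None else shoot.shoot_id,
                        "species": EMPTY if shoot is None else shoot.species,
                        "start_time": c_start,
                        "end_time": c_end,
                    }
                )
                truth_rows.append(
                    {
                        "closure_id": cid,
                        "shoot_id": EMPTY if shoot is None else shoot.shoot_id,
                        "true_flux": true_flux,
                        "true_co2_dw_flux": series.meta["true_co2_dw_flux"],
                        "needle_mass_g": mass,
                        "par": met["par"],
                        "global_radiation": met["global_radiation"],
                        "air_temp": met["air_temp"],
                    }
                )
    return Campaign(
        config=config,
        meteo=meteo,
        biomass=biomass,
        closures=closures,
        metadata=pd.DataFrame(meta_rows),
        truth_table=pd.DataFrame(truth_rows),
        tree_intercepts=intercepts,
    )


# ---------------------------------------------------------------------------
# file emission (the documented CSV dialects, version 1)

DIALECT_VERSION = 1


def write_campaign(campaign: Campaign, out_dir: str | Path) -> Path:
    """Write a campaign as the raw file set the pipeline ingests.

    Layout: ``raw/<closure_id>.csv`` analyser files (iso-8601 timestamp,
    ch4_dry_ppm, co2_ppm, h2o_ppm, sample_temp_K), ``closures.csv``,
    ``meteo.csv``, ``biomass.csv`` and ``truth.json`` (ground truth, for
    tests only).  Deterministic formatting: same campaign -> same bytes.
    """
    out = Path(out_dir)
    raw = out / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    for c in campaign.closures:
        ts = c.start_time + pd.to_timedelta(c.data["t"], unit="s")
        df = pd.DataFrame(
            {
                "timestamp": ts.dt.strftime("%Y-%m-%dT%H:%M:%S"),
                "ch4_dry_ppm": c.data["ch4_dry_raw"].map("{:.10f}".format),
                "co2_ppm": c.data["co2"].map("{:.6f}".format),
                "h2o_ppm": c.data["h2o"].map("{:.4f}".format),
                "sample_temp_K": c.data["sample_temp"].map("{:.5f}".format),
            }
        )
        df.to_csv(raw / f"{c.closure_id}.csv", index=False)
    campaign.metadata.to_csv(out / "closures.csv", index=False)
    m = campaign.meteo.copy()
    for col in ("par", "global_radiation", "air_temp", "precipitation"):
        m[col] = m[col].map("{:.5f}".format)
    m.to_csv(out / "meteo.csv", index=False)
    pd.DataFrame(
        [
            {
                "shoot_id": b.shoot_id,
                "species": b.species,
                "m_y1_g": f"{b.m_y1:.6f}",
                "m_y0_final_g": f"{b.m_y0_final:.6f}",
            }
            for b in campaign.biomass
        ]
    ).to_csv(out / "biomass.csv", index=False)
    truth = {
        "dialect_version": DIALECT_VERSION,
        "tree_intercepts": campaign.tree_intercepts,
        "truth_params": asdict(campaign.config.truth),
        "per_closure": campaign.truth_table.assign(
            needle_mass_g=campaign.truth_table["needle_mass_g"].astype(object).where(
                campaign.truth_table["needle_mass_g"].notna(), None
            )
        ).to_dict(orient="records"),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, default=float))
    return out
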