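"""Spring phenology, growing-degree-day shoot growth, and needle-mass tracking.

Flux normalization needs the needle dry mass inside the chamber on every
measuring day.  One-year-old (Y1) needles are constant; current-year (Y0)
needles grow during the campaign, so their final mass is scaled by a
relative-growth curve: measured shoot elongation where available, otherwise
a logistic model in cumulative growing degree days (GDD, base 5 degrees C)
rescaled to reach exactly 1 at campaign end.

Photosystem-II recovery is tracked through chlorophyll-a fluorescence as
Fv/Fm = (Fm - F0)/Fm, with ~0.8 the fully recovered summer value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize


@dataclass
class ShootBiomass:
    """Needle dry masses for one shoot: Y1 cohort and final Y0 cohort (g),
    with optional weekly shoot-elongation observations (date, mm)."""

    shoot_id: str
    species: str
    m_y1: float
    m_y0_final: float
    elongation: pd.DataFrame | None = None  # columns: date, length_mm

    def __post_init__(self) -> None:
        if self.m_y1 < 0 or self.m_y0_final < 0:
            raise ValueError("needle masses must be >= 0")

    @property
    def m_total_final(self) -> float:
        return self.m_y1 + self.m_y0_final


def fv_fm(f0: float, fm: float) -> float:
    """Maximum PSII quantum efficiency (Fm - F0)/Fm."""
    if fm <= 0:
        raise ValueError("Fm must be > 0")
    if f0 < 0:
        raise ValueError("F0 must be >= 0")
    if f0 > fm:
        raise ValueError("F0 exceeds Fm: saturating flash must exceed minimum fluorescence")
    return (fm - f0) / fm


def gdd_accumulate(
    daily_mean_temps: pd.Series | np.ndarray, base_c: float = 5.0
) -> pd.Series:
    """Cumulative growing degree days: running sum of max(0, T_mean - base).

    Accepts a date-indexed Series (index preserved) or a plain array.
    """
    temps = pd.Series(daily_mean_temps, dtype=float)
    return (temps - base_c).clip(lower=0.0).cumsum()


def logistic_growth(gdd: np.ndarray, g50: float, steepness: float) -> np.ndarray:
    """Unrescaled logistic elongation fraction 1/(1+exp(-s (GDD - g50)))."""
    if steepness <= 0:
        raise ValueError("steepness must be > 0")
    return 1.0 / (1.0 + np.exp(-steepness * (np.asarray(gdd, float) - g50)))


def relative_growth(
    gdd: pd.Series,
    g50: float = 150.0,
    steepness: float = 0.03,
    rescale: bool = True,
) -> pd.Series:
    """Relative Y0 elongation (fraction of final length) over the campaign.

    A two-parameter logistic in cumulative GDD, rescaled so the value at the
    last date is exactly 1 (the shoot has its final length when it is
    harvested and weighed).  Raises when there is no growth signal to
    rescale against (GDD never leaves zero).
    """
    curve = logistic_growth(gdd.to_numpy(), g50, steepness)
    if not rescale:
        return pd.Series(curve, index=gdd.index)
    if float(gdd.iloc[-1]) <= 0 or curve[-1] <= curve[0] + 1e-12:
        raise ValueError("no growth signal: GDD accumulation is degenerate")
    # anchor at the pre-season floor so the curve spans [0, 1]
    floor = logistic_growth(np.array([0.0]), g50, steepness)[0]
    scaled = (curve - floor) / (curve[-1] - floor)
    return pd.Series(np.clip(scaled, 0.0, 1.0), index=gdd.index)


def fit_growth_params(
    gdd_at_obs: np.ndarray, rel_measured: np.ndarray, g50_init: float = 150.0, s_init: float = 0.03
) -> tuple[float, float]:
    """Least-squares (g50, steepness) of the logistic against measured
    relative elongation at the observation dates."""

    def model(g, g50, s):
        return logistic_growth(g, g50, s)

    popt, _ = optimize.curve_fit(
        model,
        np.asarray(gdd_at_obs, float),
        np.asarray(rel_measured, float),
        p0=(g50_init, s_init),
        bounds=([1.0, 1e-4], [2000.0, 1.0]),
        maxfev=20000,
    )
    return float(popt[0]), float(popt[1])


def measured_relative_growth(elongation: pd.DataFrame) -> pd.Series:
    """Relative growth from measured shoot lengths: length on the day divided
    by length at campaign end, linearly interpolated between observations."""
    obs = elongation.sort_values("date")
    final = float(obs["length_mm"].iloc[-1])
    if final <= 0:
        raise ValueError("final shoot length must be > 0")
    return pd.Series(
        (obs["length_mm"] / final).to_numpy(), index=pd.DatetimeIndex(obs["date"])
    )


def needle_mass_at(
    date: pd.Timestamp, biomass: ShootBiomass, rel: pd.Series
) -> float:
    """Needle dry mass (g) in the chamber on ``date``.

    m(date) = m_y1 + rel(date) * m_y0_final, with ``rel`` the relative-growth
    series (measured-elongation based where observations exist, GDD-model
    based otherwise).  Dates before the series start return m_y1 (rel = 0);
    between entries the fraction is linearly interpolated.
    """
    date = pd.Timestamp(date)
    idx = pd.DatetimeIndex(rel.index)
    if date < idx[0]:
        frac = 0.0
    elif date >= idx[-1]:
        frac = float(rel.iloc[-1])
    else:
        frac = float(np.interp(date.value, idx.asi8.astype(float), rel.to_numpy(float)))
    return biomass.m_y1 + frac * biomass.m_y0_final


def validate_growth_model(measured_rel: pd.Series, model_rel: pd.Series) -> dict:
    """Agreement between measured and modelled relative-growth curves on
    their shared dates: RMSE and maximum absolute deviation."""
    shared = measured_rel.index.intersection(model_rel.index)
    if len(shared) < 4:
        raise ValueError("need >= 4 overlapping dates to validate the growth model")
    diff = measured_rel.loc[shared].to_numpy(float) - model_rel.loc[shared].to_numpy(float)
    return {
        "rmse": float(np.sqrt(np.mean(diff**2))),
        "max_abs_dev": float(np.max(np.abs(diff))),
        "n_dates": int(len(shared)),
    }
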