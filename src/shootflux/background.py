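"""Empty-chamber background modelling and the method-detection-limit ladder.

The chamber materials themselves release small amounts of CH4, so blank
("empty chamber") closures are run at the start of every measurement round.
Their apparent fluxes serve two purposes:

* a **background model** — either a campaign-constant mean or, when the
  blank flux tracks global radiation significantly, a linear regression on
  radiation — whose prediction is subtracted from every shoot-chamber flux
  on the chamber (ng h^-1) scale, *before* dry-weight normalization;
* the **method detection limit (MDL)** — three times the SD of the blank
  fluxes — which is scaled down the ladder: per chamber closure (ng h^-1),
  per measurement (divided by the species' average shoot dry weight), and
  per averaging period (further divided by sqrt(n) replicate measurements).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm

from .fluxes import FluxEstimate


@dataclass
class BackgroundModel:
    """Fitted empty-chamber CH4 background, constant or radiation-driven."""

    mode: str  # "constant_mean" | "radiation_regression"
    mean_flux: float
    mean_se: float
    slope: float  # ng h^-1 per W m^-2 (radiation mode)
    intercept: float
    sd_resid: float
    n_empty: int
    diagnostics: dict = field(default_factory=dict)

    def predict(self, global_radiation: float | None = None) -> float:
        """Background flux (ng h^-1) to subtract from one shoot closure."""
        if self.mode == "constant_mean":
            return self.mean_flux
        if global_radiation is None or not np.isfinite(global_radiation):
            raise ValueError("radiation_regression background needs a radiation value")
        return self.intercept + self.slope * global_radiation


@dataclass
class DetectionLimits:
    """The 3-sigma blank-scaled detection-limit ladder.

    Identities (held at full precision; rounding is report-time only):
    ``per_measurement[sp] = per_chamber / avg_dw[sp]`` and
    ``per_period[sp] = per_measurement[sp] / sqrt(n_used[sp])``.
    """

    per_chamber: float  # ng CH4 h^-1
    per_measurement: dict[str, float]  # ng gDW^-1 h^-1 by species
    per_period: dict[str, float]
    n_used: dict[str, int]
    avg_dw: dict[str, float]

    @classmethod
    def from_per_chamber(
        cls,
        per_chamber: float,
        avg_dw: Mapping[str, float],
        n_per_period: Mapping[str, int],
    ) -> "DetectionLimits":
        if any(dw <= 0 for dw in avg_dw.values()):
            raise ValueError("average dry weights must be > 0")
        if any(n < 1 for n in n_per_period.values()):
            raise ValueError("n per period must be >= 1")
        per_meas = {sp: per_chamber / dw for sp, dw in avg_dw.items()}
        per_period = {sp: per_meas[sp] / math.sqrt(n_per_period[sp]) for sp in per_meas}
        return cls(
            per_chamber=float(per_chamber),
            per_measurement=per_meas,
            per_period=per_period,
            n_used=dict(n_per_period),
            avg_dw=dict(avg_dw),
        )

    def report(self) -> dict:
        """Rounded, human-facing ladder: per-measurement limits to three
        significant figures, per-period limits to two decimals."""
        return {
            "per_chamber_ng_h": round_sig(self.per_chamber, 4),
            "per_measurement_ng_gDW_h": {
                sp: round_sig(v, 3) for sp, v in self.per_measurement.items()
            },
            "per_period_ng_gDW_h": {sp: round(v, 2) for sp, v in self.per_period.items()},
            "n_used": self.n_used,
        }


def round_sig(x: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0 or not np.isfinite(x):
        return x
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


def fit_background(
    empty_fluxes: Sequence[float],
    global_radiation: Sequence[float] | None = None,
    air_temp: Sequence[float] | None = None,
    time_index: Sequence[float] | None = None,
    alpha: float = 0.05,
) -> BackgroundModel:
    """Fit the empty-chamber background and choose its functional form.

    The blank fluxes are tested for sensitivity to global radiation, air
    temperature and time by separate OLS fits.  If the radiation slope is
    significant at ``alpha`` (two-sided t-test) the radiation regression
    becomes the background model; otherwise the campaign mean is used.
    Temperature/time sensitivities are reported as diagnostics only.
    """
    y = np.asarray(empty_fluxes, float)
    if len(y) < 3:
        raise ValueError("need >= 3 empty-chamber closures to fit a background")
    diagnostics: dict = {}

    def _slope_test(x: Sequence[float] | None, name: str):
        if x is None:
            return None
        x = np.asarray(x, float)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        diagnostics[name] = {
            "slope": float(ols.params[1]),
            "p": float(ols.pvalues[1]),
            "intercept": float(ols.params[0]),
            "resid_sd": float(np.sqrt(ols.mse_resid)) if ols.df_resid > 0 else 0.0,
        }
        return ols

    rad_fit = _slope_test(global_radiation, "global_radiation")
    _slope_test(air_temp, "air_temp")
    _slope_test(time_index, "time")

    mean = float(y.mean())
    mean_se = float(y.std(ddof=1) / np.sqrt(len(y))) if len(y) > 1 else 0.0
    if rad_fit is not None and diagnostics["global_radiation"]["p"] < alpha:
        d = diagnostics["global_radiation"]
        return BackgroundModel(
            mode="radiation_regression",
            mean_flux=mean,
            mean_se=mean_se,
            slope=d["slope"],
            intercept=d["intercept"],
            sd_resid=d["resid_sd"],
            n_empty=len(y),
            diagnostics=diagnostics,
        )
    return BackgroundModel(
        mode="constant_mean",
        mean_flux=mean,
        mean_se=mean_se,
        slope=0.0,
        intercept=mean,
        sd_resid=float(y.std(ddof=1)) if len(y) > 1 else 0.0,
        n_empty=len(y),
        diagnostics=diagnostics,
    )


def subtract_background(
    chamber_flux: float,
    model: BackgroundModel,
    global_radiation_mean: float | None = None,
) -> float:
    """Background-corrected chamber flux (ng h^-1).

    Subtraction happens on the chamber scale, before any dry-weight
    normalization, so it preserves differences between shoot fluxes
    measured under equal radiation.
    """
    return chamber_flux - model.predict(global_radiation_mean)


def compute_mdl(
    empty_fluxes: Sequence[float],
    avg_dw: Mapping[str, float],
    n_per_period: Mapping[str, int],
) -> DetectionLimits:
    """Detection-limit ladder from blank closures: 3 x sample SD of the
    empty-chamber apparent fluxes (H2O-corrected, no background subtraction),
    scaled by average shoot dry weight and sqrt(replicates per period)."""
    y = np.asarray(empty_fluxes, float)
    if len(y) < 3:
        raise ValueError("need >= 3 empty-chamber fluxes for an MDL")
    per_chamber = 3.0 * float(y.std(ddof=1))
    return DetectionLimits.from_per_chamber(per_chamber, avg_dw, n_per_period)


def flag_below_mdl(flux: FluxEstimate, limits: DetectionLimits, species: str) -> FluxEstimate:
    """Set ``below_mdl`` when |dw_flux| is under the species' per-measurement
    limit.  The flux value itself is never altered or deleted."""
    if species not in limits.per_measurement:
        raise KeyError(f"species {species!r} not in detection limits")
    if flux.dw_flux is None:
        raise ValueError("empty-chamber fluxes carry no dry-weight value to flag")
    flux.below_mdl = abs(flux.dw_flux) < limits.per_measurement[species]
    return flux
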