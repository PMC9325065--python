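"""Concentration-change fitting and conversion to chamber and dry-weight fluxes.

In a closed non-steady-state chamber the amount of gas accumulating (or
depleting) per unit time follows from the fitted mixing-ratio change dC/dt
and the molar amount of air enclosed::

    F_chamber = dC/dt [mol-fraction s^-1] * (p V / (R T)) * M * 3600

with p the pressure (Pa), V the chamber + loop volume (m^3), T the sample
temperature (K), M the molar mass in the reporting unit (ng/mol for CH4,
mg/mol for CO2).  dC/dt is carried internally as mol-fraction per second
(ppm inputs are multiplied by 1e-6) so the expression is dimensionally
closed.  Division by the needle dry mass yields the biomass-normalized flux.

CH4 changes little during a 7-10 min closure, so a straight line is fitted;
CO2 is drawn down by photosynthesis toward a compensation level, so a
saturating exponential ``C(t) = Clim + (C0 - Clim) exp(-k t)`` is fitted and
its initial slope ``-k (C0 - Clim)`` used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from scipy import optimize, stats

from .closures import ClosureSeries

R_GAS = 8.31446  # J mol^-1 K^-1
M_CH4_NG = 1.604e10  # ng mol^-1
M_CO2_MG = 4.401e4  # mg mol^-1
PPM = 1e-6


@dataclass(frozen=True)
class ChamberSpec:
    """Physical chamber parameters; defaults are the 5.2 l shoot chamber
    (loop volume included) at assumed ambient pressure."""

    volume_m3: float = 5.2e-3
    pressure_pa: float = 101325.0

    def __post_init__(self) -> None:
        if self.volume_m3 <= 0:
            raise ValueError("chamber volume must be > 0")
        if self.pressure_pa <= 0:
            raise ValueError("pressure must be > 0")

    def air_moles(self, temp_k: float) -> float:
        """mol of air enclosed at the given sample temperature."""
        return self.pressure_pa * self.volume_m3 / (R_GAS * temp_k)


@dataclass(frozen=True)
class LinearFit:
    """OLS fit of concentration on time over the trimmed window.

    ``slope`` is in mol-fraction s^-1 (input ppm scaled by 1e-6);
    ``slope_se`` is its standard error on the same scale.
    """

    slope: float
    intercept: float
    slope_se: float
    r2: float
    n_points: int


@dataclass(frozen=True)
class ExponentialFit:
    """Saturating-exponential CO2 fit C(t) = Clim + (C0-Clim) e^{-k t}.

    ``initial_slope`` (ppm s^-1) is -k (C0 - Clim); when the optimiser
    cannot identify k (near-linear decay), ``converged`` is False and the
    initial slope falls back to the linear fit.
    """

    c0: float
    clim: float
    k: float
    initial_slope: float
    converged: bool


@dataclass
class FluxEstimate:
    """A chamber-level and (for shoot chambers) dry-weight-normalized flux."""

    gas: str  # "CH4" | "CO2"
    chamber_flux: float  # ng h^-1 (CH4) or mg h^-1 (CO2)
    dw_flux: float | None  # per g needle DW; None for empty chambers
    needle_mass_used: float | None
    sample_temp_used: float
    slope: float
    slope_se: float
    r2: float
    background_corrected: bool = False
    below_mdl: bool = False
    flags: dict = field(default_factory=dict)


def _window(series: ClosureSeries, channel: str) -> tuple[np.ndarray, np.ndarray]:
    sub = series.trimmed()
    if channel == "ch4_dry_corr" and channel not in sub.columns:
        channel = "ch4_dry_raw"  # uncorrected input: fit the reported channel
    return sub["t"].to_numpy(float), sub[channel].to_numpy(float)


def fit_linear_slope(series: ClosureSeries, channel: str = "ch4_dry_corr") -> LinearFit:
    """Least-squares line through the trimmed window of one channel.

    The slope is returned in mol-fraction s^-1; requires >= 20 samples.
    """
    t, y = _window(series, channel)
    if len(t) < 20:
        raise ValueError(f"need >= 20 points for a linear fit, got {len(t)}")
    res = stats.linregress(t, y)
    return LinearFit(
        slope=res.slope * PPM,
        intercept=res.intercept * PPM,
        slope_se=(res.stderr if np.isfinite(res.stderr) else 0.0) * PPM,
        r2=res.rvalue**2 if np.isfinite(res.rvalue) else 0.0,
        n_points=len(t),
    )


def fit_exponential(
    series: ClosureSeries, channel: str = "co2", k_min: float = 1e-8
) -> ExponentialFit:
    """Fit the CO2 drawdown curve and report its initial slope (ppm s^-1).

    Time is kept on the closure clock (t = 0 at closure start, before any
    trimming), so ``c0`` and the initial slope describe the undisturbed
    chamber at sealing even when the fit window starts later.
    Initialization: C0 from the first sample, Clim from the last, k from a
    log-linearized decrement.  When k is not identifiable (k*duration
    effectively 0, or no convergence after restarts) the fit degrades
    gracefully to the linear slope with ``converged=False``.
    """
    t, y = _window(series, channel)
    if len(t) < 20:
        raise ValueError(f"need >= 20 points for an exponential fit, got {len(t)}")
    t0 = t
    lin = stats.linregress(t0, y)

    c0_init, clim_init = float(y[0]), float(y[-1])
    if abs(c0_init - clim_init) < 1e-12:
        return ExponentialFit(c0_init, clim_init, 0.0, 0.0, converged=True)
    # log-linearized decrement for k init; fall back to 1/duration
    span = t0[-1] - t0[0]
    k_init = 1.0 / max(span, 1.0)
    mid = y[len(y) // 2]
    ratio = (mid - clim_init) / (c0_init - clim_init)
    if 0 < ratio < 1:
        k_init = max(-np.log(ratio) / (t0[len(y) // 2] - t0[0] + 1e-9), k_min)

    def model(tt, c0, clim, k):
        return clim + (c0 - clim) * np.exp(-k * tt)

    for k_try in (k_init, k_init * 10, k_init / 10):
        try:
            popt, _ = optimize.curve_fit(
                model,
                t0,
                y,
                p0=(c0_init, clim_init, k_try),
                bounds=([-np.inf, -np.inf, k_min], [np.inf, np.inf, np.inf]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        c0, clim, k = (float(v) for v in popt)
        if k > k_min * 1.01 or abs(k * span) > 1e-6:
            return ExponentialFit(c0, clim, k, -k * (c0 - clim), converged=True)
    return ExponentialFit(c0_init, clim_init, 0.0, float(lin.slope), converged=False)


def slope_to_flux(
    slope_molfrac_s: float,
    chamber: ChamberSpec,
    gas: str,
    needle_mass_g: float | None,
    sample_temp_k: float,
    slope_se: float = 0.0,
    r2: float = float("nan"),
) -> FluxEstimate:
    """Convert a fitted concentration slope into hourly fluxes.

    ``needle_mass_g=None`` (empty chamber) yields a chamber-level flux only.
    ``sample_temp_k`` should be the mean analyser intake temperature over
    the trimmed window and must lie in [250, 330] K.
    """
    if not 250.0 <= sample_temp_k <= 330.0:
        raise ValueError(f"sample temperature {sample_temp_k} K outside [250, 330]")
    if gas == "CH4":
        molar_mass = M_CH4_NG
    elif gas == "CO2":
        molar_mass = M_CO2_MG
    else:
        raise ValueError(f"unknown gas {gas!r}")
    n_air = chamber.air_moles(sample_temp_k)
    chamber_flux = slope_molfrac_s * n_air * molar_mass * 3600.0
    dw_flux = None
    if needle_mass_g is not None:
        if needle_mass_g <= 0:
            raise ValueError("needle mass must be > 0 for a dry-weight flux")
        dw_flux = chamber_flux / needle_mass_g
    return FluxEstimate(
        gas=gas,
        chamber_flux=float(chamber_flux),
        dw_flux=None if dw_flux is None else float(dw_flux),
        needle_mass_used=needle_mass_g,
        sample_temp_used=float(sample_temp_k),
        slope=float(slope_molfrac_s),
        slope_se=float(slope_se),
        r2=float(r2),
    )


def flux_from_closure(
    series: ClosureSeries,
    chamber: ChamberSpec,
    gas: str,
    needle_mass_g: float | None,
    ch4_model: str = "linear",
) -> FluxEstimate:
    """Fit the appropriate concentration model on a QC-passed closure and
    convert to fluxes using the mean sample temperature over the trim window."""
    if series.qc_status != "pass":
        raise ValueError(f"closure {series.closure_id!r} has qc_status={series.qc_status!r}")
    sub = series.trimmed()
    temp = float(sub["sample_temp"].mean())
    if gas == "CH4":
        channel = "ch4_dry_corr" if "ch4_dry_corr" in sub.columns else "ch4_dry_raw"
        if ch4_model == "linear":
            fit = fit_linear_slope(series, channel)
            slope, se, r2 = fit.slope, fit.slope_se, fit.r2
        else:
            efit = fit_exponential(series, channel)
            slope, se, r2 = efit.initial_slope * PPM, 0.0, float("nan")
    elif gas == "CO2":
        efit = fit_exponential(series, "co2")
        slope, se, r2 = efit.initial_slope * PPM, 0.0, float("nan")
    else:
        raise ValueError(f"unknown gas {gas!r}")
    est = slope_to_flux(slope, chamber, gas, needle_mass_g, temp, slope_se=se, r2=r2)
    if gas == "CO2":
        est.flags["exp_converged"] = efit.converged
    return est
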