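"""End-to-end orchestration: raw closures -> flux table -> driver statistics.

``run_process`` sequences the flux workflow — trim, QC, H2O-interference
correction, linear CH4 / exponential CO2 fits, unit conversion, needle-mass
normalization, background subtraction, detection-limit flagging — and
guarantees that every input closure lands in exactly one of the flux table
or the discard log.  ``run_analyze`` runs the statistics battery on the
resulting table.  Both are deterministic given inputs and configuration,
and stamp their outputs with a configuration hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .background import (
    BackgroundModel,
    DetectionLimits,
    compute_mdl,
    fit_background,
    subtract_background,
)
from .closures import (
    EMPTY,
    ClosureSeries,
    InterferenceCalibration,
    QcRules,
    TrimRules,
    correct_h2o,
    qc_closure,
    trim_closure,
)
from .drivers import (
    assign_periods,
    compare_period_means,
    fit_lmm,
    par_split_regression,
    residual_disentangle,
    temp_bin_interaction,
    ttest_vs_empty,
)
from .fluxes import ChamberSpec, flux_from_closure
from .io import read_campaign_dir
from .phenology import ShootBiomass
from .synthetic import Campaign, campaign_mass_series

#: printed value of the H2O interference coefficient used when no
#: calibration runs are supplied (ppm CH4 per ppm H2O)
DEFAULT_F = -9.122e-7


@dataclass
class PipelineConfig:
    """Everything the processing and analysis stages need, in one place."""

    f: float = DEFAULT_F
    chamber_volume_m3: float = 5.2e-3
    chamber_pressure_pa: float = 101325.0
    deadband_s: float = 30.0
    mad_k: float = 4.0
    min_span_s: float = 120.0
    qc_max_resid_sd: float = 0.0025
    qc_max_drift_z: float = 6.0
    background_alpha: float = 0.05
    growth_g50: float = 150.0
    growth_steepness: float = 0.03
    period_width_days: int = 14
    par_threshold: float = 500.0
    temp_bins: tuple = (0.0, 5.0, 10.0, 15.0, 20.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dc_fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "temp_bins" in raw:
            raw["temp_bins"] = tuple(raw["temp_bins"])
        return cls(**raw)

    def chamber(self) -> ChamberSpec:
        return ChamberSpec(self.chamber_volume_m3, self.chamber_pressure_pa)

    def trim_rules(self) -> TrimRules:
        return TrimRules(
            deadband_s=self.deadband_s, mad_k=self.mad_k, min_span_s=self.min_span_s
        )

    def qc_rules(self) -> QcRules:
        return QcRules(
            max_resid_sd=self.qc_max_resid_sd,
            max_drift_z=self.qc_max_drift_z,
            min_span_s=self.min_span_s,
        )

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ProcessResult:
    """Outputs of the processing stage."""

    flux_table: pd.DataFrame
    discard_log: pd.DataFrame
    background: BackgroundModel
    detection_limits: DetectionLimits | None
    config_hash: str
    meta: dict = field(default_factory=dict)


def _meteo_window_means(
    meteo: pd.DataFrame, start: pd.Timestamp, trim: tuple[float, float]
) -> dict:
    """Means of the meteo records overlapping the trimmed closure window."""
    lo = start + pd.Timedelta(seconds=trim[0])
    hi = start + pd.Timedelta(seconds=trim[1])
    idx = meteo.set_index("timestamp")
    # meteo rows are window averages stamped at window start: include the
    # record covering lo even when its stamp precedes it
    step = pd.Timedelta(
        seconds=float(np.median(np.diff(idx.index.values)) / np.timedelta64(1, "s"))
        if len(idx) > 1
        else 300.0
    )
    window = idx.loc[lo - step : hi]
    if window.empty:
        pos = idx.index.get_indexer([lo], method="nearest")
        window = idx.iloc[pos]
    return {
        "par": float(window["par"].mean()),
        "global_radiation": float(window["global_radiation"].mean()),
        "air_temp": float(window["air_temp"].mean()),
    }


def _needle_mass_lookup(
    biomass: list[ShootBiomass], meteo: pd.DataFrame, config: PipelineConfig
) -> dict[str, pd.Series]:
    return {
        b.shoot_id: campaign_mass_series(
            b, meteo, config.growth_g50, config.growth_steepness
        )
        for b in biomass
    }


def process_closures(
    closures: list[ClosureSeries],
    meteo: pd.DataFrame,
    biomass: list[ShootBiomass],
    config: PipelineConfig | None = None,
) -> ProcessResult:
    """Core processing stage on in-memory objects.

    Every closure is trimmed, QC-labelled and, if passing, H2O-corrected,
    fitted and converted to fluxes; empty-chamber closures feed the
    background model and MDL ladder; shoot fluxes are background-corrected
    on the chamber scale and flagged against the per-measurement MDL.
    """
    config = config or PipelineConfig()
    chamber = config.chamber()
    cal = InterferenceCalibration(config.f, 0.0, 0, method="configured")
    mass_series = _needle_mass_lookup(biomass, meteo, config)

    processed, discards = [], []
    for c in closures:
        # interference correction precedes trim/QC so instability rules see
        # the concentration signal, not the H2O cross-talk curvature
        corrected = correct_h2o(c, cal)
        trimmed = trim_closure(corrected, config.trim_rules())
        labelled = qc_closure(trimmed, config.qc_rules())
        if labelled.qc_status != "pass":
            discards.append(
                {"closure_id": c.closure_id, "shoot_id": c.shoot_id,
                 "species": c.species, "reason": labelled.qc_reason}
            )
            continue
        processed.append(labelled)

    rows = []
    for c in processed:
        met = _meteo_window_means(meteo, c.start_time, c.trim)
        if c.is_empty_chamber:
            mass = None
        else:
            ms = mass_series[c.shoot_id]
            mass = float(ms.asof(pd.Timestamp(c.start_time).normalize()))
            if np.isnan(mass):
                mass = float(ms.iloc[0])
        ch4 = flux_from_closure(c, chamber, "CH4", mass)
        co2 = flux_from_closure(c, chamber, "CO2", mass)
        rows.append(
            {
                "closure_id": c.closure_id,
                "date": pd.Timestamp(c.start_time),
                "chamber_id": c.chamber_id,
                "shoot_id": c.shoot_id,
                "species": c.species,
                "is_empty": c.is_empty_chamber,
                "needle_mass_g": mass,
                "par": met["par"],
                "global_radiation": met["global_radiation"],
                "air_temp": met["air_temp"],
                "ch4_chamber_raw": ch4.chamber_flux,
                "ch4_slope_se": ch4.slope_se,
                "ch4_r2": ch4.r2,
                "co2_chamber_flux": co2.chamber_flux,
                "co2_exp_converged": co2.flags.get("exp_converged", True),
            }
        )
    table = pd.DataFrame(rows)
    discard_log = pd.DataFrame(discards, columns=["closure_id", "shoot_id", "species", "reason"])

    empties = table[table["is_empty"]]
    if len(empties) >= 3:
        background = fit_background(
            empties["ch4_chamber_raw"].to_numpy(),
            global_radiation=empties["global_radiation"].to_numpy(),
            air_temp=empties["air_temp"].to_numpy(),
            time_index=(empties["date"] - empties["date"].min()).dt.total_seconds().to_numpy(),
            alpha=config.background_alpha,
        )
    else:
        raise ValueError("fewer than 3 empty-chamber closures; cannot model background")

    shoots = table[~table["is_empty"]].copy()
    if len(shoots):
        shoots["ch4_chamber_corrected"] = [
            subtract_background(fx, background, gr)
            for fx, gr in zip(shoots["ch4_chamber_raw"], shoots["global_radiation"])
        ]
        shoots["ch4_dw_flux"] = shoots["ch4_chamber_corrected"] / shoots["needle_mass_g"]
        shoots["co2_dw_flux"] = shoots["co2_chamber_flux"] / shoots["needle_mass_g"]
        shoots["period"] = assign_periods(shoots["date"], config.period_width_days)
    else:
        for col in ("ch4_chamber_corrected", "ch4_dw_flux", "co2_dw_flux", "period"):
            shoots[col] = pd.Series(dtype=float)

    limits = None
    if len(shoots):
        avg_dw = shoots.groupby("species")["needle_mass_g"].mean().to_dict()
        n_per = (
            shoots.groupby(["species", "period"]).size().groupby("species").median()
        )
        n_per_period = {sp: max(int(round(v)), 1) for sp, v in n_per.items()}
        limits = compute_mdl(empties["ch4_chamber_raw"].to_numpy(), avg_dw, n_per_period)
        shoots["below_mdl"] = [
            abs(v) < limits.per_measurement[sp]
            for v, sp in zip(shoots["ch4_dw_flux"], shoots["species"])
        ]

    flux_table = pd.concat([shoots, empties], ignore_index=True, sort=False)
    n_in, n_out = len(closures), len(flux_table) + len(discard_log)
    assert n_in == n_out, f"closure conservation violated: {n_in} in, {n_out} out"
    return ProcessResult(
        flux_table=flux_table,
        discard_log=discard_log,
        background=background,
        detection_limits=limits,
        config_hash=config.hash(),
        meta={
            "version": __version__,
            "n_closures": n_in,
            "n_pass": len(flux_table),
            "n_discard": len(discard_log),
            "f_used": config.f,
            "background_mode": background.mode,
        },
    )


def run_process(
    raw_dir: str | Path,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    column_map: dict[str, str] | None = None,
) -> ProcessResult:
    """File-based processing: read a raw campaign directory, process it,
    optionally write the flux table, QC report and background/MDL report.
    ``column_map`` translates foreign analyser headers to the native ones
    (externally deposited data sets)."""
    config = config or PipelineConfig()
    loaded = read_campaign_dir(raw_dir, column_map=column_map)
    biomass = [
        ShootBiomass(r.shoot_id, r.species, float(r.m_y1_g), float(r.m_y0_final_g))
        for r in loaded["biomass"].itertuples()
    ]
    result = process_closures(loaded["closures"], loaded["meteo"], biomass, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.flux_table.to_csv(out / "fluxes.csv", index=False)
        result.discard_log.to_csv(out / "qc_discards.csv", index=False)
        report = {
            "config_hash": result.config_hash,
            "meta": result.meta,
            "background": {
                "mode": result.background.mode,
                "mean_flux": result.background.mean_flux,
                "mean_se": result.background.mean_se,
                "slope": result.background.slope,
                "intercept": result.background.intercept,
                "sd_resid": result.background.sd_resid,
                "n_empty": result.background.n_empty,
            },
            "detection_limits": (
                result.detection_limits.report() if result.detection_limits else None
            ),
        }
        (out / "background_mdl.json").write_text(json.dumps(report, indent=1))
    return result


def process_campaign(campaign: Campaign, config: PipelineConfig | None = None) -> ProcessResult:
    """Process an in-memory synthetic campaign (no file round trip)."""
    return process_closures(campaign.closures, campaign.meteo, campaign.biomass, config)


def run_analyze(
    flux_table: pd.DataFrame, config: PipelineConfig | None = None
) -> dict:
    """Run the driver-statistics battery on a processed flux table.

    Produces, per species: period-mean comparisons with a compact letter
    display, mixed-model driver fits (PAR, global radiation, temperature,
    CO2 flux), the PAR-split temperature regressions, the temperature-bin
    Helmert interaction analysis, residual disentangling, and Welch t-tests
    of each shoot against the empty-chamber blanks.  Row order of the input
    does not affect the result.
    """
    config = config or PipelineConfig()
    if flux_table.empty:
        raise ValueError("empty flux table")
    table = flux_table.sort_values("closure_id").reset_index(drop=True)
    empties = table[table["is_empty"]]
    shoots = table[~table["is_empty"]].copy()
    shoots["tree_id"] = shoots["shoot_id"]
    shoots["period"] = shoots["period"].astype(int)
    report: dict = {
        "version": __version__,
        "config_hash": config.hash(),
        "empty_comparison_uses_uncorrected_chamber_fluxes": True,
        "species": {},
    }
    ttests = ttest_vs_empty(
        {
            sid: grp["ch4_chamber_raw"].to_numpy()
            for sid, grp in shoots.groupby("shoot_id")
        },
        empties["ch4_chamber_raw"].to_numpy(),
    )
    report["ttest_vs_empty"] = ttests.to_dict(orient="records")
    for sp, sub in shoots.groupby("species"):
        entry: dict = {"n": int(len(sub))}
        if len(sub) >= 10 and sub["period"].nunique() >= 1:
            entry["period_comparison"] = _jsonable(
                compare_period_means(sub, "ch4_dw_flux")
            )
        drv = {}
        for name, col in (
            ("par", "par"),
            ("global_radiation", "global_radiation"),
            ("air_temp", "air_temp"),
            ("co2_dw_flux", "co2_dw_flux"),
        ):
            if len(sub) >= 10:
                fit = fit_lmm(sub, "ch4_dw_flux", [col])
                drv[name] = {
                    "slope": fit.coef(col),
                    "se": fit.se(col),
                    "p": fit.p(col),
                    "marginal_r2": fit.marginal_r2,
                    "random_intercept_sd": fit.random_intercept_sd,
                }
        entry["drivers"] = drv
        if len(sub) >= 20:
            entry["par_split"] = par_split_regression(
                sub, threshold=config.par_threshold
            )
            try:
                tbi = temp_bin_interaction(sub, bins=config.temp_bins)
                entry["temp_bin_interaction"] = {
                    "per_bin": tbi["per_bin"],
                    "helmert_contrasts": tbi["helmert_contrasts"],
                    "merged_bins": tbi["merged_bins"],
                }
            except ValueError as e:
                entry["temp_bin_interaction"] = {"error": str(e)}
            entry["residual_disentangle"] = residual_disentangle(sub)
        report["species"][sp] = entry
    return report


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
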