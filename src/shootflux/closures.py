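"""Closure parsing, trimming, quality control, and water-vapour interference correction.

A *closure* is the interval during which a shoot chamber is sealed and its
headspace recirculates through the gas analyser.  Raw closures contain
unstable segments (headspace mixing at the start, leaks or clock errors at
the end) that must be excluded before a flux can be fitted.  Trimming here is
algorithmic: a fixed initial deadband followed by iterative shrinkage of the
window wherever rolling residuals from a robust provisional linear CH4 fit
exceed a MAD-based threshold.

The analyser's internal water-vapour correction is imperfect: reported dry
CH4 carries a residual linear cross-talk with the H2O mixing ratio.  The
interference coefficient ``f`` (ppm CH4 per ppm H2O) is calibrated from
water-injection experiments and removed pointwise::

    ch4_dry_corr(t) = ch4_dry_raw(t) - h2o(t) * f
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

# sentinel shoot/species label for blank (background) chambers
EMPTY = "EMPTY"

#: columns every closure data frame must carry
REQUIRED_COLUMNS = ("t", "ch4_dry_raw", "co2", "h2o", "sample_temp")


@dataclass
class TrimRules:
    """Parameters of the automated trim algorithm.

    deadband_s
        Seconds discarded unconditionally at the start of every closure
        (headspace mixing transient), default 30 s.
    mad_k
        Multiple of the MAD of provisional-fit residuals beyond which a
        rolling residual marks a sample as unstable, default 4.
    roll_window
        Width (samples) of the rolling-median residual used for edge
        shrinkage.
    min_span_s
        Minimum post-trim span; shorter closures are discarded.
    max_iter
        Iterations of refit-and-shrink; the window is monotone shrinking so
        this always terminates.
    """

    deadband_s: float = 30.0
    mad_k: float = 4.0
    roll_window: int = 5
    min_span_s: float = 120.0
    max_iter: int = 10


@dataclass
class QcRules:
    """Discard thresholds applied after trimming.

    max_resid_sd
        Robust residual SD (1.4826*MAD, ppm) of the CH4 linear fit above
        which a closure is labelled unstable.
    max_drift_z
        z-score of the middle-third residual mean against the outer thirds
        (curvature / monotone drift in residuals) above which a closure is
        discarded.
    min_span_s, min_records
        Minimum trimmed span and sample count for a pass.
    """

    max_resid_sd: float = 0.0025
    max_drift_z: float = 6.0
    min_span_s: float = 120.0
    min_records: int = 20


@dataclass
class ClosureSeries:
    """One chamber closure: metadata, sample records, trim window, QC state.

    ``data`` has columns ``t`` (s since closure start, strictly increasing),
    ``ch4_dry_raw``, ``co2``, ``h2o`` (ppm) and ``sample_temp`` (K); a
    ``ch4_dry_corr`` column appears once :func:`correct_h2o` has run.  The
    trim window is half-open ``[t_start, t_end)`` in seconds.
    """

    chamber_id: str
    shoot_id: str  # EMPTY for blank chambers
    species: str  # EMPTY for blank chambers
    data: pd.DataFrame
    closure_id: str = ""
    start_time: pd.Timestamp | None = None
    trim: tuple[float, float] | None = None
    qc_status: str = "pending"  # pending | pass | discard
    qc_reason: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"closure data missing columns: {missing}")
        t = np.asarray(self.data["t"], float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("closure time axis must be strictly increasing")

    @property
    def is_empty_chamber(self) -> bool:
        return self.shoot_id == EMPTY

    def trimmed(self) -> pd.DataFrame:
        """Records inside the trim window (all records if never trimmed)."""
        if self.trim is None:
            return self.data
        lo, hi = self.trim
        t = self.data["t"]
        return self.data[(t >= lo) & (t < hi)]

    @property
    def duration(self) -> float:
        t = self.data["t"].to_numpy()
        return float(t[-1] - t[0]) if len(t) else 0.0


@dataclass(frozen=True)
class InterferenceCalibration:
    """H2O spectral-interference coefficient with its 95% CI.

    ``f`` is in ppm CH4 per ppm H2O; ``method`` records whether replicate
    slopes were averaged ("mean_of_slopes") or all points pooled into one
    regression ("pooled").
    """

    f: float
    ci95_halfwidth: float
    n_replicates: int
    method: str = "mean_of_slopes"

    def __post_init__(self) -> None:
        if self.ci95_halfwidth < 0:
            raise ValueError("ci95_halfwidth must be >= 0")


def _ch4_channel(series: ClosureSeries) -> str:
    """Trim/QC operate on the interference-corrected CH4 when available."""
    return "ch4_dry_corr" if "ch4_dry_corr" in series.data.columns else "ch4_dry_raw"


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def _provisional_residuals(t: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    """Residuals from a least-trimmed-squares provisional line.

    Theil-Sen start, then iterated OLS on the 60% of points closest to the
    line: converges to the dominant stable segment even when a leak or
    mixing artefact contaminates a third of the closure.  Returns residuals
    and the robust scale (1.4826*MAD) of the kept points.
    """
    slope, intercept, *_ = stats.theilslopes(y, t)
    keep = np.ones(len(t), bool)
    for _ in range(10):
        resid = y - (intercept + slope * t)
        cut = np.quantile(np.abs(resid), 0.6)
        new_keep = np.abs(resid) <= cut
        if new_keep.sum() < 10 or np.array_equal(new_keep, keep):
            keep = new_keep if new_keep.sum() >= 10 else keep
            break
        keep = new_keep
        slope, intercept = np.polyfit(t[keep], y[keep], 1)
    resid = y - (intercept + slope * t)
    scale = 1.4826 * _mad(resid[keep])
    return resid, scale


def _shrink_once(
    t: np.ndarray, y: np.ndarray, lo: float, hi: float, rules: TrimRules
) -> tuple[float, float]:
    """One refit-and-shrink pass over the half-open window [lo, hi)."""
    inside = (t >= lo) & (t < hi)
    ti, yi = t[inside], y[inside]
    if len(ti) < 10:
        return lo, hi
    resid, scale = _provisional_residuals(ti, yi)
    scale = max(scale, 1e-12)
    roll = (
        pd.Series(np.abs(resid))
        .rolling(rules.roll_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    bad = roll > rules.mad_k * scale
    # shrink from the leading edge
    k = 0
    while k < len(bad) and bad[k]:
        k += 1
    # shrink from the trailing edge
    m = len(bad)
    while m > k and bad[m - 1]:
        m -= 1
    if k == 0 and m == len(bad):
        return lo, hi
    if m <= k:
        return lo, lo  # everything unstable
    dt = float(np.median(np.diff(ti))) if len(ti) > 1 else 1.0
    return float(ti[k]), float(ti[m - 1] + dt)


def trim_closure(series: ClosureSeries, rules: TrimRules | None = None) -> ClosureSeries:
    """Set the stable flux-calculation window on a closure.

    Removes the initial deadband, then iteratively shrinks the window from
    both edges wherever the rolling median absolute residual from a robust
    provisional linear CH4 fit exceeds ``mad_k`` times the residual MAD.
    The window never widens and the operation is idempotent.  Closures whose
    post-trim span falls below ``min_span_s`` are marked for discard.
    """
    rules = rules or TrimRules()
    if series.duration < 60:
        raise ValueError("need at least 60 s of records to trim")
    t = series.data["t"].to_numpy(float)
    y = series.data[_ch4_channel(series)].to_numpy(float)
    lo = t[0] + rules.deadband_s
    hi = t[-1] + float(np.median(np.diff(t)))
    for _ in range(rules.max_iter):
        lo2, hi2 = _shrink_once(t, y, lo, hi, rules)
        if (lo2, hi2) == (lo, hi):
            break
        lo, hi = lo2, hi2
        if hi - lo < rules.min_span_s:
            break
    if series.trim is not None:  # never widen a pre-existing window
        lo = max(lo, series.trim[0])
        hi = min(hi, series.trim[1])
    out = replace(series, trim=(lo, hi))
    if hi - lo < rules.min_span_s:
        out.qc_status = "discard"
        out.qc_reason = "too short after trim"
    return out


def qc_closure(series: ClosureSeries, rules: QcRules | None = None) -> ClosureSeries:
    """Label a trimmed closure pass/discard.  QC never raises; it labels."""
    rules = rules or QcRules()
    if series.trim is None:
        return replace(series, qc_status="discard", qc_reason="not trimmed")
    if series.qc_status == "discard":
        return series
    sub = series.trimmed()
    if len(sub) < rules.min_records:
        return replace(series, qc_status="discard", qc_reason="too few records")
    t = sub["t"].to_numpy(float)
    y = sub[_ch4_channel(series)].to_numpy(float)
    if t[-1] - t[0] < rules.min_span_s:
        return replace(series, qc_status="discard", qc_reason="too short after trim")
    res = stats.linregress(t, y)
    resid = y - (res.intercept + res.slope * t)
    robust_sd = 1.4826 * _mad(resid)
    if robust_sd > rules.max_resid_sd:
        return replace(series, qc_status="discard", qc_reason="unstable")
    # curvature / drift: middle third vs outer thirds of the residuals
    n3 = len(resid) // 3
    if n3 >= 3 and robust_sd > 0:
        mid = resid[n3 : 2 * n3]
        outer = 0.5 * (resid[:n3].mean() + resid[2 * n3 :].mean())
        z = abs(mid.mean() - outer) / (robust_sd / np.sqrt(len(mid)))
        if z > rules.max_drift_z:
            return replace(series, qc_status="discard", qc_reason="residual drift")
    return replace(series, qc_status="pass", qc_reason="")


def correct_h2o(
    series: ClosureSeries, cal: InterferenceCalibration | float
) -> ClosureSeries:
    """Remove the linear H2O cross-talk from the reported dry CH4 channel.

    Adds/overwrites a ``ch4_dry_corr`` column; the raw channel is preserved.
    The correction is linear and invertible: applying it with ``-f`` undoes
    applying it with ``+f``.
    """
    f = cal.f if isinstance(cal, InterferenceCalibration) else float(cal)
    if "h2o" not in series.data.columns or series.data["h2o"].isna().all():
        raise ValueError("closure has no h2o channel; interference correction cannot apply")
    data = series.data.copy()
    data["ch4_dry_corr"] = data["ch4_dry_raw"] - data["h2o"] * f
    return replace(series, data=data)


def estimate_f(
    injection_runs: Sequence[ClosureSeries],
    min_h2o_range: float = 5000.0,
    pooled: bool = False,
) -> InterferenceCalibration:
    """Calibrate the H2O interference coefficient from water-injection runs.

    Each run holds actual dry CH4 constant while H2O rises sharply; the
    per-run OLS slope of reported dry CH4 on H2O estimates ``f``.  The
    default estimator is the mean of the replicate slopes with a
    t-distribution 95% CI on that mean; ``pooled=True`` instead regresses
    all points of all runs jointly.

    Parameters
    ----------
    injection_runs
        At least two replicate runs, each spanning ``min_h2o_range`` ppm of
        H2O (the slope is unidentifiable otherwise).
    """
    if len(injection_runs) < 2:
        raise ValueError("need at least 2 injection replicates to estimate f")
    slopes = []
    all_h2o, all_ch4 = [], []
    for run in injection_runs:
        h2o = run.data["h2o"].to_numpy(float)
        ch4 = run.data["ch4_dry_raw"].to_numpy(float)
        if h2o.max() - h2o.min() < min_h2o_range:
            raise ValueError(
                f"H2O range {h2o.max() - h2o.min():.0f} ppm < {min_h2o_range:.0f}; "
                "slope unidentifiable"
            )
        slopes.append(stats.linregress(h2o, ch4).slope)
        all_h2o.append(h2o)
        all_ch4.append(ch4)
    n = len(slopes)
    if pooled:
        res = stats.linregress(np.concatenate(all_h2o), np.concatenate(all_ch4))
        half = float(stats.t.ppf(0.975, len(np.concatenate(all_h2o)) - 2) * res.stderr)
        return InterferenceCalibration(float(res.slope), half, n, method="pooled")
    f = float(np.mean(slopes))
    se = float(np.std(slopes, ddof=1) / np.sqrt(n))
    half = float(stats.t.ppf(0.975, n - 1) * se)
    return InterferenceCalibration(f, half, n, method="mean_of_slopes")
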