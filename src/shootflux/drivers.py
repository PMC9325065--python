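"""Driver analysis of the per-closure flux table.

Repeated measurements on the same saplings are not independent, so every
regression here is a linear mixed model with a random intercept per tree
(REML, Wald tests on the fixed effects).  The module reproduces the full
analysis battery:

* 14-day period grouping with Tukey-style simultaneous comparisons of
  period means and a compact letter display;
* Welch t-tests of each shoot chamber against the empty-chamber blanks on
  the raw chamber (ng h^-1) scale;
* PAR-stratified temperature regressions (low/high split at
  500 umol m^-2 s^-1, boundary rows in both strata);
* temperature-binned PAR slopes with Helmert contrasts (each bin's
  PAR x temperature interaction tested against the mean of the preceding
  bins) — the light-by-temperature interaction analysis;
* residual disentangling of PAR vs temperature as collinear drivers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm


@dataclass
class LmmResult:
    """Fixed-effect table and variance components of a random-intercept fit."""

    names: list[str]
    estimates: np.ndarray
    ses: np.ndarray
    pvalues: np.ndarray
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool = False
    cov: np.ndarray | None = None
    flags: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.estimates[self.names.index(name)])

    def se(self, name: str) -> float:
        return float(self.ses[self.names.index(name)])

    def p(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])

    @property
    def marginal_r2(self) -> float:
        """Share of total variance explained by the fixed effects."""
        return self.flags.get("marginal_r2", float("nan"))


def assign_periods(dates: Sequence, width_days: int = 14) -> np.ndarray:
    """Consecutive half-open calendar bins anchored at the first date;
    labels are 1-based: label = floor((date - first)/width) + 1."""
    d = pd.to_datetime(pd.Series(list(dates)))
    delta_days = (d - d.min()).dt.total_seconds() / 86400.0
    return (np.floor(delta_days / width_days) + 1).astype(int).to_numpy()


def _fit_mixed(
    y: np.ndarray, X: np.ndarray, groups: np.ndarray, names: list[str]
) -> LmmResult:
    """REML random-intercept fit with an OLS fallback for one group."""
    n_groups = len(pd.unique(groups))
    if np.allclose(np.var(y), 0.0):
        est = np.zeros(X.shape[1])
        est[names.index("Intercept")] = float(np.mean(y))
        return LmmResult(
            names, est, np.zeros_like(est), np.ones_like(est), 0.0, 0.0,
            len(y), n_groups, converged=True, cov=np.zeros((len(est), len(est))),
        )
    if n_groups < 2:
        ols = sm.OLS(y, X).fit()
        res = LmmResult(
            names,
            np.asarray(ols.params, float),
            np.asarray(ols.bse, float),
            np.asarray(ols.pvalues, float),
            0.0,
            float(np.sqrt(ols.mse_resid)),
            len(y),
            n_groups,
            converged=True,
            cov=np.asarray(ols.cov_params(), float),
        )
        res.flags["ols_fallback"] = True
        return res
    fit = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, X, groups=groups)
        for method in (["lbfgs", "cg"], ["powell"], ["nm"]):
            try:
                fit = model.fit(reml=True, method=method)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.all(np.isfinite(fit.fe_params)):
                break
            fit = None
    if fit is None:  # degenerate mixed fit: report the OLS solution, flagged
        ols = sm.OLS(y, X).fit()
        res = LmmResult(
            names,
            np.asarray(ols.params, float),
            np.asarray(ols.bse, float),
            np.asarray(ols.pvalues, float),
            0.0,
            float(np.sqrt(ols.mse_resid)),
            len(y),
            n_groups,
            converged=False,
            singular=True,
            cov=np.asarray(ols.cov_params(), float),
        )
        res.flags["ols_fallback"] = True
        fixed_pred = X @ res.estimates
        denom = np.var(fixed_pred) + ols.mse_resid
        res.flags["marginal_r2"] = float(np.var(fixed_pred) / denom) if denom > 0 else 0.0
        return res
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits emit sqrt warnings
        ri_var = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
        params = np.asarray(fit.fe_params, float)
        ses = np.asarray(fit.bse_fe, float)
        cov_fe = np.asarray(fit.cov_params(), float)[: len(params), : len(params)]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(ses > 0, params / ses, 0.0)
    # Wald t with a conservative residual df (obs minus fixed effects minus
    # groups); close to z for large n, less liberal in small strata
    df_t = max(len(y) - X.shape[1] - n_groups, 1)
    pvals = 2 * stats.t.sf(np.abs(z), df_t)
    fixed_pred = X @ params
    resid_var = float(fit.scale)
    denom = np.var(fixed_pred) + ri_var + resid_var
    res = LmmResult(
        names,
        params,
        ses,
        pvals,
        float(np.sqrt(max(ri_var, 0.0))),
        float(np.sqrt(resid_var)),
        len(y),
        n_groups,
        converged=bool(fit.converged),
        singular=ri_var <= 1e-10,
        cov=cov_fe,
    )
    res.flags["marginal_r2"] = float(np.var(fixed_pred) / denom) if denom > 0 else 0.0
    return res


def fit_lmm(
    table: pd.DataFrame,
    response: str,
    fixed: Sequence[str],
    group: str = "tree_id",
) -> LmmResult:
    """Random-intercept linear model of ``response`` on the ``fixed`` columns.

    Requires >= 10 rows; with >= 2 trees the intercept variance is estimated
    by REML (a zero estimate is flagged ``singular``), with a single tree
    the model reduces exactly to OLS.
    """
    sub = table.dropna(subset=[response, *fixed]).reset_index(drop=True)
    if len(sub) < 10:
        raise ValueError(f"need >= 10 rows to fit, got {len(sub)}")
    X = np.column_stack(
        [np.ones(len(sub))] + [sub[c].to_numpy(float) for c in fixed]
    )
    names = ["Intercept", *fixed]
    return _fit_mixed(sub[response].to_numpy(float), X, sub[group].to_numpy(), names)


# ---------------------------------------------------------------------------
# period comparisons and the compact letter display


def _tukey_pvalues(z: np.ndarray, k: int, df: float) -> np.ndarray:
    """Single-step studentized-range adjustment of pairwise z statistics."""
    return stats.studentized_range.sf(np.abs(z) * np.sqrt(2.0), k, df)


def compact_letter_display(
    levels: Sequence, different: Mapping[tuple, bool]
) -> dict:
    """Assign letters so that two levels share a letter iff no significant
    difference separates them (letters = maximal cliques of the
    not-different graph, in level order)."""
    g = nx.Graph()
    g.add_nodes_from(levels)
    for (a, b), diff in different.items():
        if not diff:
            g.add_edge(a, b)
    order = {lv: i for i, lv in enumerate(levels)}
    cliques = sorted(
        (sorted(c, key=order.get) for c in nx.find_cliques(g)),
        key=lambda c: order[c[0]],
    )
    letters = {lv: "" for lv in levels}
    for j, clique in enumerate(cliques):
        ch = chr(ord("a") + j)
        for lv in clique:
            letters[lv] += ch
    return {lv: "".join(sorted(s)) for lv, s in letters.items()}


def compare_period_means(
    table: pd.DataFrame,
    response: str = "ch4_dw_flux",
    period: str = "period",
    group: str = "tree_id",
    alpha: float = 0.05,
) -> dict:
    """Tukey-style simultaneous pairwise comparisons of period means.

    Period means come from a random-intercept model with the period as a
    factor; all pairwise contrasts are tested with the studentized-range
    adjustment and summarised as a compact letter display.  Periods with
    fewer than two observations are excluded (flagged in the result).
    """
    counts = table[period].value_counts()
    keep = sorted(counts[counts >= 2].index)
    excluded = sorted(set(counts.index) - set(keep))
    sub = table[table[period].isin(keep)].reset_index(drop=True)
    if len(keep) < 1:
        raise ValueError("no period with >= 2 observations")
    if len(keep) == 1:
        return {
            "periods": keep,
            "means": {keep[0]: float(sub[response].mean())},
            "pairwise": {},
            "letters": {keep[0]: "a"},
            "excluded_periods": excluded,
        }
    # cell-means coding: one column per period, no global intercept
    dummies = pd.get_dummies(sub[period]).astype(float)
    X = dummies[keep].to_numpy()
    names = [f"period_{p}" for p in keep]
    y = sub[response].to_numpy(float)
    groups = sub[group].to_numpy()
    n_groups = len(pd.unique(groups))
    params = cov = None
    if n_groups >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.MixedLM(y, X, groups=groups)
            for method in (["lbfgs", "cg"], ["powell"], ["nm"]):
                try:
                    fitres = model.fit(reml=True, method=method)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                if np.all(np.isfinite(fitres.fe_params)):
                    params = np.asarray(fitres.fe_params, float)
                    cov = np.asarray(fitres.cov_params(), float)[
                        : len(params), : len(params)
                    ]
                    break
    if params is None:  # single tree or degenerate mixed fit
        fitres = sm.OLS(y, X).fit()
        params = np.asarray(fitres.params, float)
        cov = np.asarray(fitres.cov_params(), float)
    k = len(keep)
    df = max(len(sub) - k, 5)
    pairwise = {}
    different = {}
    for i in range(k):
        for j in range(i + 1, k):
            contrast = np.zeros(k)
            contrast[i], contrast[j] = 1.0, -1.0
            est = float(contrast @ params)
            se = float(np.sqrt(contrast @ cov @ contrast))
            z = est / se if se > 0 else 0.0
            p = float(_tukey_pvalues(np.array([z]), k, df)[0]) if se > 0 else 1.0
            pairwise[(keep[i], keep[j])] = {"diff": est, "se": se, "p_adj": p}
            different[(keep[i], keep[j])] = p < alpha
    letters = compact_letter_display(keep, different)
    return {
        "periods": keep,
        "means": dict(zip(keep, (float(v) for v in params))),
        "pairwise": pairwise,
        "letters": letters,
        "excluded_periods": excluded,
    }


def ttest_vs_empty(
    shoot_fluxes: Mapping[str, Sequence[float]],
    empty_fluxes: Sequence[float],
    min_n: int = 3,
) -> pd.DataFrame:
    """Welch t-test of each shoot chamber's raw (uncorrected, chamber-scale)
    CH4 fluxes against the empty-chamber blanks."""
    empty = np.asarray(empty_fluxes, float)
    rows = []
    for shoot_id, vals in shoot_fluxes.items():
        v = np.asarray(vals, float)
        if len(v) < min_n or len(empty) < min_n:
            rows.append(
                {"shoot_id": shoot_id, "n": len(v), "t": np.nan, "p": np.nan,
                 "mean_diff": np.nan, "insufficient_n": True}
            )
            continue
        t, p = stats.ttest_ind(v, empty, equal_var=False)
        rows.append(
            {"shoot_id": shoot_id, "n": len(v), "t": float(t), "p": float(p),
             "mean_diff": float(v.mean() - empty.mean()), "insufficient_n": False}
        )
    return pd.DataFrame(rows)


def par_split_regression(
    table: pd.DataFrame,
    response: str = "ch4_dw_flux",
    threshold: float = 500.0,
    group: str = "tree_id",
) -> dict:
    """Temperature regressions within low- and high-light strata.

    The split is at 500 umol m^-2 s^-1 PAR with boundary rows included in
    both strata (matching the overlapping <=/>= convention); each stratum
    gets a random-intercept fit of flux on air temperature.
    """
    out: dict = {"threshold": threshold}
    for name, mask in (
        ("low", table["par"] <= threshold),
        ("high", table["par"] >= threshold),
    ):
        sub = table[mask]
        if len(sub) < 10:
            out[name] = {"empty": True, "n": int(len(sub))}
            continue
        fit = fit_lmm(sub, response, ["air_temp"], group=group)
        out[name] = {
            "empty": False,
            "n": int(len(sub)),
            "slope": fit.coef("air_temp"),
            "se": fit.se("air_temp"),
            "p": fit.p("air_temp"),
            "marginal_r2": fit.marginal_r2,
        }
    return out


def helmert_matrix(k: int) -> np.ndarray:
    """Reverse-Helmert coding for ``k`` levels: contrast j compares level
    j+1 against the mean of levels 1..j.  Columns are orthogonal and sum
    to zero."""
    H = np.zeros((k, k - 1))
    for j in range(1, k):
        H[:j, j - 1] = -1.0 / j
        H[j, j - 1] = 1.0
    return H


def temp_bin_interaction(
    table: pd.DataFrame,
    response: str = "ch4_dw_flux",
    bins: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 20.0),
    group: str = "tree_id",
    min_bin_rows: int = 5,
) -> dict:
    """Light-by-temperature interaction: PAR slopes by temperature bin.

    Air temperature is cut into the given bins (values outside are clipped
    into the end bins; bins with fewer than ``min_bin_rows`` rows are merged
    into their neighbour).  A random-intercept model with PAR, the
    Helmert-coded bin factor and their interaction yields a PAR slope +- SE
    per bin and, through the interaction contrasts, a test of whether each
    bin's slope exceeds the mean slope of the colder bins.
    """
    edges = np.asarray(bins, float)
    temp = table["air_temp"].clip(edges[0], edges[-1] - 1e-9).to_numpy(float)
    idx = np.clip(np.searchsorted(edges, temp, side="right") - 1, 0, len(edges) - 2)
    sub = table.copy().reset_index(drop=True)
    sub["_bin"] = idx[: len(sub)]
    # merge sparse bins into the nearest populated neighbour
    merged_note = []
    counts = sub["_bin"].value_counts()
    present = sorted(counts.index)
    for b in present:
        if counts[b] < min_bin_rows and len(present) > 1:
            others = [x for x in present if x != b]
            tgt = min(others, key=lambda x: abs(x - b))
            sub.loc[sub["_bin"] == b, "_bin"] = tgt
            merged_note.append((int(b), int(tgt)))
            counts = sub["_bin"].value_counts()
            present = sorted(counts.index)
    levels = sorted(sub["_bin"].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 populated temperature bins")
    level_pos = {b: i for i, b in enumerate(levels)}
    H = helmert_matrix(k)
    rows_H = H[[level_pos[b] for b in sub["_bin"]], :]
    par = sub["par"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(sub)), par, rows_H, par[:, None] * rows_H]
    )
    names = (
        ["Intercept", "par"]
        + [f"bin_h{j + 1}" for j in range(k - 1)]
        + [f"par:bin_h{j + 1}" for j in range(k - 1)]
    )
    fit = _fit_mixed(sub[response].to_numpy(float), X, sub[group].to_numpy(), names)
    # per-bin PAR slope: base PAR coefficient + Helmert row . interaction coefs
    inter_ix = [names.index(f"par:bin_h{j + 1}") for j in range(k - 1)]
    par_ix = names.index("par")
    per_bin = []
    for b in levels:
        L = np.zeros(len(names))
        L[par_ix] = 1.0
        L[inter_ix] = H[level_pos[b], :]
        slope = float(L @ fit.estimates)
        # boundary variance fits can yield a slightly negative quadratic form
        var = float(L @ fit.cov @ L) if fit.cov is not None else float("nan")
        se = float(np.sqrt(max(var, 0.0))) if np.isfinite(var) else float("nan")
        per_bin.append(
            {
                "bin": int(b),
                "range_c": (float(edges[b]), float(edges[b + 1])),
                "par_slope": slope,
                "se": se,
                "n": int((sub["_bin"] == b).sum()),
            }
        )
    contrasts = [
        {
            "contrast": f"bin>{j}",  # slope of level j+1 vs mean of preceding
            "estimate": fit.coef(f"par:bin_h{j + 1}"),
            "se": fit.se(f"par:bin_h{j + 1}"),
            "p": fit.p(f"par:bin_h{j + 1}"),
        }
        for j in range(k - 1)
    ]
    return {
        "per_bin": per_bin,
        "helmert_contrasts": contrasts,
        "merged_bins": merged_note,
        "fit": fit,
    }


def residual_disentangle(
    table: pd.DataFrame, response: str = "ch4_dw_flux"
) -> dict:
    """Which of two collinear drivers carries the signal?

    Regresses (i) the residuals of flux~temperature on PAR and (ii) the
    residuals of flux~PAR on temperature.  A driver whose residual
    regression stays significant explains variance the other cannot.
    """
    sub = table.dropna(subset=[response, "par", "air_temp"])
    y = sub[response].to_numpy(float)
    par = sub["par"].to_numpy(float)
    temp = sub["air_temp"].to_numpy(float)

    def _ols_resid(yv, xv):
        fit = sm.OLS(yv, sm.add_constant(xv)).fit()
        return yv - fit.fittedvalues

    def _slope_p(yv, xv):
        fit = sm.OLS(yv, sm.add_constant(xv)).fit()
        return {"slope": float(fit.params[1]), "p": float(fit.pvalues[1])}

    return {
        "temp_resid_on_par": _slope_p(_ols_resid(y, temp), par),
        "par_resid_on_temp": _slope_p(_ols_resid(y, par), temp),
    }
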