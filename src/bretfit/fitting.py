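"""Per-experiment estimators for the four assay modes and their aggregation.

The pipeline is: ratio computation -> (kinetics only) vehicle baseline
correction -> per-experiment nonlinear least squares -> cross-experiment
mean +/- SEM.  Affinities and rate constants are fitted on the log10
scale for positivity and conditioning and back-transformed for reporting;
file-boundary units (nM) are used in reported parameter names ending in
``_nM``.

Fitting is per independent experiment followed by averaging, not one
pooled fit: summaries are mean +/- SEM over experiments, and the
kinetically derived Kd is computed as koff/kon within each experiment
before averaging (which is why a table of mean rates need not reproduce
the mean kinetic Kd).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import lmfit
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import models

logger = logging.getLogger(__name__)

__all__ = [
    "InputDataError",
    "IdentifiabilityError",
    "FitResult",
    "RegressionSummary",
    "CompetitionResult",
    "AggregateSummary",
    "compute_bret_ratio",
    "baseline_correct",
    "fit_saturation",
    "fit_association_single",
    "fit_association_global",
    "fit_competition",
    "fit_ic50_regression",
    "fit_concentration_response",
    "aggregate_parameters",
    "power_delta_pki",
    "pki_probe_anova",
]

NM = 1e-9  # molar per nanomolar

# log10 bounds for rate constants (M^-1 min^-1 and min^-1)
LOG_KON_BOUNDS = (3.0, 12.0)
LOG_KOFF_BOUNDS = (-5.0, 2.0)
# log10 bounds for affinities/midpoints in molar: 1 fM .. 100 uM
LOG_CONC_BOUNDS = (-15.0, -4.0)


class InputDataError(ValueError):
    """The plate table lacks the rows or columns an estimator needs."""


class IdentifiabilityError(ValueError):
    """The requested fit is not identifiable from the supplied design."""


@dataclass
class FitResult:
    """One converged (or flagged) per-experiment fit."""

    parameters: Dict[str, float]
    standard_errors: Dict[str, float]
    residual_sd: float
    n_points: int
    converged: bool
    experiment_id: str = ""
    messages: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "parameters": {k: float(v) for k, v in self.parameters.items()},
            "standard_errors": {k: float(v) for k, v in self.standard_errors.items()},
            "residual_sd": float(self.residual_sd),
            "n_points": int(self.n_points),
            "converged": bool(self.converged),
            "messages": list(self.messages),
        }


@dataclass
class RegressionSummary:
    """OLS of IC50 against probe concentration: intercept = Ki, slope = Ki/Kd."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    kd_estimate: Optional[float]
    n_points: int

    def to_dict(self) -> dict:
        return {
            "slope": float(self.slope),
            "intercept_M": float(self.intercept),
            "r_squared": float(self.r_squared),
            "p_value": float(self.p_value),
            "kd_estimate_M": None if self.kd_estimate is None else float(self.kd_estimate),
            "n_points": int(self.n_points),
        }


@dataclass
class CompetitionResult:
    """Per-experiment competition analysis across probe concentrations."""

    experiment_id: str
    per_probe: Dict[float, Dict[str, float]]  # probe conc (M) -> ic50/ki/pki (+flags)
    pooled_pki: float
    regression: Optional[RegressionSummary]

    def to_dict(self) -> dict:
        return {
            "experiment_id": self.experiment_id,
            "per_probe": {
                f"{k * 1e9:g}": {kk: float(vv) for kk, vv in v.items()}
                for k, v in self.per_probe.items()
            },
            "pooled_pki": float(self.pooled_pki),
            "regression": None if self.regression is None else self.regression.to_dict(),
        }


@dataclass
class AggregateSummary:
    """Cross-experiment mean +/- SEM of per-experiment fits."""

    per_experiment: List[FitResult]
    mean: Dict[str, float]
    sem: Dict[str, Optional[float]]
    n: int

    def to_dict(self) -> dict:
        return {
            "n_experiments": int(self.n),
            "mean": {k: float(v) for k, v in self.mean.items()},
            "sem": {
                k: (None if v is None else float(v)) for k, v in self.sem.items()
            },
            "per_experiment": [f.to_dict() for f in self.per_experiment],
        }


# ---------------------------------------------------------------------------
# table preparation
# ---------------------------------------------------------------------------

def compute_bret_ratio(table: pd.DataFrame) -> pd.DataFrame:
    """Fill ``bret_ratio`` as acceptor/donor emission; drop nonpositive-donor rows.

    Rows that already carry a ratio are kept as-is.  Raises
    :class:`InputDataError` if neither channels nor ratios are present.
    """
    out = table.copy()
    have_channels = out["donor_em"].notna() & out["acceptor_em"].notna()
    need = out["bret_ratio"].isna()
    if (need & ~have_channels).any():
        raise InputDataError(
            "rows lack both a bret_ratio and donor/acceptor emission channels"
        )
    bad = have_channels & (out["donor_em"] <= 0)
    if bad.any():
        logger.warning(
            "excluding %d row(s) with nonpositive donor emission", int(bad.sum())
        )
        out = out[~bad].copy()
        have_channels = out["donor_em"].notna() & out["acceptor_em"].notna()
        need = out["bret_ratio"].isna()
    fill = need & have_channels
    out.loc[fill, "bret_ratio"] = (
        out.loc[fill, "acceptor_em"] / out.loc[fill, "donor_em"]
    )
    return out


def baseline_correct(table: pd.DataFrame) -> pd.DataFrame:
    """Subtract each experiment's mean vehicle ratio at time zero.

    Applies to association-mode tables; vehicle wells are the ligand-free
    controls read alongside the kinetic traces.
    """
    out = table.copy()
    for exp, group in out.groupby("experiment_id"):
        veh = group[
            (group["well_type"] == "vehicle") & (group["time_min"] == 0.0)
        ]["bret_ratio"].dropna()
        if veh.empty:
            raise InputDataError(
                f"experiment {exp!r} has no vehicle wells at time zero; "
                "cannot baseline-correct"
            )
        out.loc[group.index, "bret_ratio"] = group["bret_ratio"] - veh.mean()
    return out


def _probe_M(df: pd.DataFrame) -> np.ndarray:
    return df["probe_conc_nM"].to_numpy(dtype=float) * NM


# ---------------------------------------------------------------------------
# least-squares machinery
# ---------------------------------------------------------------------------

def _grid_starts(params: lmfit.Parameters, n: int = 3) -> List[Dict[str, float]]:
    """Deterministic alternative starts spread across each bounded box."""
    starts: List[Dict[str, float]] = []
    for i in range(n):
        frac = (i + 1) / (n + 1)
        start = {}
        for name, par in params.items():
            if not par.vary:
                continue
            lo, hi = par.min, par.max
            if np.isfinite(lo) and np.isfinite(hi):
                start[name] = lo + frac * (hi - lo)
            else:
                start[name] = par.value
        starts.append(start)
    return starts


def _minimize(residual, params: lmfit.Parameters, args=()) -> lmfit.minimizer.MinimizerResult:
    """Levenberg-Marquardt with a deterministic multi-start fallback."""
    result = lmfit.minimize(
        residual, params, args=args, method="leastsq", nan_policy="raise"
    )
    if result.success and np.isfinite(result.chisqr):
        return result
    best = result if np.isfinite(result.chisqr) else None
    for start in _grid_starts(params):
        trial = params.copy()
        for name, value in start.items():
            trial[name].value = value
        res = lmfit.minimize(
            residual, trial, args=args, method="leastsq", nan_policy="raise"
        )
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    return best if best is not None else result


def _stderr(result, name: str) -> float:
    err = result.params[name].stderr
    return float(err) if err is not None and np.isfinite(err) else float("nan")


def _residual_sd(result) -> float:
    dof = max(result.ndata - result.nvarys, 1)
    return float(np.sqrt(result.chisqr / dof))


def _log10_stderr_to_linear(value: float, log_err: float) -> float:
    """Delta-method SE of 10**x given SE of x."""
    if not np.isfinite(log_err):
        return float("nan")
    return float(value * np.log(10.0) * log_err)


# ---------------------------------------------------------------------------
# saturation
# ---------------------------------------------------------------------------

def _fit_saturation_one(exp: str, tot: pd.DataFrame, nsb: pd.DataFrame) -> FitResult:
    L_tot, y_tot = _probe_M(tot), tot["bret_ratio"].to_numpy(dtype=float)
    L_nsb, y_nsb = _probe_M(nsb), nsb["bret_ratio"].to_numpy(dtype=float)

    baseline0 = float(np.min(y_nsb)) if len(y_nsb) else float(np.min(y_tot))
    if len(L_nsb) >= 2 and np.ptp(L_nsb) > 0:
        ns0 = max(float(np.polyfit(L_nsb, y_nsb, 1)[0]), 0.0)
    else:
        ns0 = 0.0
    span = float(np.max(y_tot) - baseline0 - ns0 * np.max(L_tot))
    bmax0 = max(span, 1e-6)
    kd0 = float(np.median(L_tot[L_tot > 0])) if np.any(L_tot > 0) else 1e-9

    params = lmfit.Parameters()
    params.add("log10_kd", value=np.log10(kd0), min=LOG_CONC_BOUNDS[0], max=LOG_CONC_BOUNDS[1])
    params.add("bmax", value=bmax0, min=0.0)
    params.add("ns_slope", value=ns0, min=0.0)
    params.add("baseline", value=baseline0)

    def residual(p, L_t, y_t, L_n, y_n):
        kd = 10.0 ** p["log10_kd"].value
        spec = p["bmax"].value * L_t / (L_t + kd)
        r_tot = p["baseline"].value + spec + p["ns_slope"].value * L_t - y_t
        r_nsb = p["baseline"].value + p["ns_slope"].value * L_n - y_n
        return np.concatenate([r_tot, r_nsb])

    result = _minimize(residual, params, args=(L_tot, y_tot, L_nsb, y_nsb))
    kd = 10.0 ** result.params["log10_kd"].value
    parameters = {
        "kd_nM": kd / NM,
        "bmax": float(result.params["bmax"].value),
        "ns_slope": float(result.params["ns_slope"].value),
        "baseline": float(result.params["baseline"].value),
    }
    errors = {
        "kd_nM": _log10_stderr_to_linear(kd, _stderr(result, "log10_kd")) / NM,
        "bmax": _stderr(result, "bmax"),
        "ns_slope": _stderr(result, "ns_slope"),
        "baseline": _stderr(result, "baseline"),
    }
    return FitResult(
        parameters=parameters,
        standard_errors=errors,
        residual_sd=_residual_sd(result),
        n_points=int(result.ndata),
        converged=bool(result.success and np.isfinite(kd)),
        experiment_id=exp,
    )


def fit_saturation(table: pd.DataFrame) -> AggregateSummary:
    """Joint one-site fit of total and NSB wells, per experiment.

    Total wells follow baseline + Bmax L/(L+Kd) + ns*L and NSB wells
    baseline + ns*L, with baseline and non-specific slope shared between
    the two well sets.  Kd is fitted as log10(Kd) and reported in nM.
    """
    df = table[table["mode"] == "saturation"]
    if df.empty:
        raise InputDataError("no saturation-mode rows in table")
    fits = []
    for exp, group in df.groupby("experiment_id"):
        tot = group[group["well_type"] == "total"]
        nsb = group[group["well_type"] == "nsb"]
        if tot.empty:
            raise InputDataError(
                f"experiment {exp!r} has only NSB wells; nothing to fit"
            )
        n_concs = tot["probe_conc_nM"].nunique()
        if n_concs < 4:
            warnings.warn(
                f"experiment {exp!r}: only {n_concs} probe concentrations; "
                "Kd estimate may be poorly constrained",
                stacklevel=2,
            )
        fits.append(_fit_saturation_one(str(exp), tot, nsb))
    return aggregate_parameters(fits)


# ---------------------------------------------------------------------------
# association kinetics
# ---------------------------------------------------------------------------

def fit_association_single(t, y) -> FitResult:
    """Fit one baseline-corrected time course to B_eq (1 - exp(-k_obs t)).

    Returns parameters ``b_eq`` (signal units) and ``k_obs`` (min^-1).
    A flat trace is flagged unconverged with ``k_obs`` = NaN.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 5:
        raise InputDataError("need >= 5 timepoints to fit an association curve")
    if np.ptp(y) == 0.0:
        return FitResult(
            parameters={"b_eq": float(np.mean(y)), "k_obs": float("nan")},
            standard_errors={"b_eq": float("nan"), "k_obs": float("nan")},
            residual_sd=0.0,
            n_points=int(t.size),
            converged=False,
            messages=["flat trace: observed rate unidentifiable"],
        )

    b0 = float(np.max(y))
    # time at which the trace first crosses (1 - 1/e) of its apparent plateau
    target = (1.0 - np.exp(-1.0)) * b0
    above = np.nonzero(y >= target)[0]
    t_char = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(np.median(t[t > 0]))
    k0 = 1.0 / max(t_char, 1e-6)

    params = lmfit.Parameters()
    params.add("b_eq", value=b0)
    params.add("log10_kobs", value=np.log10(k0), min=-6.0, max=3.0)

    def residual(p, t_, y_):
        k = 10.0 ** p["log10_kobs"].value
        return p["b_eq"].value * (1.0 - np.exp(-k * t_)) - y_

    result = _minimize(residual, params, args=(t, y))
    k_obs = 10.0 ** result.params["log10_kobs"].value
    messages = []
    if np.max(t) * k_obs < models.LN2:
        messages.append(
            "time window shorter than one half-time; k_obs poorly constrained"
        )
        warnings.warn(messages[-1], stacklevel=2)
    return FitResult(
        parameters={"b_eq": float(result.params["b_eq"].value), "k_obs": float(k_obs)},
        standard_errors={
            "b_eq": _stderr(result, "b_eq"),
            "k_obs": _log10_stderr_to_linear(k_obs, _stderr(result, "log10_kobs")),
        },
        residual_sd=_residual_sd(result),
        n_points=int(t.size),
        converged=bool(result.success),
        messages=messages,
    )


def _fit_association_one(exp: str, group: pd.DataFrame) -> FitResult:
    L = _probe_M(group)
    t = group["time_min"].to_numpy(dtype=float)
    y = group["bret_ratio"].to_numpy(dtype=float)

    # initialize from per-concentration single-curve fits: k_obs is linear
    # in L with slope kon and intercept koff
    concs = np.unique(L)
    conc_used, kobs_hat, beq_hat = [], [], []
    for c in concs:
        sel = L == c
        try:
            single = fit_association_single(t[sel], y[sel])
        except InputDataError:
            continue
        if single.converged and np.isfinite(single.parameters["k_obs"]):
            conc_used.append(c)
            kobs_hat.append(single.parameters["k_obs"])
            beq_hat.append(single.parameters["b_eq"])
    if len(kobs_hat) >= 2:
        slope, intercept = np.polyfit(conc_used, kobs_hat, 1)
        kon0 = float(np.clip(slope, 10.0 ** LOG_KON_BOUNDS[0], 10.0 ** LOG_KON_BOUNDS[1]))
        koff0 = float(np.clip(intercept, 10.0 ** LOG_KOFF_BOUNDS[0], 10.0 ** LOG_KOFF_BOUNDS[1]))
    else:
        kon0, koff0 = 1e7, 0.1
    kd0 = koff0 / kon0
    occ = np.max(concs) / (np.max(concs) + kd0)
    bmax0 = max((np.max(beq_hat) if beq_hat else np.max(y)) / max(occ, 1e-6), 1e-6)

    params = lmfit.Parameters()
    params.add("log10_kon", value=np.log10(kon0), min=LOG_KON_BOUNDS[0], max=LOG_KON_BOUNDS[1])
    params.add("log10_koff", value=np.log10(koff0), min=LOG_KOFF_BOUNDS[0], max=LOG_KOFF_BOUNDS[1])
    params.add("bmax", value=bmax0, min=0.0)

    def residual(p, L_, t_, y_):
        kon = 10.0 ** p["log10_kon"].value
        koff = 10.0 ** p["log10_koff"].value
        beq = p["bmax"].value * L_ / (L_ + koff / kon)
        return beq * (1.0 - np.exp(-(kon * L_ + koff) * t_)) - y_

    result = _minimize(residual, params, args=(L, t, y))
    kon = 10.0 ** result.params["log10_kon"].value
    koff = 10.0 ** result.params["log10_koff"].value
    parameters = {
        "kon": float(kon),
        "koff": float(koff),
        "bmax": float(result.params["bmax"].value),
        "kinetic_kd_nM": float(koff / kon / NM),
    }
    kon_err = _log10_stderr_to_linear(kon, _stderr(result, "log10_kon"))
    koff_err = _log10_stderr_to_linear(koff, _stderr(result, "log10_koff"))
    kd_rel = np.hypot(
        kon_err / kon if np.isfinite(kon_err) else np.nan,
        koff_err / koff if np.isfinite(koff_err) else np.nan,
    )
    errors = {
        "kon": kon_err,
        "koff": koff_err,
        "bmax": _stderr(result, "bmax"),
        "kinetic_kd_nM": float(parameters["kinetic_kd_nM"] * kd_rel),
    }
    return FitResult(
        parameters=parameters,
        standard_errors=errors,
        residual_sd=_residual_sd(result),
        n_points=int(result.ndata),
        converged=bool(result.success),
        experiment_id=exp,
    )


def fit_association_global(table: pd.DataFrame) -> AggregateSummary:
    """Global exponential-association fit with shared kon, koff and Bmax.

    Expects a baseline-corrected association table (see
    :func:`baseline_correct`); only ``total`` wells enter the fit.  Within
    each experiment, all concentrations are fitted simultaneously; the
    kinetic Kd (koff/kon, nM) is computed per experiment and aggregated
    alongside the rates.
    """
    df = table[(table["mode"] == "association") & (table["well_type"] == "total")]
    if df.empty:
        raise InputDataError("no association-mode total wells in table")
    fits = []
    for exp, group in df.groupby("experiment_id"):
        if group["probe_conc_nM"].nunique() < 2:
            raise IdentifiabilityError(
                f"experiment {exp!r} has a single probe concentration: kon and "
                "koff are not separately identifiable; use "
                "fit_association_single for k_obs at one concentration"
            )
        fits.append(_fit_association_one(str(exp), group))
    return aggregate_parameters(fits)


# ---------------------------------------------------------------------------
# competition
# ---------------------------------------------------------------------------

def _fit_competition_curve(I: np.ndarray, y: np.ndarray, free_hill: bool) -> Tuple[dict, bool, list]:
    nonzero = I[I > 0]
    top0 = float(np.mean(y[I == np.min(I)]))
    bot0 = float(np.mean(y[I == np.max(I)]))
    mid = 0.5 * (top0 + bot0)
    order = np.argsort(I)
    below = np.nonzero(y[order] <= mid)[0]
    if below.size and I[order][below[0]] > 0:
        ic50_0 = float(I[order][below[0]])
    else:
        ic50_0 = float(np.exp(np.mean(np.log(nonzero)))) if nonzero.size else 1e-9

    params = lmfit.Parameters()
    params.add("log10_ic50", value=np.log10(ic50_0), min=LOG_CONC_BOUNDS[0], max=LOG_CONC_BOUNDS[1])
    params.add("top", value=top0)
    params.add("bottom", value=bot0)
    params.add("hill", value=1.0, vary=free_hill, min=0.2, max=5.0)

    def residual(p, I_, y_):
        ic50 = 10.0 ** p["log10_ic50"].value
        frac = 1.0 / (1.0 + (I_ / ic50) ** p["hill"].value)
        return p["bottom"].value + (p["top"].value - p["bottom"].value) * frac - y_

    result = _minimize(residual, params, args=(I, y))
    ic50 = 10.0 ** result.params["log10_ic50"].value
    top = float(result.params["top"].value)
    bottom = float(result.params["bottom"].value)
    messages = []
    ok = bool(result.success)
    if top < bottom:
        messages.append("non-physical fit: top < bottom")
        ok = False
    out = {
        "ic50": float(ic50),
        "ic50_se": _log10_stderr_to_linear(ic50, _stderr(result, "log10_ic50")),
        "top": top,
        "bottom": bottom,
        "hill": float(result.params["hill"].value),
        "residual_sd": _residual_sd(result),
        "n_points": int(result.ndata),
    }
    return out, ok, messages


def fit_competition(
    table: pd.DataFrame,
    probe_kd: float,
    free_hill: bool = False,
) -> Tuple[List[CompetitionResult], AggregateSummary]:
    """Per-probe IC50 fits, Cheng-Prusoff Ki, pooled pKi and the
    IC50-vs-probe regression, per experiment.

    Parameters
    ----------
    table : plate table in competition mode.
    probe_kd : float
        Probe equilibrium dissociation constant in molar (from a prior
        saturation analysis).
    free_hill : bool
        Let the slope factor vary (default fixes it at 1, the mass-action
        expectation).

    Returns the list of per-experiment :class:`CompetitionResult` plus an
    :class:`AggregateSummary` of the pooled pKi (and the regression-based
    Kd estimate, in nM) across experiments.
    """
    if not (np.isfinite(probe_kd) and probe_kd > 0):
        raise models.InvalidParameterError(f"probe_kd must be > 0, got {probe_kd!r}")
    df = table[table["mode"] == "competition"]
    if df.empty:
        raise InputDataError("no competition-mode rows in table")

    results: List[CompetitionResult] = []
    fits: List[FitResult] = []
    for exp, group in df.groupby("experiment_id"):
        per_probe: Dict[float, Dict[str, float]] = {}
        kis: List[float] = []
        points: List[Tuple[float, float]] = []
        any_bad = False
        for probe_nM, curve_df in group.groupby("probe_conc_nM"):
            L = float(probe_nM) * NM
            I = curve_df["competitor_conc_nM"].to_numpy(dtype=float) * NM
            y = curve_df["bret_ratio"].to_numpy(dtype=float)
            if np.unique(I).size < 4:
                warnings.warn(
                    f"experiment {exp!r}, probe {probe_nM:g} nM: fewer than 4 "
                    "competitor concentrations; IC50 may be unreliable",
                    stacklevel=2,
                )
            curve, ok, msgs = _fit_competition_curve(I, y, free_hill)
            ki = models.cheng_prusoff_ki(curve["ic50"], L, probe_kd)
            per_probe[L] = {**curve, "ki": ki, "pki": -np.log10(ki), "converged": float(ok)}
            if ok:
                kis.append(ki)
                points.append((L, curve["ic50"]))
            else:
                any_bad = True
                logger.warning("experiment %s probe %g nM: %s", exp, probe_nM, msgs)
        if not kis:
            fits.append(
                FitResult({}, {}, float("nan"), int(len(group)), False, str(exp),
                          ["no probe concentration yielded a usable IC50"])
            )
            results.append(CompetitionResult(str(exp), per_probe, float("nan"), None))
            continue
        # pooled pKi: average Ki on the linear scale, then take -log10
        pooled_pki = float(-np.log10(np.mean(kis)))
        regression = fit_ic50_regression(points) if len(points) >= 3 else None
        results.append(CompetitionResult(str(exp), per_probe, pooled_pki, regression))
        parameters = {"pki": pooled_pki, "ki_nM": float(np.mean(kis) / NM)}
        if regression is not None and regression.kd_estimate is not None:
            parameters["kd_estimate_nM"] = regression.kd_estimate / NM
        fits.append(
            FitResult(
                parameters=parameters,
                standard_errors={k: float("nan") for k in parameters},
                residual_sd=float(
                    np.mean([v["residual_sd"] for v in per_probe.values()])
                ),
                n_points=int(len(group)),
                converged=not any_bad,
                experiment_id=str(exp),
            )
        )
    summary = aggregate_parameters(fits, require_converged=False)
    return results, summary


def fit_ic50_regression(points: Sequence[Tuple[float, float]]) -> RegressionSummary:
    """Ordinary least squares of IC50 (M) on probe concentration (M).

    Under competitive mass action the line's intercept estimates the
    competitor Ki and the slope Ki/Kd, so intercept/slope estimates the
    probe Kd.  A nonpositive slope leaves ``kd_estimate`` as None.
    """
    pts = [(float(L), float(ic50)) for L, ic50 in points]
    if len(pts) < 3:
        raise InputDataError("need >= 3 (probe, IC50) points for the regression")
    L = np.array([p[0] for p in pts])
    ic50 = np.array([p[1] for p in pts])
    X = sm.add_constant(L)
    ols = sm.OLS(ic50, X).fit()
    intercept, slope = float(ols.params[0]), float(ols.params[1])
    if slope > 0:
        kd_estimate = intercept / slope
    else:
        kd_estimate = None
        logger.warning("IC50-vs-probe slope is nonpositive; Kd estimate undefined")
    return RegressionSummary(
        slope=slope,
        intercept=intercept,
        r_squared=float(ols.rsquared),
        p_value=float(ols.pvalues[1]),
        kd_estimate=kd_estimate,
        n_points=len(pts),
    )


# ---------------------------------------------------------------------------
# concentration-response
# ---------------------------------------------------------------------------

def _fit_cr_one(exp: str, group: pd.DataFrame, free_hill: bool) -> FitResult:
    conc = _probe_M(group)
    y = group["bret_ratio"].to_numpy(dtype=float)
    if np.ptp(y) == 0.0:
        return FitResult(
            parameters={"pec50": float("nan"), "emax": float(np.mean(y)),
                        "basal": float(np.mean(y)), "hill": 1.0},
            standard_errors={k: float("nan") for k in ("pec50", "emax", "basal", "hill")},
            residual_sd=0.0,
            n_points=int(len(y)),
            converged=False,
            experiment_id=exp,
            messages=["flat response: EC50 unidentifiable"],
        )
    basal0 = float(np.mean(y[conc == np.min(conc)]))
    emax0 = float(np.mean(y[conc == np.max(conc)]))
    mid = 0.5 * (basal0 + emax0)
    nonzero = conc[conc > 0]
    order = np.argsort(conc)
    crossing = np.nonzero((y[order] >= mid) if emax0 >= basal0 else (y[order] <= mid))[0]
    if crossing.size and conc[order][crossing[0]] > 0:
        ec50_0 = float(conc[order][crossing[0]])
    else:
        ec50_0 = float(np.exp(np.mean(np.log(nonzero))))

    params = lmfit.Parameters()
    params.add("log10_ec50", value=np.log10(ec50_0), min=LOG_CONC_BOUNDS[0], max=LOG_CONC_BOUNDS[1])
    params.add("emax", value=emax0)
    params.add("basal", value=basal0)
    params.add("hill", value=1.0, vary=free_hill, min=0.2, max=5.0)

    def residual(p, c_, y_):
        ec50 = 10.0 ** p["log10_ec50"].value
        safe = np.where(c_ > 0, c_, 1.0)
        with np.errstate(divide="ignore", over="ignore"):
            ratio = np.where(c_ > 0, (ec50 / safe) ** p["hill"].value, np.inf)
        return p["basal"].value + (p["emax"].value - p["basal"].value) / (1.0 + ratio) - y_

    result = _minimize(residual, params, args=(conc, y))
    log_ec50 = float(result.params["log10_ec50"].value)
    parameters = {
        "pec50": -log_ec50,
        "emax": float(result.params["emax"].value),
        "basal": float(result.params["basal"].value),
        "hill": float(result.params["hill"].value),
    }
    errors = {
        "pec50": _stderr(result, "log10_ec50"),
        "emax": _stderr(result, "emax"),
        "basal": _stderr(result, "basal"),
        "hill": _stderr(result, "hill") if free_hill else 0.0,
    }
    return FitResult(
        parameters=parameters,
        standard_errors=errors,
        residual_sd=_residual_sd(result),
        n_points=int(result.ndata),
        converged=bool(result.success),
        experiment_id=exp,
    )


def fit_concentration_response(table: pd.DataFrame, free_hill: bool = False) -> AggregateSummary:
    """Logistic concentration-response fit per experiment; reports pEC50
    (-log10 M), emax and basal, aggregated across experiments."""
    df = table[table["mode"] == "concentration_response"]
    if df.empty:
        raise InputDataError("no concentration_response-mode rows in table")
    fits = []
    for exp, group in df.groupby("experiment_id"):
        if group["probe_conc_nM"].nunique() < 5:
            warnings.warn(
                f"experiment {exp!r}: fewer than 5 concentrations; EC50 may be "
                "poorly constrained",
                stacklevel=2,
            )
        fits.append(_fit_cr_one(str(exp), group, free_hill))
    return aggregate_parameters(fits)


# ---------------------------------------------------------------------------
# aggregation & statistics
# ---------------------------------------------------------------------------

def aggregate_parameters(
    fits: Sequence[FitResult],
    scales: Optional[Dict[str, str]] = None,
    require_converged: bool = True,
) -> AggregateSummary:
    """Mean +/- SEM of per-experiment parameter estimates.

    ``scales`` maps a parameter name to ``"linear"`` (default) or
    ``"log"``; log-scale parameters are averaged as log10 values and
    reported under ``log10_<name>``.  SEM is the sample SD over
    experiments divided by sqrt(n); with a single usable fit it is
    reported as None.
    """
    scales = scales or {}
    fits = list(fits)
    used = [f for f in fits if f.converged] if require_converged else list(fits)
    dropped = len(fits) - len(used)
    if dropped:
        warnings.warn(
            f"excluding {dropped} unconverged fit(s) from aggregation",
            stacklevel=2,
        )
    keys: List[str] = []
    for f in used:
        for k in f.parameters:
            if k not in keys:
                keys.append(k)
    mean: Dict[str, float] = {}
    sem: Dict[str, Optional[float]] = {}
    for k in keys:
        values = np.array(
            [f.parameters[k] for f in used if k in f.parameters and np.isfinite(f.parameters[k])]
        )
        out_key = k
        if scales.get(k) == "log":
            values = np.log10(values)
            out_key = f"log10_{k}"
        if values.size == 0:
            continue
        mean[out_key] = float(np.mean(values))
        sem[out_key] = (
            float(np.std(values, ddof=1) / np.sqrt(values.size)) if values.size >= 2 else None
        )
    return AggregateSummary(per_experiment=fits, mean=mean, sem=sem, n=len(used))


def power_delta_pki(
    n_per_group: int, sd: float, delta: float, alpha: float = 0.05
) -> float:
    """Power of a two-sample two-sided t test to detect a pKi shift.

    ``n_per_group`` independent experiments per fluorescent probe, common
    standard deviation ``sd`` (pKi log units), true difference ``delta``.
    Computed exactly from the noncentral t distribution.
    """
    if not 0.0 < alpha < 1.0:
        raise InputDataError(f"alpha must lie in (0, 1), got {alpha!r}")
    if n_per_group < 2:
        raise InputDataError("need n >= 2 per group")
    if sd <= 0:
        raise InputDataError("sd must be > 0")
    df = 2 * n_per_group - 2
    ncp = abs(delta) / (sd * np.sqrt(2.0 / n_per_group))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    return float(
        1.0 - stats.nct.cdf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp)
    )


def pki_probe_anova(results: Sequence[CompetitionResult]) -> Tuple[float, float]:
    """One-way fixed-effects ANOVA of per-experiment pKi across probe
    concentrations (tests probe dependence of the competitor affinity)."""
    groups: Dict[float, List[float]] = {}
    for res in results:
        for L, curve in res.per_probe.items():
            if curve.get("converged"):
                groups.setdefault(L, []).append(curve["pki"])
    usable = [v for v in groups.values() if len(v) >= 2]
    if len(usable) < 2:
        raise InputDataError("need >= 2 probe concentrations with >= 2 experiments each")
    f_stat, p_value = stats.f_oneway(*usable)
    return float(f_stat), float(p_value)
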