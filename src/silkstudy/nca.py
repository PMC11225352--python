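"""Noncompartmental pharmacokinetics for Posiphen and its N1/N8 metabolites.

Model-free summaries of a concentration-time profile: AUC(0-24) by linear
trapezoid on observed points, Cmax/Tmax (earliest on ties), terminal slope
lambda_z by best-adjusted-r2 log-linear regression over suffixes strictly
after Tmax, and the derived dose-normalized parameters Cl/F, Vz/F and t1/2.
Arm-level tables report geometric mean (%GCV), with median (min-max) for
Tmax, following the usual PK reporting convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import ConcentrationSeries

LN2 = float(np.log(2.0))


class InsufficientDataError(ValueError):
    pass


class LambdaUndefinedError(ValueError):
    """No credible terminal elimination phase (flat or rising tail)."""


@dataclass
class NcaResult:
    subject_id: str
    analyte: str
    matrix: str
    auc_0_24: float              # h*ng/mL
    cmax: float                  # ng/mL
    tmax: float                  # h
    lambda_z: float | None       # 1/h
    t_half: float | None         # h
    vz_f: float | None           # L
    cl_f: float | None           # L/h
    n_lambda_points: int | None
    lambda_r2_adj: float | None


def _observed(series: ConcentrationSeries):
    return series.observed_times, series.observed_values


def auc_0_24(series: ConcentrationSeries) -> float:
    """Linear-trapezoid AUC over observed points in [0, 24] h; no
    extrapolation beyond the last observed point."""
    t, v = _observed(series)
    m = (t >= 0) & (t <= 24)
    if m.sum() < 2:
        raise InsufficientDataError(
            f"{series.subject_id}/{series.analyte}: need >= 2 points in "
            "[0, 24] h")
    return float(np.trapezoid(v[m], t[m]))


def auc_interval(series: ConcentrationSeries, lo: float, hi: float) -> float:
    """Linear-trapezoid AUC over observed points in [lo, hi]."""
    t, v = _observed(series)
    m = (t >= lo) & (t <= hi)
    if m.sum() < 2:
        raise InsufficientDataError("need >= 2 points in the interval")
    return float(np.trapezoid(v[m], t[m]))


def cmax_tmax(series: ConcentrationSeries) -> tuple[float, float]:
    """Maximum observed concentration and its time (earliest on ties)."""
    t, v = _observed(series)
    if len(v) == 0:
        raise InsufficientDataError("all samples missing")
    i = int(np.argmax(v))  # argmax returns the first maximum
    return float(v[i]), float(t[i])


def lambda_z(series: ConcentrationSeries) -> tuple[float, int, float]:
    """Terminal elimination rate by log-linear regression.

    Candidate point sets are all suffixes of >= 3 positive concentrations
    strictly after Tmax; the suffix with maximal adjusted r2 wins, and the
    slope must be negative (lambda_z > 0) or the terminal phase is declared
    undefined.
    """
    t, v = _observed(series)
    _, tmax = cmax_tmax(series)
    m = (t > tmax) & (v > 0)
    tt, vv = t[m], np.log(v[m])
    n = len(tt)
    if n < 3:
        raise InsufficientDataError(
            "need >= 3 positive concentrations after Tmax")
    best = None
    for start in range(n - 2):
        ts, ys = tt[start:], vv[start:]
        k = len(ts)
        slope, intercept, r, _, _ = sps.linregress(ts, ys)
        r2_adj = 1.0 - (1.0 - r * r) * (k - 1) / (k - 2)
        if slope < 0 and (best is None or r2_adj > best[2] + 1e-15):
            best = (float(-slope), k, float(r2_adj))
    if best is None:
        raise LambdaUndefinedError(
            f"{series.subject_id}/{series.analyte}: no decreasing terminal "
            "phase")
    return best


def derived_params(dose_mg: float, auc: float,
                   lam: float | None) -> tuple[float, float | None, float | None]:
    """(Cl/F L/h, Vz/F L, t1/2 h) from dose and exposure; Vz/F and t1/2 are
    None when lambda_z is undefined."""
    if not auc > 0:
        raise ValueError("AUC must be positive")
    cl_f = dose_mg * 1000.0 / auc          # mg->ng is 1e6, mL->L is 1e-3
    if lam is None:
        return cl_f, None, None
    return cl_f, cl_f / lam, LN2 / lam


def nca_subject(series: ConcentrationSeries, dose_mg: float | None = None
                ) -> NcaResult:
    """Full per-subject, per-analyte NCA parameter set."""
    auc = auc_0_24(series)
    cmax, tmax = cmax_tmax(series)
    try:
        lam, n_pts, r2 = lambda_z(series)
    except (InsufficientDataError, LambdaUndefinedError):
        lam = n_pts = r2 = None
    cl_f = vz_f = t_half = None
    if dose_mg is not None and auc > 0:
        cl_f, vz_f, t_half = derived_params(dose_mg, auc, lam)
    elif lam is not None:
        t_half = LN2 / lam
    return NcaResult(series.subject_id, series.analyte, series.matrix,
                     auc, cmax, tmax, lam, t_half, vz_f, cl_f, n_pts, r2)


@dataclass(frozen=True)
class PkSummary:
    n: int
    geometric_mean: float
    percent_gcv: float
    median: float
    minimum: float
    maximum: float


def geo_summary(values) -> PkSummary:
    """Geometric mean, %GCV (from the sample variance of the logs), and the
    median (min-max) convention used for Tmax."""
    x = np.asarray(values, float)
    if x.size == 0:
        raise InsufficientDataError("empty value set")
    bad = np.where(x <= 0)[0]
    if bad.size:
        raise ValueError(f"nonpositive values at positions {bad.tolist()}; "
                         "geometric statistics undefined")
    logs = np.log(x)
    gm = float(np.exp(logs.mean()))
    s2 = float(np.var(logs, ddof=1)) if x.size > 1 else 0.0
    gcv = 100.0 * float(np.sqrt(np.expm1(s2)))
    return PkSummary(int(x.size), gm, gcv, float(np.median(x)),
                     float(x.min()), float(x.max()))


def plasma_csf_correlation(auc_table: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of plasma vs CSF exposure per analyte.

    ``auc_table`` is long with columns subject_id, analyte, matrix, auc_0_24.
    """
    rows = []
    for analyte, g in auc_table.groupby("analyte"):
        wide = g.pivot(index="subject_id", columns="matrix", values="auc_0_24")
        if not {"plasma", "CSF"} <= set(wide.columns):
            continue
        paired = wide[["plasma", "CSF"]].dropna()
        if len(paired) < 4:
            raise InsufficientDataError(
                f"{analyte}: need >= 4 plasma/CSF pairs")
        x, y = paired["plasma"].to_numpy(), paired["CSF"].to_numpy()
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"{analyte}: constant exposures, rank "
                             "correlation undefined")
        rho, p = sps.spearmanr(x, y)
        rows.append({"analyte": analyte, "spearman_rho": float(rho),
                     "p": float(p), "n": len(paired)})
    return pd.DataFrame(rows)
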