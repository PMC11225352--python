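"""Fractional synthesis rate (FSR) estimation and group comparison.

FSR is the slope of the CSF labeled-fraction upslope divided by the plasma
leucine plateau enrichment (precursor normalization), units 1/h.  Two window
choices are provided: the prespecified fixed 6-16 h window, and an automated
detector driven by the slope of the SILK curve.  Missing samples are dropped,
never interpolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_model import SilkSeries, ConcentrationSeries


class InsufficientDataError(ValueError):
    pass


class NormalizationError(ValueError):
    pass


class DetectionError(ValueError):
    """No credible upslope found in the SILK curve."""


@dataclass(frozen=True)
class FsrResult:
    subject_id: str
    isoform: str
    window: tuple[float, float]
    slope: float          # fraction/h
    normalization: float  # plasma leucine plateau enrichment
    fsr: float            # 1/h
    r_squared: float
    n_points: int


def plateau_enrichment(leucine: ConcentrationSeries,
                       window: tuple[float, float] = (4.0, 9.0)) -> float:
    """Mean plasma leucine enrichment over the infusion plateau."""
    t, v = leucine.observed_times, leucine.observed_values
    m = (t >= window[0]) & (t <= window[1])
    if not m.any():
        raise InsufficientDataError("no leucine samples in the plateau window")
    return float(np.mean(v[m]))


def _ols_line(t: np.ndarray, y: np.ndarray):
    tbar, ybar = t.mean(), y.mean()
    sxx = np.sum((t - tbar) ** 2)
    sxy = np.sum((t - tbar) * (y - ybar))
    slope = sxy / sxx
    resid = y - (ybar + slope * (t - tbar))
    sst = np.sum((y - ybar) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / sst if sst > 0 else 1.0
    return float(slope), float(r2)


def fsr_fixed_window(silk: SilkSeries, plateau: float,
                     window: tuple[float, float] = (6.0, 16.0)) -> FsrResult:
    """OLS slope of the labeled fraction over ``window``, normalized by the
    precursor plateau enrichment."""
    if not plateau > 0:
        raise NormalizationError(f"plateau enrichment {plateau:g} must be > 0")
    t, y = silk.observed_times, silk.observed_values
    m = (t >= window[0]) & (t <= window[1])
    if m.sum() < 3:
        raise InsufficientDataError(
            f"{silk.subject_id}/{silk.isoform}: only {int(m.sum())} points in "
            f"window {window}; need >= 3")
    slope, r2 = _ols_line(t[m], y[m])
    return FsrResult(silk.subject_id, silk.isoform, tuple(window), slope,
                     plateau, slope / plateau, r2, int(m.sum()))


def detect_upslope(silk: SilkSeries,
                   trim_fraction: float = 0.2) -> tuple[float, float]:
    """Automated upslope window from the slope of the SILK curve.

    3-point running-median smoothing, first differences, then the contiguous
    run of positive differences containing the steepest rise.  Edge segments
    of the run rising at less than ``trim_fraction`` of the steepest rise are
    trimmed (the near-flat lead-in before the label arrives and the rollover
    into the peak are not upslope); the window is then widened symmetrically
    (earliest first) to cover at least 4 samples.
    """
    t, y = silk.observed_times, silk.observed_values
    n = len(t)
    if n < 6:
        raise InsufficientDataError(
            f"{silk.subject_id}/{silk.isoform}: need >= 6 points, have {n}")
    sm = y.copy()
    for i in range(1, n - 1):
        sm[i] = np.median(y[i - 1:i + 2])
    d = np.diff(sm)
    pos = d > 0
    # contiguous positive runs as (start, stop) difference-index slices
    runs = []
    i = 0
    while i < n - 1:
        if pos[i]:
            j = i
            while j + 1 < n - 1 and pos[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    if not any(j - i + 1 >= 3 for i, j in runs):
        raise DetectionError(
            f"{silk.subject_id}/{silk.isoform}: no positive run of >= 3 "
            "differences; curve has no credible upslope")
    imax = int(np.argmax(d))
    run = next(((i, j) for i, j in runs if i <= imax <= j), None)
    if run is None:  # steepest diff not positive: fall back to earliest long run
        run = next((i, j) for i, j in runs if j - i + 1 >= 3)
    rlo, rhi = run
    dmax = d[rlo:rhi + 1].max()
    while rlo < rhi and d[rlo] < trim_fraction * dmax:
        rlo += 1
    while rhi > rlo and d[rhi] < trim_fraction * dmax:
        rhi -= 1
    lo, hi = rlo, rhi + 1                # sample indices spanned by the run
    while hi - lo + 1 < 4:               # enforce >= 4 samples, earliest first
        if lo > 0:
            lo -= 1
        elif hi < n - 1:
            hi += 1
        else:
            break
    return float(t[lo]), float(t[hi])


def fsr_auto_window(silk: SilkSeries, plateau: float) -> FsrResult:
    """FSR over the automatically detected upslope window."""
    return fsr_fixed_window(silk, plateau, window=detect_upslope(silk))


def newly_synthesized_series(conc_at_t0: float, silk: SilkSeries):
    """Newly synthesized Abeta: baseline concentration x labeled fraction.

    Returns (times, values in pg/mL, AUC over the observed span, pg*h/mL)
    with the AUC by linear trapezoid on non-missing samples.
    """
    if conc_at_t0 < 0:
        raise ValueError("baseline concentration must be nonnegative")
    t, f = silk.observed_times, silk.observed_values
    values = conc_at_t0 * f
    auc = float(np.trapezoid(values, t)) if len(t) >= 2 else 0.0
    return t, values, auc


@dataclass(frozen=True)
class AnovaTable:
    f: float
    df_between: int
    df_within: int
    p: float


def compare_fsr_groups(table: pd.DataFrame, value_col: str = "fsr",
                       group_col: str = "arm") -> AnovaTable:
    """One-way fixed-effects ANOVA of FSR by treatment arm."""
    groups = [g[value_col].to_numpy(float) for _, g in table.groupby(group_col)]
    if len(groups) < 2:
        raise InsufficientDataError("need >= 2 groups for ANOVA")
    if any(len(g) < 2 for g in groups):
        raise InsufficientDataError("every group needs >= 2 observations")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(np.sum((g - g.mean()) ** 2) for g in groups)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    if ss_between == 0.0:
        return AnovaTable(0.0, df_b, df_w, 1.0)
    if ss_within == 0.0:
        return AnovaTable(np.inf, df_b, df_w, 0.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(sps.f.sf(f, df_b, df_w))
    return AnovaTable(float(f), df_b, df_w, p)


def isoform_correlation(table: pd.DataFrame, value_col: str = "fsr"
                        ) -> pd.DataFrame:
    """Pearson r (and two-sided p) between FSR estimates of isoform pairs.

    ``table`` is long with columns subject_id, isoform, ``value_col``.
    """
    wide = table.pivot(index="subject_id", columns="isoform", values=value_col)
    rows = []
    isoforms = list(wide.columns)
    for i, a in enumerate(isoforms):
        for b in isoforms[i + 1:]:
            paired = wide[[a, b]].dropna()
            if len(paired) < 4:
                raise InsufficientDataError(
                    f"{a} vs {b}: need >= 4 paired observations")
            x, y = paired[a].to_numpy(), paired[b].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                raise ValueError(f"{a} vs {b}: constant vector, correlation "
                                 "undefined")
            r, p = sps.pearsonr(x, y)
            rows.append({"isoform_a": a, "isoform_b": b, "r": float(r),
                         "p": float(p), "n": len(paired)})
    return pd.DataFrame(rows)
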