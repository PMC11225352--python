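"""Trial statistics: baseline-table tests, change-score ANCOVA, dose-response
with a pre-treatment covariate, and the design power calculation.

Baseline categorical rows use Pearson's chi-square without continuity
correction and the two-sided Fisher exact test (both are exposed because
small-trial baseline tables mix the two); continuous rows use the pooled
two-sample t computable from printed group summaries.  Change analyses are
ordinary least squares with age and sex (optionally baseline MMSE) as
covariates; power for the two-sample design uses the noncentral t.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


class SingularDesignError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = arm, columns = trait: [[a, b], [c, d]]."""
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be nonnegative integers")
        if self.a + self.b + self.c + self.d < 1:
            raise ValueError("table must contain at least one observation")

    @property
    def array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], int)


def pearson_chi2_2x2(table: ContingencyTable2x2) -> tuple[float, float]:
    """Uncorrected Pearson chi-square: n(ad-bc)^2 / product of margins."""
    a, b, c, d = table.a, table.b, table.c, table.d
    n = a + b + c + d
    margins = (a + b) * (c + d) * (a + c) * (b + d)
    if margins == 0:
        raise ValueError("chi-square undefined with a zero margin")
    chi2 = n * (a * d - b * c) ** 2 / margins
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


def fisher_exact_2x2(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p: total hypergeometric probability of tables
    (at fixed margins) no more probable than the observed one."""
    _, p = sps.fisher_exact(table.array, alternative="two-sided")
    return float(min(p, 1.0))


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be nonnegative")
        if self.n < 2:
            raise ValueError("need n >= 2 per group")


def pooled_t_from_summary(g1: GroupSummary, g2: GroupSummary
                          ) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from printed summary statistics."""
    df = g1.n + g2.n - 2
    sp2 = ((g1.n - 1) * g1.sd ** 2 + (g2.n - 1) * g2.sd ** 2) / df
    if sp2 == 0.0:
        if g1.mean == g2.mean:
            return 0.0, df, 1.0
        return np.inf, df, 0.0
    se = np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
    t = (g1.mean - g2.mean) / se
    return float(t), df, float(2.0 * sps.t.sf(abs(t), df))


@dataclass(frozen=True)
class AncovaResult:
    ls_mean_change: dict
    difference: float     # treatment coefficient (treated - reference)
    se: float
    t: float
    df: int
    p: float


def _design_matrix(df: pd.DataFrame, factor: str, covariates: list[str]):
    """Treatment dummies (reference level dropped) plus covariate columns."""
    levels = sorted(df[factor].unique())
    ref = "placebo" if "placebo" in levels else levels[0]
    others = [l for l in levels if l != ref]
    cols = {"const": np.ones(len(df))}
    for lev in others:
        cols[f"{factor}[{lev}]"] = (df[factor] == lev).astype(float).to_numpy()
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or str(col.dtype) == "category":
            cats = sorted(col.unique())
            for cat in cats[1:]:
                cols[f"{cov}[{cat}]"] = (col == cat).astype(float).to_numpy()
        else:
            cols[cov] = col.to_numpy(float)
    X = pd.DataFrame(cols, index=df.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise SingularDesignError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]} "
            f"columns {list(X.columns)})")
    return X, ref, others


def ancova_change(df: pd.DataFrame, outcome: str = "change",
                  treatment: str = "treatment",
                  covariates: tuple[str, ...] = ("age", "sex"),
                  include_mmse: bool = False) -> AncovaResult:
    """OLS ANCOVA of a change score on treatment with baseline covariates.

    With a two-level treatment the reported difference is the treated-minus-
    reference coefficient; LS means are model predictions per arm at the
    covariate means.
    """
    covs = list(covariates) + (["mmse_baseline"] if include_mmse else [])
    X, ref, others = _design_matrix(df, treatment, covs)
    if len(df) <= X.shape[1]:
        raise ValueError("need more observations than coefficients")
    model = sm.OLS(df[outcome].to_numpy(float), X).fit()
    lev = others[-1] if others else ref
    name = f"{treatment}[{lev}]"
    coef = float(model.params[name]) if others else 0.0
    se = float(model.bse[name]) if others else float("nan")
    dfres = int(model.df_resid)
    scale = max(1.0, float(np.abs(df[outcome]).max()))
    if not others or se <= 1e-12 * scale:
        # degenerate (perfect or single-level) fit: no evidence of an effect
        coef = 0.0 if abs(coef) <= 1e-10 * scale else coef
        tval, p = 0.0, 1.0
    else:
        tval = coef / se
        p = float(2.0 * sps.t.sf(abs(tval), dfres))
    # LS means: prediction at covariate means for each arm
    base = X.mean(axis=0)
    ls = {}
    for level in [ref] + others:
        row = base.copy()
        for other in others:
            row[f"{treatment}[{other}]"] = 1.0 if other == level else 0.0
        ls[level] = float(np.dot(row.to_numpy(), model.params))
    return AncovaResult(ls, coef, se, float(tval), dfres, p)


def dose_response_ancova(df: pd.DataFrame, outcome: str = "r_app",
                         dose: str = "arm", baseline: str = "baseline_ab40"
                         ) -> pd.DataFrame:
    """Adjusted dose-level contrasts vs placebo for the production-rate
    estimates, controlling for the pre-treatment lumbar concentration."""
    if df[dose].nunique() < 2:
        raise ValueError("need >= 2 dose levels")
    X, ref, others = _design_matrix(df, dose, [baseline])
    model = sm.OLS(df[outcome].to_numpy(float), X).fit()
    rows = []
    for lev in others:
        name = f"{dose}[{lev}]"
        coef = float(model.params[name])
        se = float(model.bse[name])
        t = coef / se if se > 0 else 0.0
        rows.append({
            "arm": lev, "reference": ref, "adjusted_difference": coef,
            "se": se, "t": t, "df": int(model.df_resid),
            "p": float(2.0 * sps.t.sf(abs(t), model.df_resid)),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PowerSpec:
    n1: int
    n2: int
    alpha: float
    percent_change: float   # effect as % of the reference mean
    reference_mean: float
    reference_sd: float

    def __post_init__(self):
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")
        if self.percent_change < 0:
            raise ValueError("percent_change must be nonnegative")


def power_two_sample(spec: PowerSpec) -> float:
    """Power of the two-sided pooled t-test for a mean shift of
    ``percent_change`` % of the reference mean, via the noncentral t."""
    if not spec.reference_sd > 0:
        raise ValueError("reference sd must be positive")
    delta = spec.percent_change / 100.0 * spec.reference_mean / spec.reference_sd
    nc = delta * np.sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    df = spec.n1 + spec.n2 - 2
    tcrit = sps.t.ppf(1.0 - spec.alpha / 2.0, df)
    power = sps.nct.sf(tcrit, df, nc) + sps.nct.cdf(-tcrit, df, nc)
    return float(power)
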