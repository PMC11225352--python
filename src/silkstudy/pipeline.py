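"""End-to-end orchestration: from a study directory (or an in-memory
synthetic study) to the full set of report tables.

Outputs mirror the shapes a dose-finding SILK trial reports: a baseline
characteristics table with per-row tests, FSR by arm with one-way ANOVA,
per-subject and arm-level NCA summaries, biomarker change ANCOVA, grid-fit
production estimates and the dose-response model with the pre-treatment
lumbar concentration as covariate.  A JSON manifest with content hashes
makes reruns verifiable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fsr as fsr_mod
from . import nca as nca_mod
from . import stats as stats_mod
from .cohort import DOSING, SyntheticStudy, generate_cohort, CohortConfig
from .data_model import read_long_table, SampleSchedule
from .gridfit import (GridConfig, OptimizerSettings, prepare_fit_data,
                      fit_subject_grid, select_and_average, records_to_frame)
from .compartment import EnrichmentCurve


@dataclass
class PipelineConfig:
    input_dir: str | None = None        # None: generate the default cohort
    output_dir: str = "results/pipeline"
    seed: int = 0
    grid_preset: str = "test"           # 'default' (128) or 'test' (8)
    fsr_modes: tuple[str, ...] = ("fixed", "auto")
    run_grid_fit: bool = True
    optimizer: OptimizerSettings = field(
        default_factory=lambda: OptimizerSettings(maxiter=150, n_restarts=1,
                                                  xatol=1e-3))


class StageError(RuntimeError):
    pass


def load_study(input_dir) -> SyntheticStudy:
    """Re-read a written study directory into the in-memory form."""
    d = Path(input_dir)
    subjects = read_long_table(d / "subjects.csv", "subjects")
    silk = read_long_table(d / "silk.csv", "silk")
    conc = read_long_table(d / "concentrations.csv", "concentration")
    truth = (pd.read_csv(d / "truth.csv")
             if (d / "truth.csv").exists() else pd.DataFrame())
    biomarkers = (pd.read_csv(d / "biomarkers.csv")
                  if (d / "biomarkers.csv").exists() else pd.DataFrame())
    enrichment = {}
    for s in conc:
        if s.analyte == "leucine_enrichment" and s.matrix == "plasma":
            enrichment[s.subject_id] = EnrichmentCurve(
                s.observed_times, s.observed_values)
    return SyntheticStudy(config=None, schedule=SampleSchedule.default(),
                          subjects=subjects, silk=silk, concentrations=conc,
                          enrichment=enrichment, truth=truth,
                          biomarkers=biomarkers, log={})


def make_table1(subjects) -> pd.DataFrame:
    """Baseline characteristics, placebo vs pooled active, with the tests a
    small-trial baseline table uses (pooled t; chi-square and Fisher)."""
    arms = {s.arm for s in subjects}
    if len(arms) < 2:
        raise StageError("baseline table needs at least two arms")
    placebo = [s for s in subjects if s.arm == "placebo"]
    active = [s for s in subjects if s.arm != "placebo"]
    rows = []

    def cont_row(name, attr):
        x = np.array([getattr(s, attr) for s in placebo], float)
        y = np.array([getattr(s, attr) for s in active], float)
        g1 = stats_mod.GroupSummary(x.mean(), x.std(ddof=1), len(x))
        g2 = stats_mod.GroupSummary(y.mean(), y.std(ddof=1), len(y))
        t, df, p = stats_mod.pooled_t_from_summary(g1, g2)
        rows.append({"characteristic": name, "kind": "continuous",
                     "placebo": f"{g1.mean:.1f} ± {g1.sd:.1f}",
                     "active": f"{g2.mean:.1f} ± {g2.sd:.1f}",
                     "test": "pooled t", "statistic": t, "p": p})

    def binary_row(name, attr):
        a = sum(getattr(s, attr) for s in placebo)
        c = sum(getattr(s, attr) for s in active)
        tbl = stats_mod.ContingencyTable2x2(a, len(placebo) - a,
                                            c, len(active) - c)
        p_f = stats_mod.fisher_exact_2x2(tbl)
        try:
            chi2, p_c = stats_mod.pearson_chi2_2x2(tbl)
        except ValueError:
            chi2, p_c = np.nan, np.nan
        rows.append({"characteristic": name, "kind": "binary",
                     "placebo": f"{a} ({100 * a / len(placebo):.0f}%)",
                     "active": f"{c} ({100 * c / len(active):.0f}%)",
                     "test": "chi2/Fisher", "statistic": chi2, "p": p_c,
                     "p_fisher": p_f})

    cont_row("Age, years", "age")
    n_f_pl = sum(s.sex == "female" for s in placebo)
    n_f_ac = sum(s.sex == "female" for s in active)
    tbl = stats_mod.ContingencyTable2x2(n_f_pl, len(placebo) - n_f_pl,
                                        n_f_ac, len(active) - n_f_ac)
    rows.append({"characteristic": "Sex (female:male)", "kind": "binary",
                 "placebo": f"{n_f_pl} : {len(placebo) - n_f_pl}",
                 "active": f"{n_f_ac} : {len(active) - n_f_ac}",
                 "test": "Fisher", "statistic": np.nan,
                 "p": stats_mod.fisher_exact_2x2(tbl)})
    cont_row("Education, years", "education")
    cont_row("MMSE", "mmse_baseline")
    binary_row("AChE-I", "on_achei")
    binary_row("Memantine", "on_memantine")
    binary_row("Antidepressants", "on_antidepressant")
    return pd.DataFrame(rows)


def fsr_table(study: SyntheticStudy, modes=("fixed", "auto")) -> pd.DataFrame:
    """Per-subject, per-isoform FSR under the requested window modes."""
    arm_of = {s.subject_id: s.arm for s in study.subjects}
    leucine = {c.subject_id: c for c in study.concentrations
               if c.analyte == "leucine_enrichment" and c.matrix == "plasma"}
    rows = []
    for silk in study.silk:
        sid = silk.subject_id
        if sid not in leucine:
            continue
        plateau = fsr_mod.plateau_enrichment(leucine[sid])
        for mode in modes:
            try:
                if mode == "fixed":
                    res = fsr_mod.fsr_fixed_window(silk, plateau)
                else:
                    res = fsr_mod.fsr_auto_window(silk, plateau)
            except (fsr_mod.InsufficientDataError,
                    fsr_mod.DetectionError):
                continue
            rows.append({"subject_id": sid, "arm": arm_of.get(sid, ""),
                         "isoform": silk.isoform, "mode": mode,
                         "window_lo": res.window[0],
                         "window_hi": res.window[1], "slope": res.slope,
                         "plateau": res.normalization, "fsr": res.fsr,
                         "r_squared": res.r_squared,
                         "n_points": res.n_points})
    return pd.DataFrame(rows)


def nca_tables(study: SyntheticStudy):
    """Per-subject NCA for drug analytes plus arm-level geometric summaries."""
    arm_of = {s.subject_id: s.arm for s in study.subjects}
    per_subject = []
    for series in study.concentrations:
        if series.analyte not in ("Posiphen", "N1", "N8"):
            continue
        arm = arm_of.get(series.subject_id, "")
        if arm == "placebo" or not np.any(series.observed_values > 0):
            continue
        dose = DOSING[arm][0] if series.analyte == "Posiphen" else None
        try:
            res = nca_mod.nca_subject(series, dose_mg=dose)
        except nca_mod.InsufficientDataError:
            continue
        row = res.__dict__ | {"arm": arm}
        per_subject.append(row)
    per_subject = pd.DataFrame(per_subject)
    summaries = []
    if len(per_subject):
        for (arm, analyte, matrix), g in per_subject.groupby(
                ["arm", "analyte", "matrix"]):
            for param in ("auc_0_24", "cmax"):
                vals = g[param].dropna()
                vals = vals[vals > 0]
                if len(vals) == 0:
                    continue
                s = nca_mod.geo_summary(vals)
                summaries.append({
                    "arm": arm, "analyte": analyte, "matrix": matrix,
                    "parameter": param, "n": s.n,
                    "geometric_mean": s.geometric_mean,
                    "percent_gcv": s.percent_gcv})
            tmax = g["tmax"].dropna()
            if len(tmax):
                summaries.append({
                    "arm": arm, "analyte": analyte, "matrix": matrix,
                    "parameter": "tmax", "n": len(tmax),
                    "median": float(tmax.median()),
                    "minimum": float(tmax.min()),
                    "maximum": float(tmax.max())})
    return per_subject, pd.DataFrame(summaries)


def biomarker_change_table(study: SyntheticStudy) -> pd.DataFrame:
    """Per-analyte change-score ANCOVA (active vs placebo, age+sex adjusted)."""
    if study.biomarkers is None or not len(study.biomarkers):
        return pd.DataFrame()
    covs = pd.DataFrame([{"subject_id": s.subject_id, "age": s.age,
                          "sex": s.sex} for s in study.subjects])
    rows = []
    for analyte, g in study.biomarkers.groupby("analyte"):
        df = g.merge(covs, on="subject_id")
        df["treatment"] = np.where(df["arm"] == "placebo", "placebo",
                                   "posiphen")
        res = stats_mod.ancova_change(df, outcome="change")
        rows.append({"analyte": analyte,
                     "ls_mean_change_placebo": res.ls_mean_change["placebo"],
                     "ls_mean_change_posiphen": res.ls_mean_change["posiphen"],
                     "difference": res.difference, "se": res.se,
                     "t": res.t, "df": res.df, "p": res.p})
    return pd.DataFrame(rows)


def grid_fit_tables(study: SyntheticStudy, grid: GridConfig,
                    optimizer: OptimizerSettings):
    """Per-subject grid-fit summaries and the dose-response ANCOVA."""
    arm_of = {s.subject_id: s.arm for s in study.subjects}
    age_of = {s.subject_id: s.age for s in study.subjects}
    lumbar = {c.subject_id: c for c in study.concentrations
              if c.analyte == "Ab40" and c.matrix == "CSF"}
    rows, records_all = [], []
    for silk in study.silk:
        if silk.isoform != "Ab40":
            continue
        sid = silk.subject_id
        if sid not in lumbar or sid not in study.enrichment:
            continue
        data = prepare_fit_data(silk, lumbar[sid], study.enrichment[sid],
                                study.schedule, grid, age_of[sid])
        records = fit_subject_grid(data, grid, optimizer)
        summ = select_and_average(records, grid, sid)
        baseline = lumbar[sid].observed_values[0] \
            if len(lumbar[sid].observed_values) else np.nan
        rows.append({"subject_id": sid, "arm": arm_of.get(sid, ""),
                     "r_app": summ.r_app, "n_kept": summ.n_kept,
                     "best_ssr_silk": summ.best_ssr_silk,
                     "best_ssr_conc": summ.best_ssr_conc,
                     "fallback_used": summ.fallback_used,
                     "baseline_ab40": baseline})
        df_rec = records_to_frame(records)
        df_rec.insert(0, "subject_id", sid)
        records_all.append(df_rec)
    summaries = pd.DataFrame(rows)
    dose_resp = pd.DataFrame()
    if len(summaries) and summaries["arm"].nunique() >= 2:
        dose_resp = stats_mod.dose_response_ancova(
            summaries.rename(columns={"baseline_ab40": "baseline"}),
            outcome="r_app", dose="arm", baseline="baseline")
    records_df = (pd.concat(records_all, ignore_index=True)
                  if records_all else pd.DataFrame())
    return summaries, records_df, dose_resp


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_end_to_end(config: PipelineConfig) -> dict:
    """Run every stage and write the report bundle; returns the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    errors = {}
    if config.input_dir is None:
        study = generate_cohort(CohortConfig(seed=config.seed))
    else:
        study = load_study(config.input_dir)

    grid = (GridConfig() if config.grid_preset == "default"
            else GridConfig.test_preset())

    artifacts = {}

    def stage(name, fn):
        try:
            result = fn()
        except Exception as exc:   # retain partial outputs, record failure
            errors[name] = f"{type(exc).__name__}: {exc}"
            return None
        return result

    t1 = stage("table1", lambda: make_table1(study.subjects))
    if t1 is not None:
        t1.to_csv(out / "table1.csv", index=False)
        artifacts["table1"] = "table1.csv"

    fsr_df = stage("fsr", lambda: fsr_table(study, config.fsr_modes))
    if fsr_df is not None and len(fsr_df):
        fsr_df.to_csv(out / "fsr.csv", index=False)
        artifacts["fsr"] = "fsr.csv"
        ab40 = fsr_df[(fsr_df["isoform"] == "Ab40")
                      & (fsr_df["mode"] == "fixed")]
        anova = stage("fsr_anova",
                      lambda: fsr_mod.compare_fsr_groups(ab40))
        if anova is not None:
            (out / "fsr_anova.json").write_text(json.dumps(
                anova.__dict__, indent=2))
            artifacts["fsr_anova"] = "fsr_anova.json"

    nca_res = stage("nca", lambda: nca_tables(study))
    if nca_res is not None:
        per_subject, summaries = nca_res
        per_subject.to_csv(out / "nca_subjects.csv", index=False)
        summaries.to_csv(out / "nca_summary.csv", index=False)
        artifacts["nca_subjects"] = "nca_subjects.csv"
        artifacts["nca_summary"] = "nca_summary.csv"

    bio = stage("biomarker_change", lambda: biomarker_change_table(study))
    if bio is not None and len(bio):
        bio.to_csv(out / "biomarker_change.csv", index=False)
        artifacts["biomarker_change"] = "biomarker_change.csv"

    if config.run_grid_fit:
        gf = stage("grid_fit", lambda: grid_fit_tables(
            study, grid, config.optimizer))
        if gf is not None:
            summaries, records_df, dose_resp = gf
            summaries.to_csv(out / "subject_fits.csv", index=False)
            records_df.to_csv(out / "fit_records.csv", index=False)
            dose_resp.to_csv(out / "dose_response.csv", index=False)
            artifacts["subject_fits"] = "subject_fits.csv"
            artifacts["fit_records"] = "fit_records.csv"
            artifacts["dose_response"] = "dose_response.csv"

    manifest = {
        "seed": config.seed,
        "grid_preset": config.grid_preset,
        "artifacts": {k: {"file": v, "sha256": _sha256(out / v)}
                      for k, v in artifacts.items()},
        "errors": errors,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True))
    if errors:
        raise StageError(f"stage failures: {errors}")
    return manifest
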