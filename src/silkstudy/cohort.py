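"""Synthetic SILK dose-finding study generator.

Generates a full trial — eligible subjects, permuted-block 5:3 randomization
into sequential dose cohorts, primed leucine-infusion enrichment curves, SILK
and lumbar-concentration time courses from the transport model, multi-dose
drug PK, biomarker change scores, proportional measurement noise and missing
CSF draws — so every pipeline stage runs without external data.  A truth
table (per-subject kinetic parameters and production rates) is retained for
parameter-recovery experiments.

Defaults encode the study conditions: 3 cohorts of 8 (5 active : 3 placebo)
sampled 19 times over 36 h with 6 mL draws, ~18.25% missing CSF samples,
7.5% proportional SILK noise, eligibility at Abeta42/40 < 0.131, and
fractional production reductions of 0/10/20/30% across placebo/QD/BID/TID.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .compartment import (EnrichmentCurve, KineticParameters, simulate)
from .data_model import (ConcentrationSeries, SampleSchedule, SilkSeries,
                         SubjectRecord, write_long_table)


@dataclass(frozen=True)
class InfusionSpec:
    bolus_mg_per_kg: float = 3.0
    rate_mg_per_kg_h: float = 2.0
    duration_h: float = 9.0
    plateau_enrichment: float = 0.12
    k_leucine_per_h: float = 0.6667


@dataclass(frozen=True)
class DrugPk:
    """One-compartment first-order-absorption profile parameters."""
    ka: float          # 1/h
    ke: float          # 1/h
    cl_f: float        # L/h
    formation_fraction: float = 1.0   # of the administered parent dose
    csf_ratio: float = 0.1            # CSF:plasma concentration ratio


DEFAULT_DRUG_PK = {
    # parent t1/2 ~ 3.5 h, Cl/F sized so QD 60 mg gives a 24-h mean plasma
    # concentration of order 10 ng/mL
    "Posiphen": DrugPk(ka=1.0, ke=0.198, cl_f=280.0, formation_fraction=1.0,
                       csf_ratio=0.12),
    "N1": DrugPk(ka=1.0, ke=0.150, cl_f=450.0, formation_fraction=0.35,
                 csf_ratio=0.10),
    "N8": DrugPk(ka=1.0, ke=0.250, cl_f=600.0, formation_fraction=0.25,
                 csf_ratio=0.10),
}

# per-administration dose (mg) and dosing interval (h) by arm
DOSING = {"QD60": (60.0, 24.0), "BID120": (60.0, 12.0), "TID180": (60.0, 8.0)}

BIOMARKER_BASELINES = {   # typical CSF immunoassay levels, pg/mL
    "Ab38": 2500.0, "Ab40": 6000.0, "Ab42": 600.0,
    "sAPPa": 250000.0, "sAPPb": 200000.0, "tTau": 400.0,
}


@dataclass
class CohortConfig:
    seed: int = 0
    cohort_arms: tuple[str, ...] = ("QD60", "BID120", "TID180")
    block_size: int = 8
    n_active_per_block: int = 5
    n_blocks_per_cohort: int = 1
    sites: tuple[str, ...] = ("S1",)
    # subject-level truth
    r_app_median: float = 1.0        # nmol/h
    r_app_cv: float = 0.20
    k_bpd40_median: float = 0.08     # 1/h
    k_bpd40_cv: float = 0.15
    q_csf_mean: float = 20.0         # mL/h
    q_csf_cv: float = 0.10
    q_osc_median: float = 30.0       # mL/h
    q_osc_cv: float = 0.20
    v_sp_choices: tuple[float, ...] = (40.0, 60.0, 80.0, 100.0)
    q_leak_choices: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0)
    f_vcsf_true_cv: float = 0.08   # error of the age-volume regression
    sf40_true: float = 1.0
    dose_effects: dict = field(default_factory=lambda: {
        "placebo": 0.0, "QD60": 0.10, "BID120": 0.20, "TID180": 0.30})
    # measurement model
    silk_noise_cv: float = 0.075
    conc_noise_cv: float = 0.10
    missingness: float = 0.1825
    eligibility_threshold: float = 0.131
    start_clock_choices: tuple[int, ...] = (540, 570, 600, 630, 660)
    infusion: InfusionSpec = field(default_factory=InfusionSpec)
    drug_pk: dict = field(default_factory=lambda: dict(DEFAULT_DRUG_PK))
    treatment_days: int = 21
    fine_step: float = 0.25

    def validate(self) -> None:
        for p in (self.silk_noise_cv, self.conc_noise_cv):
            if p < 0:
                raise ValueError("noise CVs must be nonnegative")
        if not (0 <= self.missingness <= 1):
            raise ValueError("missingness must lie in [0, 1]")
        if self.block_size % (self.n_active_per_block +
                              (self.block_size - self.n_active_per_block)) != 0:
            raise ValueError("block size incompatible with allocation ratio")

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "infusion" in raw:
            raw["infusion"] = InfusionSpec(**raw["infusion"])
        if "drug_pk" in raw:
            raw["drug_pk"] = {k: DrugPk(**v) for k, v in raw["drug_pk"].items()}
        for key in ("cohort_arms", "sites", "v_sp_choices",
                    "start_clock_choices"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class SyntheticStudy:
    config: CohortConfig
    schedule: SampleSchedule
    subjects: list
    silk: list
    concentrations: list
    enrichment: dict
    truth: pd.DataFrame
    biomarkers: pd.DataFrame
    log: dict

    def write(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_long_table(self.subjects, out / "subjects.csv", "subjects")
        write_long_table(self.silk, out / "silk.csv", "silk")
        write_long_table(self.concentrations, out / "concentrations.csv",
                         "concentration")
        self.truth.to_csv(out / "truth.csv", index=False)
        self.biomarkers.to_csv(out / "biomarkers.csv", index=False)
        with open(out / "generation_log.yaml", "w") as fh:
            yaml.safe_dump(self.log, fh)


def randomize_blocks(subjects, config: CohortConfig, rng: np.random.Generator
                     ) -> dict[str, str]:
    """Permuted-block 5:3 active:placebo assignment stratified by site.

    Returns subject_id -> {'active', 'placebo'}.  Incomplete trailing blocks
    take the leading entries of a fresh permuted block.
    """
    n_pl = config.block_size - config.n_active_per_block
    assignment: dict[str, str] = {}
    by_site: dict[str, list] = {}
    for s in subjects:
        by_site.setdefault(s.site_id, []).append(s)
    for site in sorted(by_site):
        stratum = by_site[site]
        if not stratum:
            continue
        i = 0
        while i < len(stratum):
            block = ["active"] * config.n_active_per_block + ["placebo"] * n_pl
            perm = rng.permutation(len(block))
            labels = [block[j] for j in perm]
            for subj, lab in zip(stratum[i:i + config.block_size], labels):
                assignment[subj.subject_id] = lab
            i += config.block_size
    return assignment


def simulate_leucine_enrichment(infusion: InfusionSpec, weight_kg: float = 70.0,
                                grid_step: float = 0.05,
                                horizon_h: float = 40.0) -> EnrichmentCurve:
    """Plasma leucine enrichment for a primed (bolus + constant) infusion.

    The plasma leucine pool turns over at ``k_leucine_per_h``; enrichment
    rises as e_ss*(1 - (1-r) e^{-kt}) during the infusion, where
    r = bolus*k/rate is the priming ratio (r = 1 primes exactly), and decays
    mono-exponentially after the pump stops.  Dosing is per kg, so the curve
    is weight-invariant; ``weight_kg`` is kept for interface completeness.
    """
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    k = infusion.k_leucine_per_h
    ess = infusion.plateau_enrichment
    r = infusion.bolus_mg_per_kg * k / infusion.rate_mg_per_kg_h
    t = np.arange(0.0, horizon_h + grid_step / 2, grid_step)
    dur = infusion.duration_h
    on = ess * (1.0 - (1.0 - r) * np.exp(-k * t))
    e_end = ess * (1.0 - (1.0 - r) * np.exp(-k * dur))
    off = e_end * np.exp(-k * (t - dur))
    e = np.clip(np.where(t <= dur, on, off), 0.0, 1.0)
    return EnrichmentCurve(t, e)


def _lognormal_factor(rng, cv: float, size) -> np.ndarray:
    """Multiplicative noise with unit mean and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size))


def _multidose_profile(times, dose_mg: float, interval_h: float, pk: DrugPk,
                       n_days: int) -> np.ndarray:
    """Superposed one-compartment oral profiles; last dose at t = 0."""
    v = pk.cl_f / pk.ke                       # L
    amt = pk.formation_fraction * dose_mg * 1e6   # ng
    if abs(pk.ka - pk.ke) < 1e-9:
        raise ValueError("ka must differ from ke")
    coef = amt * pk.ka / (v * 1000.0 * (pk.ka - pk.ke))   # ng/mL
    n_doses = int(n_days * 24 / interval_h) + 1
    dose_times = -interval_h * np.arange(n_doses)         # 0, -tau, -2tau, ...
    t = np.asarray(times, float)[:, None] - dose_times[None, :]
    with np.errstate(over="ignore"):
        prof = np.where(t >= 0,
                        np.exp(-pk.ke * np.clip(t, 0, None)) -
                        np.exp(-pk.ka * np.clip(t, 0, None)), 0.0)
    return coef * prof.sum(axis=1)


def simulate_subject(subject: SubjectRecord, arm: str, config: CohortConfig,
                     rng: np.random.Generator, schedule: SampleSchedule):
    """Generate every measured series for one randomized subject.

    Returns (silk list, concentration list, enrichment curve, truth row).
    """
    eff = config.dose_effects[arm]
    base_r = config.r_app_median * _lognormal_factor(rng, config.r_app_cv, ())
    true_r = float(base_r * (1.0 - eff))
    k_bpd = float(np.clip(
        config.k_bpd40_median * _lognormal_factor(rng, config.k_bpd40_cv, ()),
        0.055, 0.34))
    q_csf = float(max(5.0, rng.normal(config.q_csf_mean,
                                      config.q_csf_cv * config.q_csf_mean)))
    q_osc = float(config.q_osc_median * _lognormal_factor(rng, config.q_osc_cv, ()))
    v_sp = float(rng.choice(np.asarray(config.v_sp_choices)))
    q_leak = float(rng.choice(np.asarray(config.q_leak_choices)))
    f_vcsf = float(_lognormal_factor(rng, config.f_vcsf_true_cv, ()))

    params = KineticParameters.default(
        age=subject.age, r_app=true_r, k_bpd40=k_bpd, q_csf=q_csf,
        q_osc=q_osc, v_sp=v_sp, q_leak=q_leak, f_vcsf=f_vcsf,
        sf40=config.sf40_true)
    enr = simulate_leucine_enrichment(config.infusion)
    out = simulate(params, enr, schedule, fine_step=config.fine_step)

    n_t = len(schedule.times)
    start_clock = int(rng.choice(np.asarray(config.start_clock_choices)))
    clock = (start_clock + 60.0 * schedule.times) % 1440.0
    missing_draw = rng.random(n_t) < config.missingness

    def noisy_frac(frac):
        y = frac * _lognormal_factor(rng, config.silk_noise_cv, n_t)
        return np.clip(y, 0.0, 1.0)

    silk = []
    for isoform, scale in (("Ab38", 1.0), ("Ab40", 1.0), ("Ab42", 0.9)):
        silk.append(SilkSeries(subject.subject_id, isoform,
                               schedule.times.copy(),
                               noisy_frac(scale * out.labeled_fraction_lumbar),
                               missing_draw.copy()))

    conc = []
    lumbar = out.measured_lumbar_pg * _lognormal_factor(
        rng, config.conc_noise_cv, n_t)
    conc.append(ConcentrationSeries(
        subject.subject_id, "Ab40", "CSF", schedule.times.copy(), lumbar,
        missing_draw.copy(), clock_minutes=clock.copy()))
    conc.append(ConcentrationSeries(
        subject.subject_id, "leucine_enrichment", "plasma",
        schedule.times.copy(), np.clip(enr(schedule.times), 0, 1),
        np.zeros(n_t, bool), clock_minutes=clock.copy()))

    for analyte, pk in config.drug_pk.items():
        if arm == "placebo":
            plasma = np.zeros(n_t)
            csf = np.zeros(n_t)
        else:
            dose_mg, interval = DOSING[arm]
            prof = _multidose_profile(schedule.times, dose_mg, interval, pk,
                                      config.treatment_days)
            plasma = prof * _lognormal_factor(rng, config.conc_noise_cv, n_t)
            csf = (prof * pk.csf_ratio *
                   _lognormal_factor(rng, config.conc_noise_cv, n_t))
        conc.append(ConcentrationSeries(
            subject.subject_id, analyte, "plasma", schedule.times.copy(),
            plasma, np.zeros(n_t, bool), clock_minutes=clock.copy()))
        conc.append(ConcentrationSeries(
            subject.subject_id, analyte, "CSF", schedule.times.copy(),
            csf, missing_draw.copy(), clock_minutes=clock.copy()))

    truth = {
        "subject_id": subject.subject_id, "arm": arm,
        "base_r_app": float(base_r), "dose_effect": eff, "true_r_app": true_r,
        "k_bpd40": k_bpd, "q_csf": q_csf, "q_osc": q_osc, "v_sp": v_sp,
        "q_leak": q_leak, "f_vcsf": f_vcsf,
        "sf40": config.sf40_true, "start_clock_min": start_clock,
        "baseline_lumbar_ab40_pg": float(out.measured_lumbar_pg[0]),
    }
    return silk, conc, enr, truth


def _draw_subject(rng, subject_id: str, site_id: str, threshold: float):
    """Sample screening candidates until one is amyloid-eligible."""
    screened = 0
    while True:
        screened += 1
        ratio = float(rng.normal(0.112, 0.018))
        if 0 < ratio < threshold:
            break
    age = float(np.clip(np.round(rng.normal(72.0, 8.0)), 55, 89))
    mmse = int(np.clip(np.round(rng.normal(24.5, 3.0)), 17, 30))
    rec = SubjectRecord(
        subject_id=subject_id, site_id=site_id, age=age,
        sex="female" if rng.random() < 0.5 else "male",
        education=float(np.clip(np.round(rng.normal(15.0, 3.0)), 8, 22)),
        mmse_baseline=mmse, arm="placebo",  # arm filled after randomization
        on_achei=bool(rng.random() < 0.5),
        on_memantine=bool(rng.random() < 0.25),
        on_antidepressant=bool(rng.random() < 0.55),
        csf_ab42_40=ratio,
    )
    return rec, screened


def _biomarker_changes(subjects, config, rng) -> pd.DataFrame:
    """Screening vs catheter-placement biomarker levels (Table-5-style)."""
    rows = []
    for s in subjects:
        active = s.arm != "placebo"
        for analyte, base in BIOMARKER_BASELINES.items():
            level = base * _lognormal_factor(rng, 0.25, ())
            drift = 0.05 if analyte in ("Ab38", "Ab40", "Ab42") else 0.0
            shift = 0.0
            if active:
                # small translational-inhibition signature: Abeta down, sAPP up
                shift = -0.06 if analyte.startswith("Ab") else 0.03
            follow = level * (1 + drift + shift) * _lognormal_factor(rng, 0.05, ())
            rows.append({"subject_id": s.subject_id, "arm": s.arm,
                         "analyte": analyte, "screening": float(level),
                         "confinement": float(follow),
                         "change": float(follow - level)})
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticStudy:
    """Generate the full synthetic study (default: 24 randomized subjects in
    three sequential 8-subject dose cohorts)."""
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    schedule = SampleSchedule.default()

    subjects, silk_all, conc_all = [], [], []
    enrichment, truth_rows = {}, []
    n_screened = 0
    sid = 0
    per_cohort = config.block_size * config.n_blocks_per_cohort
    for cohort_idx, active_arm in enumerate(config.cohort_arms):
        cohort_subjects = []
        for _ in range(per_cohort):
            sid += 1
            site = config.sites[(sid - 1) % len(config.sites)]
            rec, screened = _draw_subject(
                rng, f"SUBJ{sid:03d}", site, config.eligibility_threshold)
            n_screened += screened
            cohort_subjects.append(rec)
        assignment = randomize_blocks(cohort_subjects, config, rng)
        for rec in cohort_subjects:
            arm = active_arm if assignment[rec.subject_id] == "active" \
                else "placebo"
            rec = dataclasses.replace(rec, arm=arm)
            subjects.append(rec)
            silk, conc, enr, truth = simulate_subject(
                rec, arm, config, rng, schedule)
            silk_all.extend(silk)
            conc_all.extend(conc)
            enrichment[rec.subject_id] = enr
            truth_rows.append(truth)

    truth = pd.DataFrame(truth_rows)
    biomarkers = _biomarker_changes(subjects, config, rng)
    counts = pd.Series([s.arm for s in subjects]).value_counts().to_dict()
    log = {"seed": int(config.seed), "n_screened": int(n_screened),
           "n_randomized": len(subjects),
           "arm_counts": {k: int(v) for k, v in counts.items()}}
    return SyntheticStudy(config, schedule, subjects, silk_all, conc_all,
                          enrichment, truth, biomarkers, log)
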