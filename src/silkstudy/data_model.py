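"""Domain types, validation and long-table CSV I/O for the SILK pipeline.

Every table is tidy (one row per sample) with a fixed documented header.
Missing samples are encoded explicitly (empty value + ``missing`` flag), never
by row omission, so schedule accounting stays testable.  Time is hours since
lumbar catheter placement; clock times are minutes since local midnight and
exist only to support the 11 am concentration filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .config import load_defaults

SEXES = ("female", "male")
ARMS = ("placebo", "QD60", "BID120", "TID180")
ISOFORMS = ("Ab38", "Ab40", "Ab42")
ANALYTES = (
    "Posiphen", "N1", "N8",
    "Ab38", "Ab40", "Ab42",
    "sAPPa", "sAPPb", "tTau",
    "leucine_enrichment",
)
MATRICES = ("plasma", "CSF")

SUBJECT_COLUMNS = [
    "subject_id", "site_id", "age", "sex", "education", "mmse_baseline",
    "arm", "on_achei", "on_memantine", "on_antidepressant", "csf_ab42_40",
]
SILK_COLUMNS = ["subject_id", "isoform", "time_h", "labeled_fraction", "missing"]
CONCENTRATION_COLUMNS = [
    "subject_id", "analyte", "matrix", "time_h", "value", "missing", "clock_min",
]


class SchemaError(ValueError):
    """Header of an input table does not match the documented column set."""


class ValidationError(ValueError):
    """A row or field violates a domain invariant; message names the row."""


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    site_id: str
    age: float
    sex: str
    education: float
    mmse_baseline: int
    arm: str
    on_achei: bool
    on_memantine: bool
    on_antidepressant: bool
    csf_ab42_40: float

    def validate(self) -> None:
        if not (55 <= self.age <= 89):
            raise ValidationError(
                f"subject {self.subject_id}: age {self.age} outside [55, 89]")
        if self.sex not in SEXES:
            raise ValidationError(f"subject {self.subject_id}: sex {self.sex!r}")
        if not (17 <= self.mmse_baseline <= 30):
            raise ValidationError(
                f"subject {self.subject_id}: MMSE {self.mmse_baseline} outside [17, 30]")
        if self.arm not in ARMS:
            raise ValidationError(f"subject {self.subject_id}: arm {self.arm!r}")
        if not self.csf_ab42_40 > 0:
            raise ValidationError(
                f"subject {self.subject_id}: Abeta42/40 ratio must be > 0")


@dataclass(frozen=True)
class SampleSchedule:
    """CSF sampling grid: draw times (h) and per-draw volume (mL)."""

    times: np.ndarray
    draw_volume: float = 6.0

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if self.times.ndim != 1 or len(self.times) == 0:
            raise ValidationError("schedule needs a non-empty 1-d time grid")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("schedule times must be strictly increasing")
        if not self.draw_volume > 0:
            raise ValidationError("draw volume must be positive")

    @classmethod
    def default(cls) -> "SampleSchedule":
        d = load_defaults()["schedule"]
        return cls(times=np.asarray(d["times_h"], float),
                   draw_volume=float(d["draw_volume_mL"]))


@dataclass
class SilkSeries:
    """Labeled mole fraction (tracer/(tracer+tracee)) of one CSF Abeta isoform."""

    subject_id: str
    isoform: str
    times: np.ndarray
    labeled_fraction: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.labeled_fraction = np.asarray(self.labeled_fraction, float)
        self.missing_mask = np.asarray(self.missing_mask, bool)

    def validate(self) -> None:
        if self.isoform not in ISOFORMS:
            raise ValidationError(
                f"{self.subject_id}: unknown isoform {self.isoform!r}")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"{self.subject_id}/{self.isoform}: times not strictly increasing")
        obs = self.labeled_fraction[~self.missing_mask]
        bad = np.where((obs < 0) | (obs > 1))[0]
        if bad.size:
            idx = np.where(~self.missing_mask)[0][bad[0]]
            raise ValidationError(
                f"{self.subject_id}/{self.isoform} sample {idx} "
                f"(t={self.times[idx]:g} h): labeled fraction "
                f"{self.labeled_fraction[idx]:g} outside [0, 1]")

    @property
    def observed_times(self) -> np.ndarray:
        return self.times[~self.missing_mask]

    @property
    def observed_values(self) -> np.ndarray:
        return self.labeled_fraction[~self.missing_mask]


@dataclass
class ConcentrationSeries:
    """One analyte's concentration time course in one matrix.

    Units: ng/mL for drug analytes (Posiphen, N1, N8), pg/mL for protein
    biomarkers, unitless mole fraction for ``leucine_enrichment``.
    """

    subject_id: str
    analyte: str
    matrix: str
    times: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray
    clock_minutes: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.values = np.asarray(self.values, float)
        self.missing_mask = np.asarray(self.missing_mask, bool)
        if self.clock_minutes is not None:
            self.clock_minutes = np.asarray(self.clock_minutes, float)

    def validate(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValidationError(
                f"{self.subject_id}: unknown analyte {self.analyte!r}")
        if self.matrix not in MATRICES:
            raise ValidationError(
                f"{self.subject_id}: unknown matrix {self.matrix!r}")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"{self.subject_id}/{self.analyte}/{self.matrix}: "
                "times not strictly increasing")
        obs = self.values[~self.missing_mask]
        if np.any(obs < 0):
            idx = np.where(~self.missing_mask)[0][np.where(obs < 0)[0][0]]
            raise ValidationError(
                f"{self.subject_id}/{self.analyte}/{self.matrix} sample {idx}: "
                f"negative concentration {self.values[idx]:g}")
        if self.analyte == "leucine_enrichment" and np.any((obs < 0) | (obs > 1)):
            raise ValidationError(
                f"{self.subject_id}: leucine enrichment outside [0, 1]")

    @property
    def observed_times(self) -> np.ndarray:
        return self.times[~self.missing_mask]

    @property
    def observed_values(self) -> np.ndarray:
        return self.values[~self.missing_mask]


@dataclass(frozen=True)
class ScheduleReport:
    n_expected: int
    n_present: int
    n_missing: int
    fraction_present: float


def validate_against_schedule(series, schedule: SampleSchedule) -> ScheduleReport:
    """Count expected / present / missing samples against a sampling grid."""
    expected = schedule.times
    present = 0
    if len(series.times):
        mask = getattr(series, "missing_mask")
        for t in expected:
            j = np.where(np.isclose(series.times, t))[0]
            if j.size and not mask[j[0]]:
                present += 1
    n_exp = len(expected)
    return ScheduleReport(
        n_expected=n_exp,
        n_present=present,
        n_missing=n_exp - present,
        fraction_present=present / n_exp if n_exp else 0.0,
    )


# ---------------------------------------------------------------------------
# long-table I/O
# ---------------------------------------------------------------------------

_COLUMNS = {
    "subjects": SUBJECT_COLUMNS,
    "silk": SILK_COLUMNS,
    "concentration": CONCENTRATION_COLUMNS,
}


def _check_header(df: pd.DataFrame, kind: str) -> None:
    want = _COLUMNS[kind]
    missing = [c for c in want if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing column(s) {missing}; "
                          f"expected header {want}")


def _as_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    return str(x).strip().lower() in ("1", "true", "yes")


def read_long_table(path, kind: str):
    """Read and validate one of the documented tidy CSV tables.

    kind='subjects'       -> list[SubjectRecord]
    kind='silk'           -> list[SilkSeries]      (one per subject x isoform)
    kind='concentration'  -> list[ConcentrationSeries]
    """
    if kind not in _COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(path)
    _check_header(df, kind)

    if kind == "subjects":
        records = []
        for i, row in df.iterrows():
            try:
                rec = SubjectRecord(
                    subject_id=str(row["subject_id"]),
                    site_id=str(row["site_id"]),
                    age=float(row["age"]),
                    sex=str(row["sex"]),
                    education=float(row["education"]),
                    mmse_baseline=int(row["mmse_baseline"]),
                    arm=str(row["arm"]),
                    on_achei=_as_bool(row["on_achei"]),
                    on_memantine=_as_bool(row["on_memantine"]),
                    on_antidepressant=_as_bool(row["on_antidepressant"]),
                    csf_ab42_40=float(row["csf_ab42_40"]),
                )
                rec.validate()
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"subjects row {i}: {exc}") from exc
            records.append(rec)
        return records

    if kind == "silk":
        out = []
        for (sid, iso), g in df.groupby(["subject_id", "isoform"], sort=True):
            g = g.sort_values("time_h")
            miss = g["missing"].map(_as_bool).to_numpy()
            frac = pd.to_numeric(g["labeled_fraction"], errors="coerce").to_numpy()
            frac = np.where(miss, np.nan, frac)
            if np.any(~miss & ~np.isfinite(frac)):
                bad = g.index[~miss & ~np.isfinite(frac)][0]
                raise ValidationError(
                    f"silk row {bad}: non-numeric labeled_fraction for a "
                    "non-missing sample")
            series = SilkSeries(str(sid), str(iso), g["time_h"].to_numpy(float),
                                frac, miss)
            try:
                series.validate()
            except ValidationError as exc:
                first = g.index[0]
                raise ValidationError(f"silk rows from {first}: {exc}") from exc
            out.append(series)
        return out

    out = []
    has_clock = df["clock_min"].notna().any()
    for (sid, an, mat), g in df.groupby(["subject_id", "analyte", "matrix"],
                                        sort=True):
        g = g.sort_values("time_h")
        miss = g["missing"].map(_as_bool).to_numpy()
        vals = pd.to_numeric(g["value"], errors="coerce").to_numpy()
        vals = np.where(miss, np.nan, vals)
        clock = g["clock_min"].to_numpy(float) if has_clock else None
        series = ConcentrationSeries(str(sid), str(an), str(mat),
                                     g["time_h"].to_numpy(float), vals, miss,
                                     clock_minutes=clock)
        try:
            series.validate()
        except ValidationError as exc:
            raise ValidationError(f"concentration rows from {g.index[0]}: {exc}") from exc
        out.append(series)
    return out


def to_frame(records: Sequence, kind: str) -> pd.DataFrame:
    """Canonical tidy DataFrame (fixed column and row order) for any kind."""
    if kind == "subjects":
        rows = [{c: getattr(r, c) for c in SUBJECT_COLUMNS} for r in records]
        df = pd.DataFrame(rows, columns=SUBJECT_COLUMNS)
        return df.sort_values("subject_id", kind="mergesort").reset_index(drop=True)
    if kind == "silk":
        frames = []
        for s in records:
            frames.append(pd.DataFrame({
                "subject_id": s.subject_id,
                "isoform": s.isoform,
                "time_h": s.times,
                "labeled_fraction": np.where(s.missing_mask, np.nan,
                                             s.labeled_fraction),
                "missing": s.missing_mask.astype(int),
            }))
        df = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=SILK_COLUMNS))
        return df.sort_values(["subject_id", "isoform", "time_h"],
                              kind="mergesort").reset_index(drop=True)
    if kind == "concentration":
        frames = []
        for s in records:
            clock = (s.clock_minutes if s.clock_minutes is not None
                     else np.full(len(s.times), np.nan))
            frames.append(pd.DataFrame({
                "subject_id": s.subject_id,
                "analyte": s.analyte,
                "matrix": s.matrix,
                "time_h": s.times,
                "value": np.where(s.missing_mask, np.nan, s.values),
                "missing": s.missing_mask.astype(int),
                "clock_min": clock,
            }))
        df = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=CONCENTRATION_COLUMNS))
        return df.sort_values(["subject_id", "analyte", "matrix", "time_h"],
                              kind="mergesort").reset_index(drop=True)
    raise ValueError(f"unknown table kind {kind!r}")


def write_long_table(records: Sequence, path, kind: str) -> None:
    """Write records as a canonical tidy CSV (deterministic row/column order)."""
    df = to_frame(records, kind)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")
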