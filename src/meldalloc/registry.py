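"""Waitlist registry domain model.

One row of the registry is a liver-transplant waitlist registration: labs at
listing (creatinine, bilirubin, INR, dialysis use), Child-Turcotte-Pugh score
and the clinical flags that drove the pre-2016 Korean urgency statuses, an HCC
flag with tumour stage, region, follow-up and removal reason.

This module houses:

* the record types (:class:`LabPanel`, :class:`StatusCriteria`,
  :class:`PatientRecord`, :class:`SurvivalSample`);
* the MELD computation with the KONOS conventions — lab values below 1.0 are
  floored at 1.0, creatinine is capped at 4.0 mg/dL (and forced to 4.0 for
  patients on dialysis, meaning two or more sessions in the last week or 24 h
  of continuous veno-venous hemodialysis), and the score is capped at 40;
* classification into the previous CTP-based urgency statuses (1 / 2A / 2B / 3);
* the composite waitlist outcome: removal for death or clinical deterioration
  counts as an event, transplant / improvement / still waiting are censored;
* CSV reading/writing with schema validation, and a cohort summary
  (status x MELD-band cross-tabulation plus covariate marginals).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .errors import InvalidInputError, SchemaError

__all__ = [
    "LabPanel",
    "MELDFormula",
    "DEFAULT_FORMULA",
    "StatusCriteria",
    "PatientRecord",
    "SurvivalSample",
    "MeldScore",
    "MELD_BANDS",
    "meld_band",
    "band_label",
    "effective_creatinine",
    "compute_meld",
    "labs_for_meld",
    "classify_status",
    "derive_outcome",
    "read_registry",
    "write_registry",
    "summarize_cohort",
    "CohortSummary",
    "REGISTRY_COLUMNS",
]

#: Inclusive MELD bands used throughout the analysis: <=20, 21-30, 31-37, 38-40.
MELD_BANDS: tuple[tuple[int, int], ...] = ((6, 20), (21, 30), (31, 37), (38, 40))

REMOVAL_REASONS = ("death", "deterioration", "transplant", "improvement", "still_waiting")
EVENT_REASONS = ("death", "deterioration")
ETIOLOGIES = ("HBV", "HCV", "alcoholic", "cholestatic", "other")
BLOOD_TYPES = ("A", "B", "AB", "O")
HCC_STAGES = ("T1", "T2", "T3", "T4")


def meld_band(score: int) -> tuple[int, int]:
    """Return the (lo, hi) analysis band containing an integer MELD score."""
    for lo, hi in MELD_BANDS:
        if lo <= score <= hi:
            return (lo, hi)
    raise InvalidInputError(f"MELD score {score} outside [6, 40]")


def band_label(band: tuple[int, int]) -> str:
    lo, hi = band
    return "<=20" if (lo, hi) == (6, 20) else f"{lo}-{hi}"


@dataclass(frozen=True)
class LabPanel:
    """Laboratory values at registration.

    creatinine, bilirubin in mg/dL; inr dimensionless; all strictly positive.
    ``dialysis_sessions_last_week`` counts hemodialysis sessions in the week
    before registration; ``cvvh_24h`` flags >=24 h of continuous veno-venous
    hemodialysis. Either condition triggers the creatinine override.
    """

    creatinine: float
    bilirubin: float
    inr: float
    dialysis_sessions_last_week: int = 0
    cvvh_24h: bool = False

    def __post_init__(self) -> None:
        for name in ("creatinine", "bilirubin", "inr"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise InvalidInputError(f"{name} must be a positive finite number, got {value!r}")
        if not (isinstance(self.dialysis_sessions_last_week, int) and self.dialysis_sessions_last_week >= 0):
            raise InvalidInputError(
                f"dialysis_sessions_last_week must be a non-negative integer, "
                f"got {self.dialysis_sessions_last_week!r}"
            )

    @property
    def on_dialysis(self) -> bool:
        return self.dialysis_sessions_last_week >= 2 or self.cvvh_24h


@dataclass(frozen=True)
class MELDFormula:
    """Coefficients and clamping rules of the MELD equation.

    score_raw = (0.957 ln cr + 0.378 ln bili + 1.12 ln INR + 0.643) * 10,
    with each lab floored at ``lab_floor``, creatinine additionally capped at
    ``creatinine_cap`` (and set to the cap under dialysis), and the integer
    score capped at ``score_cap``.
    """

    coef_creatinine: float = 0.957
    coef_bilirubin: float = 0.378
    coef_inr: float = 1.12
    intercept: float = 0.643
    scale: float = 10.0
    lab_floor: float = 1.0
    creatinine_cap: float = 4.0
    score_cap: int = 40

    def __post_init__(self) -> None:
        if not self.lab_floor < self.creatinine_cap:
            raise InvalidInputError("lab_floor must be below creatinine_cap")


DEFAULT_FORMULA = MELDFormula()


@dataclass(frozen=True)
class MeldScore:
    """Raw (real-valued) and integer MELD score."""

    raw: float
    score: int


@dataclass(frozen=True)
class StatusCriteria:
    """Inputs to the previous CTP-based urgency classification.

    Clinical judgments ("life expectancy < 7 days") are boolean inputs, not
    computed. ``hcc_stage_t1_t2`` records stage T1/T2 HCC, which was itself a
    status 2B criterion.
    """

    ctp_score: int
    icu_admitted: bool = False
    life_expectancy_lt_7d: bool = False
    variceal_bleeding: bool = False
    refractory_ascites_hydrothorax: bool = False
    hepatic_encephalopathy: bool = False
    hepatorenal_syndrome: bool = False
    spontaneous_bacterial_peritonitis: bool = False
    hcc_stage_t1_t2: bool = False
    fulminant_or_early_graft_failure: bool = False

    def __post_init__(self) -> None:
        if not (isinstance(self.ctp_score, int) and 5 <= self.ctp_score <= 15):
            raise InvalidInputError(f"ctp_score must be an integer in [5, 15], got {self.ctp_score!r}")


@dataclass(frozen=True)
class PatientRecord:
    """One waitlist registration."""

    id: str
    age_years: float
    sex: str  # "M" | "F"
    blood_type: str
    bmi: float
    etiology: str
    hcc: bool
    labs: LabPanel
    status_criteria: StatusCriteria
    region: int
    follow_up_days: float
    removal_reason: str
    hcc_stage: str | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise InvalidInputError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.blood_type not in BLOOD_TYPES:
            raise InvalidInputError(f"blood_type must be one of {BLOOD_TYPES}, got {self.blood_type!r}")
        if self.etiology not in ETIOLOGIES:
            raise InvalidInputError(f"etiology must be one of {ETIOLOGIES}, got {self.etiology!r}")
        if self.region not in (1, 2, 3):
            raise InvalidInputError(f"region must be 1, 2 or 3, got {self.region!r}")
        if not (math.isfinite(self.follow_up_days) and self.follow_up_days >= 0):
            raise InvalidInputError(f"follow_up_days must be >= 0, got {self.follow_up_days!r}")
        if self.removal_reason not in REMOVAL_REASONS:
            raise InvalidInputError(
                f"removal_reason must be one of {REMOVAL_REASONS}, got {self.removal_reason!r}"
            )
        if self.hcc_stage is not None and self.hcc_stage not in HCC_STAGES:
            raise InvalidInputError(f"hcc_stage must be one of {HCC_STAGES} or None, got {self.hcc_stage!r}")


@dataclass(frozen=True)
class SurvivalSample:
    """A (time, event) pair: event=True means death or deterioration dropout."""

    time_days: float
    event: bool

    def __post_init__(self) -> None:
        if not (math.isfinite(self.time_days) and self.time_days >= 0):
            raise InvalidInputError(f"time_days must be >= 0, got {self.time_days!r}")


# ---------------------------------------------------------------------------
# MELD computation
# ---------------------------------------------------------------------------

def effective_creatinine(labs: LabPanel, formula: MELDFormula = DEFAULT_FORMULA) -> float:
    """Creatinine entering the MELD equation, after dialysis override, cap and floor."""
    if labs.on_dialysis:
        cr = formula.creatinine_cap
    else:
        cr = min(labs.creatinine, formula.creatinine_cap)
    return max(cr, formula.lab_floor)


def compute_meld(labs: LabPanel, formula: MELDFormula = DEFAULT_FORMULA) -> MeldScore:
    """Raw and integer MELD score under the KONOS clamping conventions.

    The integer score is the raw score rounded half-up and capped at
    ``formula.score_cap``; with all labs at the floor the raw score is 6.43 and
    the integer score its minimum of 6.
    """
    cr = effective_creatinine(labs, formula)
    bili = max(labs.bilirubin, formula.lab_floor)
    inr = max(labs.inr, formula.lab_floor)
    raw = (
        formula.coef_creatinine * math.log(cr)
        + formula.coef_bilirubin * math.log(bili)
        + formula.coef_inr * math.log(inr)
        + formula.intercept
    ) * formula.scale
    score = math.floor(raw + 0.5)  # round half up
    score = min(score, formula.score_cap)
    score = max(score, 6)
    return MeldScore(raw=raw, score=score)


def labs_for_meld(score: int, formula: MELDFormula = DEFAULT_FORMULA) -> LabPanel:
    """A minimal lab panel whose integer MELD equals ``score``.

    Creatinine and bilirubin sit at the floor and INR carries the whole score;
    convenient for constructing cohorts with prescribed MELD values.
    """
    if not 6 <= score <= formula.score_cap:
        raise InvalidInputError(f"score must be in [6, {formula.score_cap}], got {score}")
    target_raw = max(float(score), formula.intercept * formula.scale)
    ln_inr = (target_raw / formula.scale - formula.intercept) / formula.coef_inr
    labs = LabPanel(creatinine=1.0, bilirubin=1.0, inr=max(1.0, math.exp(ln_inr)))
    assert compute_meld(labs, formula).score == score
    return labs


# ---------------------------------------------------------------------------
# Urgency status under the previous (CTP-based) system
# ---------------------------------------------------------------------------

def classify_status(criteria: StatusCriteria) -> str:
    """Urgency status under the pre-2016 Korean system: '1', '2A', '2B', '3' or 'unlisted'.

    Precedence is by urgency (1 > 2A > 2B > 3). Status 1 is fulminant hepatic
    failure / early graft failure. 2A requires CTP >= 10, ICU admission, life
    expectancy < 7 days and at least one acute complication; 2B is CTP >= 10,
    or CTP >= 7 with bleeding/ascites/SBP, or stage T1-T2 HCC; 3 is CTP >= 7.
    """
    c = criteria
    if c.fulminant_or_early_graft_failure:
        return "1"
    complication_2a = (
        c.variceal_bleeding
        or c.refractory_ascites_hydrothorax
        or c.hepatic_encephalopathy
        or c.hepatorenal_syndrome
    )
    if c.ctp_score >= 10 and c.icu_admitted and c.life_expectancy_lt_7d and complication_2a:
        return "2A"
    complication_2b = (
        c.variceal_bleeding or c.refractory_ascites_hydrothorax or c.spontaneous_bacterial_peritonitis
    )
    if c.ctp_score >= 10 or (c.ctp_score >= 7 and complication_2b) or c.hcc_stage_t1_t2:
        return "2B"
    if c.ctp_score >= 7:
        return "3"
    return "unlisted"


def derive_outcome(record: PatientRecord) -> SurvivalSample:
    """Composite waitlist outcome: death/deterioration = event, otherwise censored."""
    if record.removal_reason not in REMOVAL_REASONS:  # defensive; record validates too
        raise InvalidInputError(f"unknown removal reason {record.removal_reason!r}")
    return SurvivalSample(time_days=record.follow_up_days, event=record.removal_reason in EVENT_REASONS)


# ---------------------------------------------------------------------------
# CSV input / output
# ---------------------------------------------------------------------------

REGISTRY_COLUMNS = [
    "id", "age", "sex", "blood_type", "bmi", "etiology", "hcc", "hcc_stage",
    "creatinine", "bilirubin", "inr", "dialysis_sessions_last_week", "cvvh_24h",
    "ctp_score", "icu_admitted", "life_expectancy_lt_7d", "variceal_bleeding",
    "refractory_ascites", "encephalopathy", "hepatorenal", "sbp", "fulminant",
    "region", "follow_up_days", "removal_reason",
]

_TRUE = {"true", "1", "t", "yes"}
_FALSE = {"false", "0", "f", "no"}


def _parse_bool(raw: str, column: str) -> bool:
    token = raw.strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise InvalidInputError(f"column {column!r}: cannot parse boolean from {raw!r}")


def _record_from_row(row: dict[str, str]) -> PatientRecord:
    stage = row["hcc_stage"].strip() or None
    labs = LabPanel(
        creatinine=float(row["creatinine"]),
        bilirubin=float(row["bilirubin"]),
        inr=float(row["inr"]),
        dialysis_sessions_last_week=int(row["dialysis_sessions_last_week"]),
        cvvh_24h=_parse_bool(row["cvvh_24h"], "cvvh_24h"),
    )
    criteria = StatusCriteria(
        ctp_score=int(row["ctp_score"]),
        icu_admitted=_parse_bool(row["icu_admitted"], "icu_admitted"),
        life_expectancy_lt_7d=_parse_bool(row["life_expectancy_lt_7d"], "life_expectancy_lt_7d"),
        variceal_bleeding=_parse_bool(row["variceal_bleeding"], "variceal_bleeding"),
        refractory_ascites_hydrothorax=_parse_bool(row["refractory_ascites"], "refractory_ascites"),
        hepatic_encephalopathy=_parse_bool(row["encephalopathy"], "encephalopathy"),
        hepatorenal_syndrome=_parse_bool(row["hepatorenal"], "hepatorenal"),
        spontaneous_bacterial_peritonitis=_parse_bool(row["sbp"], "sbp"),
        hcc_stage_t1_t2=stage in ("T1", "T2"),
        fulminant_or_early_graft_failure=_parse_bool(row["fulminant"], "fulminant"),
    )
    return PatientRecord(
        id=row["id"],
        age_years=float(row["age"]),
        sex=row["sex"].strip(),
        blood_type=row["blood_type"].strip(),
        bmi=float(row["bmi"]),
        etiology=row["etiology"].strip(),
        hcc=_parse_bool(row["hcc"], "hcc"),
        labs=labs,
        status_criteria=criteria,
        region=int(row["region"]),
        follow_up_days=float(row["follow_up_days"]),
        removal_reason=row["removal_reason"].strip().lower(),
        hcc_stage=stage,
    )


def read_registry(path) -> list[PatientRecord]:
    """Read a registry CSV, validating the schema and every row.

    Raises :class:`SchemaError` when mandatory columns are missing and
    :class:`InvalidInputError` listing the offending line numbers (header =
    line 1) when rows violate domain invariants.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file with no header") from exc
    missing = [c for c in REGISTRY_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    records: list[PatientRecord] = []
    problems: list[str] = []
    for idx, row in enumerate(frame.to_dict(orient="records")):
        try:
            records.append(_record_from_row(row))
        except (InvalidInputError, ValueError) as exc:
            problems.append(f"line {idx + 2}: {exc}")
    if problems:
        raise InvalidInputError(f"{path}: {len(problems)} malformed row(s): " + "; ".join(problems))
    return records


def _bool_token(value: bool) -> str:
    return "true" if value else "false"


def _format_number(value: float) -> str:
    if float(value) == int(value):
        return str(int(value))
    return format(float(value), ".10g")


def records_to_dataframe(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        c = r.status_criteria
        stage = r.hcc_stage
        if stage is None and c.hcc_stage_t1_t2:
            stage = "T2"  # preserve the flag across a round trip when no stage was given
        rows.append({
            "id": r.id,
            "age": _format_number(r.age_years),
            "sex": r.sex,
            "blood_type": r.blood_type,
            "bmi": _format_number(r.bmi),
            "etiology": r.etiology,
            "hcc": _bool_token(r.hcc),
            "hcc_stage": stage or "",
            "creatinine": _format_number(r.labs.creatinine),
            "bilirubin": _format_number(r.labs.bilirubin),
            "inr": _format_number(r.labs.inr),
            "dialysis_sessions_last_week": str(r.labs.dialysis_sessions_last_week),
            "cvvh_24h": _bool_token(r.labs.cvvh_24h),
            "ctp_score": str(c.ctp_score),
            "icu_admitted": _bool_token(c.icu_admitted),
            "life_expectancy_lt_7d": _bool_token(c.life_expectancy_lt_7d),
            "variceal_bleeding": _bool_token(c.variceal_bleeding),
            "refractory_ascites": _bool_token(c.refractory_ascites_hydrothorax),
            "encephalopathy": _bool_token(c.hepatic_encephalopathy),
            "hepatorenal": _bool_token(c.hepatorenal_syndrome),
            "sbp": _bool_token(c.spontaneous_bacterial_peritonitis),
            "fulminant": _bool_token(c.fulminant_or_early_graft_failure),
            "region": str(r.region),
            "follow_up_days": _format_number(r.follow_up_days),
            "removal_reason": r.removal_reason,
        })
    return pd.DataFrame(rows, columns=REGISTRY_COLUMNS)


def write_registry(records: Iterable[PatientRecord], path) -> None:
    """Write records to the documented CSV schema (UTF-8, comma-separated)."""
    records_to_dataframe(records).to_csv(path, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Cohort summary
# ---------------------------------------------------------------------------

STATUS_ORDER = ("1", "2A", "2B", "3", "unlisted")


@dataclass
class CohortSummary:
    """Status x MELD-band cross-tabulation plus covariate marginals.

    ``status_band_counts`` has one row per status and one column per band;
    ``status_band_percent`` expresses each row as percentages of the row total.
    ``covariates`` maps a covariate name to its count table.
    """

    n: int
    status_band_counts: pd.DataFrame
    covariates: dict[str, pd.Series] = field(default_factory=dict)

    @property
    def status_band_percent(self) -> pd.DataFrame:
        totals = self.status_band_counts.sum(axis=1)
        percent = self.status_band_counts.div(totals.where(totals > 0, 1), axis=0) * 100.0
        return percent

    def covariate_percent(self, name: str) -> pd.Series:
        table = self.covariates[name]
        return table / max(table.sum(), 1) * 100.0

    def to_text(self) -> str:
        lines = [f"Cohort summary (n = {self.n})", "", "Status x MELD band counts:"]
        lines.append(self.status_band_counts.to_string())
        lines.append("")
        lines.append("Row percentages:")
        lines.append(self.status_band_percent.round(1).to_string())
        for name, table in self.covariates.items():
            lines.append("")
            lines.append(f"{name}:")
            pct = self.covariate_percent(name)
            merged = pd.DataFrame({"n": table, "%": pct.round(1)})
            lines.append(merged.to_string())
        return "\n".join(lines)


def summarize_cohort(records: Sequence[PatientRecord]) -> CohortSummary:
    """Cross-tabulate urgency status against MELD band and tally covariates."""
    band_labels = [band_label(b) for b in MELD_BANDS]
    counts = pd.DataFrame(0, index=list(STATUS_ORDER), columns=band_labels, dtype=int)
    sex = pd.Series(0, index=["M", "F"], dtype=int)
    etiology = pd.Series(0, index=list(ETIOLOGIES), dtype=int)
    blood = pd.Series(0, index=list(BLOOD_TYPES), dtype=int)
    ctp_class = pd.Series(0, index=["A", "B", "C"], dtype=int)
    hcc = pd.Series(0, index=["HCC", "non-HCC"], dtype=int)
    region = pd.Series(0, index=[1, 2, 3], dtype=int)
    for record in records:
        status = classify_status(record.status_criteria)
        score = compute_meld(record.labs).score
        counts.loc[status, band_label(meld_band(score))] += 1
        sex[record.sex] += 1
        etiology[record.etiology] += 1
        blood[record.blood_type] += 1
        ctp = record.status_criteria.ctp_score
        ctp_class["A" if ctp <= 6 else "B" if ctp <= 9 else "C"] += 1
        hcc["HCC" if record.hcc else "non-HCC"] += 1
        region[record.region] += 1
    covariates = {
        "sex": sex,
        "etiology": etiology,
        "blood_type": blood,
        "ctp_class": ctp_class,
        "hcc": hcc,
        "region": region,
    }
    return CohortSummary(n=len(records), status_band_counts=counts, covariates=covariates)
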