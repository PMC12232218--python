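"""Domain types, validation and file I/O for goal-concordant-care cohorts.

A cohort bundle holds three tables: patients (one row per admission),
goals-of-care (GOC) discussions (dated, each carrying one of four category
labels), and paired reviewer assessments of the care received during each
epoch of follow-up. Both goals and care received share the same four-level
taxonomy: comfort-focused, maintain-or-improve-function, life-extension,
or unclear.

All dates are ISO-8601 calendar dates (``YYYY-MM-DD``) at day granularity.
Optional fields serialize as empty strings in CSV and ``null`` in JSON.
"""

from __future__ import annotations

import datetime as dt
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "CategoryLabel",
    "GOCSource",
    "DiscussionSetting",
    "RiskStratum",
    "AdmittingService",
    "InterventionCode",
    "Patient",
    "GOCDiscussion",
    "CareAssessment",
    "CohortBundle",
    "ValidationError",
    "ReferentialIntegrityError",
    "load_cohort",
    "write_records",
    "patients_to_frame",
    "discussions_to_frame",
    "assessments_to_frame",
]


class ValidationError(ValueError):
    """A record violates its schema (bad value, bad date, out-of-range)."""


class ReferentialIntegrityError(ValidationError):
    """A record references a patient_id absent from the patient table."""


class CategoryLabel(str, enum.Enum):
    """Shared 4-level taxonomy for goals of care and care received."""

    COMFORT = "comfort_focused"
    FUNCTION = "maintain_improve_function"
    LIFE_EXTENSION = "life_extension"
    UNCLEAR = "unclear"

    @classmethod
    def parse(cls, token: str) -> "CategoryLabel":
        try:
            return cls(token)
        except ValueError:
            raise ValidationError(
                f"unknown category label {token!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None

    @property
    def is_clear(self) -> bool:
        return self is not CategoryLabel.UNCLEAR


#: Stable display order used by confusion matrices and reports.
CATEGORY_ORDER: tuple[CategoryLabel, ...] = (
    CategoryLabel.COMFORT,
    CategoryLabel.FUNCTION,
    CategoryLabel.LIFE_EXTENSION,
    CategoryLabel.UNCLEAR,
)


class GOCSource(str, enum.Enum):
    """Provenance of the goals label governing an epoch."""

    BASELINE_PREHOSPITAL = "baseline_prehospital"
    DISCUSSION = "discussion"
    NONE = "none"


class DiscussionSetting(str, enum.Enum):
    PREHOSPITAL = "prehospital"
    INDEX_ADMISSION = "index_admission"
    POST_DISCHARGE = "post_discharge"


class RiskStratum(str, enum.Enum):
    """Predicted 6-month mortality risk stratum at admission."""

    HIGH_50_74 = "high_50_74"
    VERY_HIGH_GE_75 = "very_high_ge_75"


class AdmittingService(str, enum.Enum):
    MEDICAL = "medical"
    SURGICAL = "surgical"


class InterventionCode(str, enum.Enum):
    """Closed checklist of procedures/treatments noted during record review."""

    INVASIVE_DIAGNOSTIC_OR_MINOR_PROCEDURE = "invasive_diagnostic_or_minor_procedure"
    PHYSICAL_OCCUPATIONAL_THERAPY = "physical_occupational_therapy"
    DNR_DNI_ORDER = "dnr_dni_order"
    ICU_ADMISSION = "icu_admission"
    HOSPICE_ENROLLMENT = "hospice_enrollment"
    CHEMOTHERAPY = "chemotherapy"
    INVASIVE_PALLIATIVE_PROCEDURE = "invasive_palliative_procedure"
    INTUBATION_MECHANICAL_VENTILATION = "intubation_mechanical_ventilation"
    COMFORT_CARE_ONLY_ORDER = "comfort_care_only_order"
    SNF_REHAB_ADMISSION = "snf_rehab_admission"
    DIALYSIS = "dialysis"
    HOME_PALLIATIVE_CARE_CONSULT = "home_palliative_care_consult"
    SURGICAL_PROCEDURE = "surgical_procedure"
    PALLIATIVE_EXTUBATION = "palliative_extubation"
    ACLS_CPR = "acls_cpr"
    ICD_PACEMAKER_DEACTIVATION = "icd_pacemaker_deactivation"

    @classmethod
    def parse(cls, token: str) -> "InterventionCode":
        try:
            return cls(token)
        except ValueError:
            raise ValidationError(f"unknown intervention code {token!r}") from None


#: Covariates named in the association analyses; validated as booleans if present.
KNOWN_BOOLEAN_COVARIATES = (
    "metastatic_cancer",
    "cardiac_disease",
    "chronic_kidney_disease",
)


def parse_date(token: str, *, context: str = "") -> dt.date:
    """Parse a strict ISO-8601 calendar date; anything else is rejected."""
    try:
        return dt.date.fromisoformat(str(token).strip())
    except ValueError:
        raise ValidationError(
            f"invalid date {token!r}{' in ' + context if context else ''}; "
            "expected YYYY-MM-DD"
        ) from None


def _parse_optional_date(token, *, context: str = "") -> Optional[dt.date]:
    if token is None:
        return None
    if isinstance(token, float) and pd.isna(token):
        return None
    s = str(token).strip()
    if not s or s.lower() in {"nan", "none", "null"}:
        return None
    return parse_date(s, context=context)


def _parse_bool(token, *, context: str = "") -> bool:
    if isinstance(token, bool):
        return token
    s = str(token).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ValidationError(f"invalid boolean {token!r}{' in ' + context if context else ''}")


@dataclass(frozen=True)
class Patient:
    """One admitted patient with follow-up anchors and baseline covariates."""

    patient_id: str
    admission_date: dt.date
    death_date: Optional[dt.date] = None
    lost_to_followup_date: Optional[dt.date] = None
    mortality_risk_stratum: RiskStratum = RiskStratum.HIGH_50_74
    admitting_service: AdmittingService = AdmittingService.MEDICAL
    palliative_consult: bool = False
    covariates: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise ValidationError("patient_id must be non-empty")
        for name, d in (
            ("death_date", self.death_date),
            ("lost_to_followup_date", self.lost_to_followup_date),
        ):
            if d is not None and d < self.admission_date:
                raise ValidationError(
                    f"{name} {d} precedes admission_date {self.admission_date} "
                    f"for patient {self.patient_id}"
                )

    @property
    def died(self) -> bool:
        return self.death_date is not None


@dataclass(frozen=True)
class GOCDiscussion:
    """A documented goals-of-care discussion with its classified category."""

    patient_id: str
    discussion_date: dt.date
    category: CategoryLabel
    setting: DiscussionSetting = DiscussionSetting.INDEX_ADMISSION


@dataclass(frozen=True)
class CareAssessment:
    """One reviewer's care-received call for one epoch.

    ``confidence`` is the reviewer's 1-5 Likert self-rating
    (1 = not confident at all, 3 = moderately confident, 5 = very confident).
    """

    patient_id: str
    epoch_index: int
    reviewer_id: str
    category: CategoryLabel
    confidence: int
    interventions: frozenset = frozenset()
    free_text_rationale: Optional[str] = None

    def __post_init__(self) -> None:
        if self.epoch_index < 0:
            raise ValidationError(
                f"epoch_index must be >= 0, got {self.epoch_index} "
                f"(patient {self.patient_id})"
            )
        if self.confidence not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"confidence must be in 1..5, got {self.confidence} "
                f"(patient {self.patient_id}, epoch {self.epoch_index}, "
                f"reviewer {self.reviewer_id})"
            )


@dataclass
class CohortBundle:
    """Validated cohort: patients keyed by id, with date-sorted attachments."""

    patients: dict[str, Patient]
    discussions: dict[str, list[GOCDiscussion]]
    assessments: dict[str, list[CareAssessment]]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def discussions_for(self, patient_id: str) -> list[GOCDiscussion]:
        return self.discussions.get(patient_id, [])

    def assessments_for(self, patient_id: str) -> list[CareAssessment]:
        return self.assessments.get(patient_id, [])

    def all_assessments(self) -> list[CareAssessment]:
        out: list[CareAssessment] = []
        for pid in self.patients:
            out.extend(self.assessments.get(pid, []))
        return out


# ---------------------------------------------------------------------------
# Frame <-> object conversion

PATIENT_COLUMNS = [
    "patient_id",
    "admission_date",
    "death_date",
    "lost_to_followup_date",
    "mortality_risk_stratum",
    "admitting_service",
    "palliative_consult",
]
DISCUSSION_COLUMNS = ["patient_id", "discussion_date", "category", "setting"]
ASSESSMENT_COLUMNS = [
    "patient_id",
    "epoch_index",
    "reviewer_id",
    "category",
    "confidence",
    "interventions",
    "rationale",
]


def _fmt_date(d: Optional[dt.date]) -> str:
    return d.isoformat() if d is not None else ""


def patients_to_frame(patients: Iterable[Patient]) -> pd.DataFrame:
    rows = []
    cov_keys: list[str] = []
    patients = list(patients)
    for p in patients:
        for k in p.covariates:
            if k not in cov_keys:
                cov_keys.append(k)
    for p in patients:
        row = {
            "patient_id": p.patient_id,
            "admission_date": _fmt_date(p.admission_date),
            "death_date": _fmt_date(p.death_date),
            "lost_to_followup_date": _fmt_date(p.lost_to_followup_date),
            "mortality_risk_stratum": p.mortality_risk_stratum.value,
            "admitting_service": p.admitting_service.value,
            "palliative_consult": p.palliative_consult,
        }
        for k in cov_keys:
            v = p.covariates.get(k, "")
            row[k] = v
        rows.append(row)
    return pd.DataFrame(rows, columns=PATIENT_COLUMNS + cov_keys)


def discussions_to_frame(discussions: Iterable[GOCDiscussion]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": d.patient_id,
            "discussion_date": _fmt_date(d.discussion_date),
            "category": d.category.value,
            "setting": d.setting.value,
        }
        for d in discussions
    ]
    return pd.DataFrame(rows, columns=DISCUSSION_COLUMNS)


def assessments_to_frame(assessments: Iterable[CareAssessment]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": a.patient_id,
            "epoch_index": a.epoch_index,
            "reviewer_id": a.reviewer_id,
            "category": a.category.value,
            "confidence": a.confidence,
            "interventions": ";".join(sorted(c.value for c in a.interventions)),
            "rationale": a.free_text_rationale or "",
        }
        for a in assessments
    ]
    return pd.DataFrame(rows, columns=ASSESSMENT_COLUMNS)


def _patient_from_row(row: Mapping, cov_columns: Sequence[str], where: str) -> Patient:
    covs: dict[str, object] = {}
    for k in cov_columns:
        v = row.get(k)
        if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
            continue
        if k in KNOWN_BOOLEAN_COVARIATES:
            covs[k] = _parse_bool(v, context=f"{where}, column {k}")
        else:
            covs[k] = v
    return Patient(
        patient_id=str(row["patient_id"]),
        admission_date=parse_date(row["admission_date"], context=where),
        death_date=_parse_optional_date(row.get("death_date"), context=where),
        lost_to_followup_date=_parse_optional_date(
            row.get("lost_to_followup_date"), context=where
        ),
        mortality_risk_stratum=RiskStratum(str(row["mortality_risk_stratum"])),
        admitting_service=AdmittingService(str(row["admitting_service"])),
        palliative_consult=_parse_bool(row["palliative_consult"], context=where),
        covariates=covs,
    )


def _discussion_from_row(row: Mapping, where: str) -> GOCDiscussion:
    return GOCDiscussion(
        patient_id=str(row["patient_id"]),
        discussion_date=parse_date(row["discussion_date"], context=where),
        category=CategoryLabel.parse(str(row["category"])),
        setting=DiscussionSetting(str(row["setting"])),
    )


def _assessment_from_row(row: Mapping, where: str) -> CareAssessment:
    raw_iv = row.get("interventions", "")
    if raw_iv is None or (isinstance(raw_iv, float) and pd.isna(raw_iv)):
        raw_iv = ""
    codes = frozenset(
        InterventionCode.parse(tok) for tok in str(raw_iv).split(";") if tok.strip()
    )
    rationale = row.get("rationale")
    if rationale is None or (isinstance(rationale, float) and pd.isna(rationale)):
        rationale = ""
    try:
        conf = int(row["confidence"])
        ei = int(row["epoch_index"])
    except (TypeError, ValueError):
        raise ValidationError(f"non-integer epoch_index/confidence in {where}") from None
    return CareAssessment(
        patient_id=str(row["patient_id"]),
        epoch_index=ei,
        reviewer_id=str(row["reviewer_id"]),
        category=CategoryLabel.parse(str(row["category"])),
        confidence=conf,
        interventions=codes,
        free_text_rationale=str(rationale) or None,
    )


def _read_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read a CSV or JSON-records file into strings; missing -> empty."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            records = json.load(fh)
        df = pd.DataFrame.from_records(records)
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return df


def _rows(df: pd.DataFrame, path, kind: str, parser, **kw):
    out = []
    for i, row in enumerate(df.to_dict("records")):
        where = f"{path}, row {i + 2}"  # header is line 1 in CSV
        try:
            out.append(parser(row, where=where, **kw))
        except KeyError as exc:
            raise ValidationError(f"missing column {exc} in {kind} file {path}") from None
    return out


def load_cohort(
    patients_path: Union[str, Path],
    discussions_path: Optional[Union[str, Path]] = None,
    assessments_path: Optional[Union[str, Path]] = None,
) -> CohortBundle:
    """Load and validate a cohort bundle from CSV (or JSON-records) files.

    Discussions and assessments are sorted ascending by date / epoch index.
    Every referenced ``patient_id`` must resolve to a patient row.
    """
    pdf = _read_table(patients_path)
    cov_columns = [c for c in pdf.columns if c not in PATIENT_COLUMNS]
    patient_list = _rows(
        pdf, patients_path, "patient",
        lambda row, where: _patient_from_row(row, cov_columns, where),
    )
    patients: dict[str, Patient] = {}
    for p in patient_list:
        if p.patient_id in patients:
            raise ValidationError(f"duplicate patient_id {p.patient_id!r} in {patients_path}")
        patients[p.patient_id] = p

    discussions: dict[str, list[GOCDiscussion]] = {pid: [] for pid in patients}
    if discussions_path is not None:
        ddf = _read_table(discussions_path)
        for d in _rows(ddf, discussions_path, "discussion",
                       lambda row, where: _discussion_from_row(row, where)):
            if d.patient_id not in patients:
                raise ReferentialIntegrityError(
                    f"discussion references unknown patient {d.patient_id!r} "
                    f"({discussions_path})"
                )
            pat = patients[d.patient_id]
            if (d.setting is DiscussionSetting.PREHOSPITAL
                    and not d.discussion_date < pat.admission_date):
                raise ValidationError(
                    f"prehospital discussion on {d.discussion_date} is not before "
                    f"admission {pat.admission_date} (patient {d.patient_id})"
                )
            discussions[d.patient_id].append(d)
        for pid in discussions:
            discussions[pid].sort(key=lambda d: d.discussion_date)

    assessments: dict[str, list[CareAssessment]] = {pid: [] for pid in patients}
    if assessments_path is not None:
        adf = _read_table(assessments_path)
        for a in _rows(adf, assessments_path, "assessment",
                       lambda row, where: _assessment_from_row(row, where)):
            if a.patient_id not in patients:
                raise ReferentialIntegrityError(
                    f"assessment references unknown patient {a.patient_id!r} "
                    f"({assessments_path})"
                )
            assessments[a.patient_id].append(a)
        for pid in assessments:
            assessments[pid].sort(key=lambda a: (a.epoch_index, a.reviewer_id))

    return CohortBundle(patients=patients, discussions=discussions, assessments=assessments)


def write_records(records, path: Union[str, Path]) -> None:
    """Write a record set to CSV (or JSON) with a stable column order.

    Accepts a DataFrame or an iterable of Patient / GOCDiscussion /
    CareAssessment objects. ``load(write(x)) == x`` for valid bundles.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if not records:
            df = pd.DataFrame()
        elif isinstance(records[0], Patient):
            df = patients_to_frame(records)
        elif isinstance(records[0], GOCDiscussion):
            df = discussions_to_frame(records)
        elif isinstance(records[0], CareAssessment):
            df = assessments_to_frame(records)
        else:
            raise TypeError(f"cannot serialize records of type {type(records[0])}")
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        df.to_json(path, orient="records", indent=1)
    else:
        df.to_csv(path, index=False)
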