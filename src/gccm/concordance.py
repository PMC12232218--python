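"""Epoch-level goal-concordance classification.

An epoch is goal-concordant when the governing goals-of-care (GOC) label
and the final care-received label agree and neither is unclear;
goal-discordant when both are clear but differ; and of uncertain
concordance when no GOC discussion exists for the epoch or either label is
unclear. Uncertainty reasons are recorded non-exclusively: an epoch whose
goals and care are both unclear carries both reasons.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cohort import CategoryLabel, ValidationError
from .epochs import Epoch, GOCSource
from .reliability import FinalCareCall

__all__ = [
    "ConcordanceClass",
    "UncertaintyReason",
    "ConcordanceRecord",
    "classify_concordance",
    "classify_cohort",
    "uncertainty_breakdown",
    "records_to_frame",
]


class ConcordanceClass(str, enum.Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    UNCERTAIN = "uncertain"


class UncertaintyReason(str, enum.Enum):
    NO_GOC_DISCUSSION = "no_goc_discussion"
    GOC_UNCLEAR = "goc_unclear"
    CARE_UNCLEAR = "care_unclear"


@dataclass(frozen=True)
class ConcordanceRecord:
    patient_id: str
    epoch_index: int
    concordance: ConcordanceClass
    reasons: frozenset

    def __post_init__(self) -> None:
        if bool(self.reasons) != (self.concordance is ConcordanceClass.UNCERTAIN):
            raise ValidationError(
                "uncertainty reasons must be present exactly when the epoch "
                "is classified uncertain"
            )


def classify_concordance(
    goc: CategoryLabel,
    goc_source: GOCSource,
    care: CategoryLabel,
) -> tuple[ConcordanceClass, frozenset]:
    """Classify one epoch from its goals label, label provenance, and care label.

    Precedence: an epoch with no governing GOC discussion is uncertain
    (reason NO_GOC_DISCUSSION) regardless of labels; otherwise an unclear
    goals and/or care label makes it uncertain with the matching reason(s);
    otherwise concordant iff the two clear labels agree.
    """
    if goc_source is GOCSource.NONE:
        return ConcordanceClass.UNCERTAIN, frozenset({UncertaintyReason.NO_GOC_DISCUSSION})
    reasons = set()
    if goc is CategoryLabel.UNCLEAR:
        reasons.add(UncertaintyReason.GOC_UNCLEAR)
    if care is CategoryLabel.UNCLEAR:
        reasons.add(UncertaintyReason.CARE_UNCLEAR)
    if reasons:
        return ConcordanceClass.UNCERTAIN, frozenset(reasons)
    if goc == care:
        return ConcordanceClass.CONCORDANT, frozenset()
    return ConcordanceClass.DISCORDANT, frozenset()


def classify_cohort(
    epochs: Iterable[Epoch],
    final_calls: Iterable[FinalCareCall],
) -> list[ConcordanceRecord]:
    """One concordance record per epoch, in epoch order."""
    calls: Mapping[tuple[str, int], FinalCareCall] = {
        (c.patient_id, c.epoch_index): c for c in final_calls
    }
    records = []
    for e in epochs:
        key = (e.patient_id, e.epoch_index)
        if key not in calls:
            raise ValidationError(
                f"epoch {key} has no final care-received call; cannot classify"
            )
        cls, reasons = classify_concordance(e.goc_category, e.goc_source,
                                            calls[key].category)
        records.append(ConcordanceRecord(e.patient_id, e.epoch_index, cls, reasons))
    return records


def uncertainty_breakdown(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    """Counts and percentages per uncertainty reason.

    The denominator is the number of uncertain epochs; reasons are
    non-exclusive so counts may sum to more than the denominator. Returns an
    empty frame when no epoch is uncertain.
    """
    uncertain = [r for r in records if r.concordance is ConcordanceClass.UNCERTAIN]
    n = len(uncertain)
    if n == 0:
        return pd.DataFrame(columns=["reason", "count", "percent"])
    rows = []
    for reason in UncertaintyReason:
        count = sum(1 for r in uncertain if reason in r.reasons)
        rows.append({
            "reason": reason.value,
            "count": count,
            "percent": 100.0 * count / n,
        })
    return pd.DataFrame(rows, columns=["reason", "count", "percent"])


CONCORDANCE_COLUMNS = ["patient_id", "epoch_index", "concordance", "reasons"]


def records_to_frame(records: Iterable[ConcordanceRecord]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": r.patient_id,
            "epoch_index": r.epoch_index,
            "concordance": r.concordance.value,
            "reasons": ";".join(sorted(x.value for x in r.reasons)),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=CONCORDANCE_COLUMNS)
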