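"""Construct each patient's ordered, disjoint epochs of care.

Follow-up runs from hospital admission through death or a fixed horizon
(default 180 days), whichever comes first. Every documented goals-of-care
(GOC) discussion inside that window opens a new epoch on its date, so the
epochs tile the window exactly; a patient with no qualifying discussion is
assessed as a single epoch. Epoch 0 carries the baseline goals established
by the most recent prehospital discussion inside the lookback window
(default 180 days before admission), or "unclear" with source NONE when no
such discussion exists.

Intervals are half-open ``[start, end)``: a discussion takes effect the day
it is documented, and the death day belongs to the final epoch (the window
ends the day after death) so care at the time of death is attributable.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .cohort import (
    CategoryLabel,
    GOCDiscussion,
    GOCSource,
    Patient,
    ValidationError,
)

__all__ = ["Epoch", "FollowupWindow", "followup_end", "baseline_goc",
           "build_epochs", "build_cohort_epochs", "epochs_to_frame"]

ONE_DAY = dt.timedelta(days=1)


@dataclass(frozen=True)
class FollowupWindow:
    """Follow-up horizon and baseline lookback, both in calendar days."""

    followup_days: int = 180
    baseline_lookback_days: int = 180

    def __post_init__(self) -> None:
        if self.followup_days <= 0 or self.baseline_lookback_days <= 0:
            raise ValidationError("window lengths must be strictly positive")


@dataclass(frozen=True)
class Epoch:
    """Half-open interval ``[start_date, end_date)`` with its governing goals."""

    patient_id: str
    epoch_index: int
    start_date: dt.date
    end_date: dt.date
    goc_category: CategoryLabel
    goc_source: GOCSource
    opening_discussion_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if not self.start_date < self.end_date:
            raise ValidationError(
                f"zero/negative-length epoch [{self.start_date}, {self.end_date}) "
                f"for patient {self.patient_id}"
            )
        if self.goc_source is GOCSource.NONE and self.goc_category is not CategoryLabel.UNCLEAR:
            raise ValidationError("goc_source NONE requires goc_category unclear")

    @property
    def duration_days(self) -> int:
        return (self.end_date - self.start_date).days


def followup_end(
    patient: Patient,
    window: FollowupWindow = FollowupWindow(),
    censor_at_ltfu: bool = False,
) -> dt.date:
    """End (exclusive) of the patient's follow-up window.

    ``min(admission + followup_days, death + 1 day, ltfu + 1 day)``, the
    latter two only when applicable. The +1 day keeps the death (or last
    contact) day inside the final half-open epoch.
    """
    end = patient.admission_date + dt.timedelta(days=window.followup_days)
    if patient.death_date is not None:
        end = min(end, patient.death_date + ONE_DAY)
    if censor_at_ltfu and patient.lost_to_followup_date is not None:
        end = min(end, patient.lost_to_followup_date + ONE_DAY)
    return end


def baseline_goc(
    patient: Patient,
    discussions: Sequence[GOCDiscussion],
    window: FollowupWindow = FollowupWindow(),
) -> tuple[CategoryLabel, GOCSource]:
    """Baseline goals at admission from the most recent prehospital discussion.

    Considers discussions with ``admission - lookback <= date < admission``.
    A discussion dated exactly on the admission date instead governs epoch 0
    with source DISCUSSION (handled by :func:`build_epochs`). With no
    qualifying discussion the baseline is (UNCLEAR, NONE).
    """
    adm = patient.admission_date
    horizon = adm - dt.timedelta(days=window.baseline_lookback_days)
    candidates = [d for d in discussions if horizon <= d.discussion_date < adm]
    if not candidates:
        return CategoryLabel.UNCLEAR, GOCSource.NONE
    latest = max(candidates, key=lambda d: d.discussion_date)
    # same-day prehospital discussions: last clear label of that day governs
    same_day = [d for d in candidates if d.discussion_date == latest.discussion_date]
    return _collapse_same_day(same_day), GOCSource.BASELINE_PREHOSPITAL


def _collapse_same_day(discussions: Sequence[GOCDiscussion]) -> CategoryLabel:
    """Governing label for several discussions on one date.

    The last clear (non-unclear) label in input order wins; if every label
    that day is unclear, the result is unclear.
    """
    label = CategoryLabel.UNCLEAR
    for d in discussions:
        if d.category.is_clear:
            label = d.category
    return label


def build_epochs(
    patient: Patient,
    discussions: Sequence[GOCDiscussion],
    window: FollowupWindow = FollowupWindow(),
    censor_at_ltfu: bool = False,
) -> list[Epoch]:
    """Partition ``[admission, followup_end)`` into epochs at discussion dates.

    Boundary dates are the distinct discussion dates strictly inside the
    window; each epoch carries the category of the discussion opening it
    (epoch 0 carries the baseline, or the label of an admission-day
    discussion). Discussions on/after the window end are ignored; multiple
    discussions on one date collapse to a single boundary. A patient with no
    qualifying discussion yields one whole-window epoch with source NONE.
    """
    for d in discussions:
        if d.patient_id != patient.patient_id:
            raise ValidationError(
                f"discussion for patient {d.patient_id!r} mixed into "
                f"build_epochs({patient.patient_id!r})"
            )
    adm = patient.admission_date
    end = followup_end(patient, window, censor_at_ltfu)

    base_cat, base_src = baseline_goc(patient, discussions, window)

    # admission-day discussions govern epoch 0 rather than opening a boundary
    day0 = [d for d in discussions if d.discussion_date == adm]
    if day0:
        base_cat, base_src = _collapse_same_day(day0), GOCSource.DISCUSSION
    opening0 = adm if day0 else (
        max(d.discussion_date for d in discussions
            if adm - dt.timedelta(days=window.baseline_lookback_days)
            <= d.discussion_date < adm)
        if base_src is GOCSource.BASELINE_PREHOSPITAL else None
    )

    in_window = [d for d in discussions if adm < d.discussion_date < end]
    boundary_dates = sorted({d.discussion_date for d in in_window})

    epochs: list[Epoch] = []
    starts = [adm] + boundary_dates
    ends = boundary_dates + [end]
    cats = [base_cat] + [
        _collapse_same_day([d for d in in_window if d.discussion_date == b])
        for b in boundary_dates
    ]
    sources = [base_src] + [GOCSource.DISCUSSION] * len(boundary_dates)
    openings = [opening0] + boundary_dates
    for i, (s, e, c, src, op) in enumerate(zip(starts, ends, cats, sources, openings)):
        epochs.append(
            Epoch(
                patient_id=patient.patient_id,
                epoch_index=i,
                start_date=s,
                end_date=e,
                goc_category=c,
                goc_source=src,
                opening_discussion_date=op,
            )
        )
    return epochs


def build_cohort_epochs(
    patients: Iterable[Patient],
    discussions_by_patient,
    window: FollowupWindow = FollowupWindow(),
    censor_at_ltfu: bool = False,
) -> dict[str, list[Epoch]]:
    """Epochs for every patient, keyed by patient_id."""
    out: dict[str, list[Epoch]] = {}
    for p in patients:
        out[p.patient_id] = build_epochs(
            p, discussions_by_patient.get(p.patient_id, []), window, censor_at_ltfu
        )
    return out


EPOCH_COLUMNS = ["patient_id", "epoch_index", "start_date", "end_date",
                 "goc_category", "goc_source", "opening_discussion_date"]


def epochs_to_frame(epochs: Iterable[Epoch]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": e.patient_id,
            "epoch_index": e.epoch_index,
            "start_date": e.start_date.isoformat(),
            "end_date": e.end_date.isoformat(),
            "goc_category": e.goc_category.value,
            "goc_source": e.goc_source.value,
            "opening_discussion_date": (
                e.opening_discussion_date.isoformat()
                if e.opening_discussion_date is not None else ""
            ),
        }
        for e in epochs
    ]
    return pd.DataFrame(rows, columns=EPOCH_COLUMNS)
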