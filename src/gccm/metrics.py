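"""Patient-level and cohort-level aggregation of epoch concordance.

The headline patient outcome is a "high rate" of goal-concordant care
(GCC): at least 75% of the patient's epochs classified concordant. A
patient shows "variable concordance" when their epochs span two or more
distinct concordance classes. Concordance at the time of death is the
class of a decedent's final epoch, which contains the death day by the
epoch-construction convention.

Quantiles use linear interpolation (numpy's default, Hyndman-Fan type 7).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import Patient, ValidationError
from .concordance import ConcordanceClass, ConcordanceRecord
from .epochs import Epoch, GOCSource

__all__ = ["PatientSummary", "summarize_patient", "summarize_cohort_patients",
           "cohort_summary", "transition_summary", "summaries_to_frame"]

HIGH_GCC_THRESHOLD = 0.75


@dataclass(frozen=True)
class PatientSummary:
    patient_id: str
    n_epochs: int
    n_concordant: int
    n_discordant: int
    n_uncertain: int
    prop_gcc: float
    high_gcc: bool
    any_concordant: bool
    any_discordant: bool
    any_uncertain: bool
    variable_concordance: bool
    died: bool
    final_epoch_concordance: ConcordanceClass
    epoch_durations_days: tuple[int, ...]
    has_any_discussion: bool


def summarize_patient(
    records: Sequence[ConcordanceRecord],
    epochs: Sequence[Epoch],
    died: bool,
) -> PatientSummary:
    """Aggregate one patient's ordered epoch records."""
    if not records or not epochs or len(records) != len(epochs):
        raise ValidationError("records and epochs must be non-empty and aligned")
    pid = epochs[0].patient_id
    classes = [r.concordance for r in records]
    n = len(classes)
    n_c = sum(c is ConcordanceClass.CONCORDANT for c in classes)
    n_d = sum(c is ConcordanceClass.DISCORDANT for c in classes)
    n_u = n - n_c - n_d
    prop = n_c / n
    return PatientSummary(
        patient_id=pid,
        n_epochs=n,
        n_concordant=n_c,
        n_discordant=n_d,
        n_uncertain=n_u,
        prop_gcc=prop,
        high_gcc=prop >= HIGH_GCC_THRESHOLD,
        any_concordant=n_c > 0,
        any_discordant=n_d > 0,
        any_uncertain=n_u > 0,
        variable_concordance=len(set(classes)) >= 2,
        died=died,
        final_epoch_concordance=classes[-1],
        epoch_durations_days=tuple(e.duration_days for e in epochs),
        has_any_discussion=any(e.goc_source is not GOCSource.NONE for e in epochs)
        or len(epochs) > 1,
    )


def summarize_cohort_patients(
    patients: Iterable[Patient],
    epochs_by_patient,
    records: Sequence[ConcordanceRecord],
) -> list[PatientSummary]:
    by_pid: dict[str, list[ConcordanceRecord]] = {}
    for r in records:
        by_pid.setdefault(r.patient_id, []).append(r)
    out = []
    for p in patients:
        recs = sorted(by_pid.get(p.patient_id, []), key=lambda r: r.epoch_index)
        out.append(summarize_patient(recs, epochs_by_patient[p.patient_id], p.died))
    return out


def _median_iqr(values) -> dict:
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return {"median": None, "q1": None, "q3": None}
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # type-7 linear interpolation
    return {"median": float(med), "q1": float(q1), "q3": float(q3)}


def cohort_summary(
    summaries: Sequence[PatientSummary],
    epochs_by_patient,
    duration_scope: str = "discussion_opened",
) -> dict:
    """Cohort-level aggregates.

    Epoch-duration statistics cover, by default, only epochs opened by a
    goals-of-care discussion (the gaps between consecutive discussions);
    ``duration_scope="all"`` includes baseline and no-discussion epochs.
    """
    if not summaries:
        raise ValidationError("cohort_summary requires at least one patient")
    n_pat = len(summaries)
    all_epochs = [e for eps in epochs_by_patient.values() for e in eps]
    if duration_scope == "discussion_opened":
        dur_epochs = [e for e in all_epochs if e.goc_source is GOCSource.DISCUSSION
                      and e.opening_discussion_date is not None
                      and e.opening_discussion_date >= e.start_date]
    elif duration_scope == "all":
        dur_epochs = all_epochs
    else:
        raise ValueError(f"unknown duration_scope {duration_scope!r}")

    n_epochs_total = sum(s.n_epochs for s in summaries)
    decedents = [s for s in summaries if s.died]
    at_death = {c.value: 0 for c in ConcordanceClass}
    for s in decedents:
        at_death[s.final_epoch_concordance.value] += 1

    def _count(flag):
        c = sum(1 for s in summaries if getattr(s, flag))
        return {"count": c, "proportion": c / n_pat}

    return {
        "n_patients": n_pat,
        "n_epochs": n_epochs_total,
        "epochs_per_patient": _median_iqr(s.n_epochs for s in summaries),
        "epoch_duration_days": _median_iqr(e.duration_days for e in dur_epochs),
        "prop_gcc_per_patient": _median_iqr(s.prop_gcc for s in summaries),
        "any_concordant": _count("any_concordant"),
        "high_gcc": _count("high_gcc"),
        "any_discordant": _count("any_discordant"),
        "any_uncertain": _count("any_uncertain"),
        "variable_concordance": _count("variable_concordance"),
        "has_any_discussion": _count("has_any_discussion"),
        "died": _count("died"),
        "epoch_totals": {
            "concordant": sum(s.n_concordant for s in summaries),
            "discordant": sum(s.n_discordant for s in summaries),
            "uncertain": sum(s.n_uncertain for s in summaries),
        },
        "at_death": {
            "n_decedents": len(decedents),
            "counts": at_death,
            "proportions": {
                k: (v / len(decedents) if decedents else None)
                for k, v in at_death.items()
            },
        },
    }


def transition_summary(records: Sequence[ConcordanceRecord]) -> dict:
    """Resolution of initially uncertain concordance.

    Among patients with >= 2 epochs whose first epoch is uncertain, tallies
    the first non-uncertain class subsequently reached (concordant vs
    discordant), and those who never resolve.
    """
    by_pid: dict[str, list[ConcordanceRecord]] = {}
    for r in records:
        by_pid.setdefault(r.patient_id, []).append(r)
    n_initial_uncertain = 0
    to_concordant = 0
    to_discordant = 0
    never_resolved = 0
    for recs in by_pid.values():
        recs = sorted(recs, key=lambda r: r.epoch_index)
        if len(recs) < 2:
            continue
        if recs[0].concordance is not ConcordanceClass.UNCERTAIN:
            continue
        n_initial_uncertain += 1
        first_resolved = next(
            (r.concordance for r in recs[1:]
             if r.concordance is not ConcordanceClass.UNCERTAIN),
            None,
        )
        if first_resolved is ConcordanceClass.CONCORDANT:
            to_concordant += 1
        elif first_resolved is ConcordanceClass.DISCORDANT:
            to_discordant += 1
        else:
            never_resolved += 1
    return {
        "n_initial_uncertain": n_initial_uncertain,
        "to_concordant": to_concordant,
        "to_discordant": to_discordant,
        "never_resolved": never_resolved,
        "n_resolved": to_concordant + to_discordant,
    }


SUMMARY_COLUMNS = [
    "patient_id", "n_epochs", "n_concordant", "n_discordant", "n_uncertain",
    "prop_gcc", "high_gcc", "any_concordant", "any_discordant", "any_uncertain",
    "variable_concordance", "died", "final_epoch_concordance", "has_any_discussion",
]


def summaries_to_frame(summaries: Iterable[PatientSummary]) -> pd.DataFrame:
    rows = [
        {c: getattr(s, c) if c != "final_epoch_concordance"
         else s.final_epoch_concordance.value for c in SUMMARY_COLUMNS}
        for s in summaries
    ]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
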