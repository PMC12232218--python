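"""Reviewer-pair reconciliation and interrater reliability.

Each epoch is independently classified by two blinded reviewers. Equal
categories stand as the final call (AGREEMENT); disagreements are resolved
by pair consensus (CONSENSUS) or, failing that, by an independent
adjudicator (ADJUDICATED). Reliability of the pre-consensus calls is
quantified by raw percent agreement and unweighted Cohen's kappa over the
4x4 confusion matrix, with the asymptotic standard error of Fleiss, Cohen
& Everitt (1969) for the confidence interval.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import CATEGORY_ORDER, CareAssessment, CategoryLabel, ValidationError

__all__ = [
    "Resolution",
    "FinalCareCall",
    "KappaResult",
    "UnresolvedDisagreementError",
    "reconcile",
    "reconcile_all",
    "paired_assessments",
    "confusion_matrix",
    "cohen_kappa",
    "kappa_by_confidence",
    "final_calls_to_frame",
]


class Resolution(str, enum.Enum):
    AGREEMENT = "agreement"
    CONSENSUS = "consensus"
    ADJUDICATED = "adjudicated"


class UnresolvedDisagreementError(ValidationError):
    """Reviewers disagree and neither a consensus nor adjudicator label exists."""


@dataclass(frozen=True)
class FinalCareCall:
    """Reconciled care-received label for one epoch."""

    patient_id: str
    epoch_index: int
    category: CategoryLabel
    resolution: Resolution
    reviewer_categories: tuple[CategoryLabel, CategoryLabel]
    confidences: tuple[int, int]


@dataclass(frozen=True)
class KappaResult:
    """Cohen's kappa with its confusion matrix and Wald confidence interval."""

    confusion_matrix: np.ndarray
    labels: tuple[CategoryLabel, ...]
    n: int
    percent_agreement: float
    kappa: float
    se: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {
            "labels": [l.value for l in self.labels],
            "confusion_matrix": self.confusion_matrix.astype(int).tolist(),
            "n": self.n,
            "percent_agreement": self.percent_agreement,
            "kappa": self.kappa,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def reconcile(
    assessments: tuple[CareAssessment, CareAssessment],
    consensus_label: Optional[CategoryLabel] = None,
    adjudicator_label: Optional[CategoryLabel] = None,
) -> FinalCareCall:
    """Combine two blinded assessments of one epoch into the final call.

    Agreement stands as-is; otherwise the pair-consensus label is used, and
    only when consensus failed does the adjudicator's label decide.
    """
    a, b = assessments
    if (a.patient_id, a.epoch_index) != (b.patient_id, b.epoch_index):
        raise ValidationError(
            f"assessments reference different epochs: "
            f"({a.patient_id},{a.epoch_index}) vs ({b.patient_id},{b.epoch_index})"
        )
    if a.reviewer_id == b.reviewer_id:
        raise ValidationError(
            f"both assessments for ({a.patient_id},{a.epoch_index}) are by "
            f"reviewer {a.reviewer_id!r}"
        )
    # deterministic A/B roles by lexicographic reviewer id
    if b.reviewer_id < a.reviewer_id:
        a, b = b, a
    pair = (a.category, b.category)
    confs = (a.confidence, b.confidence)
    if a.category == b.category:
        if consensus_label is not None:
            warnings.warn(
                f"consensus label supplied for agreeing reviewers on "
                f"({a.patient_id},{a.epoch_index}); ignored",
                stacklevel=2,
            )
        return FinalCareCall(a.patient_id, a.epoch_index, a.category,
                             Resolution.AGREEMENT, pair, confs)
    if consensus_label is not None:
        return FinalCareCall(a.patient_id, a.epoch_index, consensus_label,
                             Resolution.CONSENSUS, pair, confs)
    if adjudicator_label is not None:
        return FinalCareCall(a.patient_id, a.epoch_index, adjudicator_label,
                             Resolution.ADJUDICATED, pair, confs)
    raise UnresolvedDisagreementError(
        f"epoch ({a.patient_id},{a.epoch_index}): reviewers disagree "
        f"({a.category.value} vs {b.category.value}) and no consensus or "
        "adjudicator label was supplied"
    )


def paired_assessments(
    assessments: Iterable[CareAssessment],
) -> dict[tuple[str, int], tuple[CareAssessment, CareAssessment]]:
    """Group assessments by epoch; every epoch must have exactly two."""
    groups: dict[tuple[str, int], list[CareAssessment]] = {}
    for a in assessments:
        groups.setdefault((a.patient_id, a.epoch_index), []).append(a)
    pairs = {}
    for key, group in sorted(groups.items()):
        if len(group) != 2:
            raise ValidationError(
                f"epoch {key} has {len(group)} assessments; expected exactly 2"
            )
        x, y = sorted(group, key=lambda a: a.reviewer_id)
        pairs[key] = (x, y)
    return pairs


def reconcile_all(
    assessments: Iterable[CareAssessment],
    resolutions: Optional[Mapping[tuple[str, int], Mapping[str, Optional[CategoryLabel]]]] = None,
) -> list[FinalCareCall]:
    """Reconcile every epoch; ``resolutions`` maps (patient_id, epoch_index)
    to ``{"consensus": label-or-None, "adjudicator": label-or-None}``."""
    resolutions = resolutions or {}
    calls = []
    for key, pair in paired_assessments(assessments).items():
        res = resolutions.get(key, {})
        cons = res.get("consensus")
        adj = res.get("adjudicator")
        if pair[0].category == pair[1].category:
            cons = adj = None  # agreement needs no resolution; avoid spurious warning
        calls.append(reconcile(pair, consensus_label=cons, adjudicator_label=adj))
    return calls


def confusion_matrix(
    assessments: Iterable[CareAssessment],
    labels: Sequence[CategoryLabel] = CATEGORY_ORDER,
) -> np.ndarray:
    """k x k pre-consensus confusion counts; rows = reviewer A (lexicographic
    smaller reviewer_id), columns = reviewer B."""
    idx = {lab: i for i, lab in enumerate(labels)}
    mat = np.zeros((len(labels), len(labels)), dtype=np.int64)
    for a, b in paired_assessments(assessments).values():
        mat[idx[a.category], idx[b.category]] += 1
    return mat


def cohen_kappa(
    matrix: np.ndarray,
    alpha: float = 0.05,
    labels: Sequence[CategoryLabel] = CATEGORY_ORDER,
) -> KappaResult:
    """Unweighted Cohen's kappa from a square confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with p_e from the marginal products.
    The standard error is the asymptotic (non-null) variance of Fleiss,
    Cohen & Everitt; the Wald interval is truncated to [-1, 1].
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if (m < 0).any():
        raise ValidationError("confusion matrix counts must be non-negative")
    n = m.sum()
    if n < 1:
        raise ValidationError("confusion matrix must contain at least one pair")
    p = m / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    p_o = np.trace(p)
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-15:
        raise ValidationError(
            "degenerate marginals: chance agreement is 1 (all mass in one "
            "category for both raters); kappa is undefined"
        )
    kappa = (p_o - p_e) / (1 - p_e)

    # Fleiss, Cohen & Everitt (1969) large-sample variance
    k = m.shape[0]
    term1 = sum(
        p[i, i] * ((1 - p_e) - (col[i] + row[i]) * (1 - p_o)) ** 2
        for i in range(k)
    )
    term2 = (1 - p_o) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2
        for i in range(k) for j in range(k) if i != j
    )
    term3 = (p_o * p_e - 2 * p_e + p_o) ** 2
    var = (term1 + term2 - term3) / (n * (1 - p_e) ** 4)
    se = float(np.sqrt(max(var, 0.0)))
    z = norm.ppf(1 - alpha / 2)
    ci_low = max(-1.0, kappa - z * se)
    ci_high = min(1.0, kappa + z * se)
    return KappaResult(
        confusion_matrix=np.asarray(matrix),
        labels=tuple(labels),
        n=int(round(n)),
        percent_agreement=float(p_o),
        kappa=float(kappa),
        se=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
    )


def kappa_by_confidence(
    assessments: Iterable[CareAssessment],
    low_band: frozenset = frozenset({1, 2}),
    high_band: frozenset = frozenset({3, 4, 5}),
    band_rule: str = "min",
    alpha: float = 0.05,
) -> dict[str, Optional[KappaResult]]:
    """Per-confidence-band kappa on the paired pre-consensus assessments.

    An epoch enters a band by the minimum of its two reviewers' confidences
    (``band_rule="mean"`` uses the pair mean instead). A band that is empty,
    or whose pairs all fall in a single category for both reviewers (kappa
    undefined), maps to None rather than raising.
    """
    pairs = paired_assessments(assessments)
    banded: dict[str, list[CareAssessment]] = {"low": [], "high": []}
    for a, b in pairs.values():
        if band_rule == "min":
            score = min(a.confidence, b.confidence)
        elif band_rule == "mean":
            score = (a.confidence + b.confidence) / 2
        else:
            raise ValueError(f"unknown band_rule {band_rule!r}")
        band = "low" if score in low_band or score <= max(low_band) else "high"
        banded[band].extend([a, b])
    out: dict[str, Optional[KappaResult]] = {}
    for band, subset in banded.items():
        if not subset:
            out[band] = None
            continue
        try:
            out[band] = cohen_kappa(confusion_matrix(subset), alpha=alpha)
        except ValidationError:
            out[band] = None  # degenerate marginals within the band
    return out


FINAL_CALL_COLUMNS = ["patient_id", "epoch_index", "category", "resolution"]


def final_calls_to_frame(calls: Iterable[FinalCareCall]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": c.patient_id,
            "epoch_index": c.epoch_index,
            "category": c.category.value,
            "resolution": c.resolution.value,
        }
        for c in calls
    ]
    return pd.DataFrame(rows, columns=FINAL_CALL_COLUMNS)
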