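"""Bivariable inference on 2x2 tables: Pearson chi-square, Fisher exact,
and single-predictor logistic regression with odds ratios.

The chi-square statistic is the classic Pearson sum over the four cells
with expected counts from the marginal products and NO continuity
correction. The Fisher exact two-sided p-value follows the "small-p"
summation rule — the sum of hypergeometric probabilities, over all tables
with the observed margins, no larger than that of the observed table —
computed by exact integer enumeration, so ties are resolved exactly rather
than by floating-point comparison.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import norm

import statsmodels.api as sm

from .cohort import ValidationError

__all__ = [
    "ContingencyTable2x2",
    "TestMethod",
    "TestResult",
    "DegenerateTableError",
    "build_table",
    "chi2_pearson",
    "fisher_exact",
    "bivariable_logistic",
    "run_prespecified_associations",
]


class DegenerateTableError(ValidationError):
    """A zero marginal makes the chi-square test undefined; use Fisher."""


class TestMethod(str, enum.Enum):
    CHI2_PEARSON = "chi2_pearson"
    FISHER_EXACT = "fisher_exact"
    LOGISTIC = "logistic"


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = exposure yes/no, columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("exposed", "unexposed")
    col_labels: tuple[str, str] = ("outcome", "no_outcome")

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValidationError(f"cell counts must be non-negative integers: {cells}")
        if self.n < 1:
            raise ValidationError("table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def to_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @classmethod
    def from_array(cls, arr, **kw) -> "ContingencyTable2x2":
        (a, b), (c, d) = np.asarray(arr)
        return cls(int(a), int(b), int(c), int(d), **kw)


@dataclass(frozen=True)
class TestResult:
    method: TestMethod
    p_value: float
    statistic: Optional[float] = None
    dof: Optional[int] = None
    odds_ratio: Optional[float] = None
    or_ci: Optional[tuple[float, float]] = None
    estimable: bool = True
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not math.isnan(self.p_value):
            raise ValidationError(f"p-value {self.p_value} outside [0, 1]")


def build_table(
    frame: pd.DataFrame,
    exposure: str,
    outcome: str,
    row_labels: Optional[tuple[str, str]] = None,
    col_labels: Optional[tuple[str, str]] = None,
) -> ContingencyTable2x2:
    """Cross-classify every row of ``frame`` by two boolean columns.

    The frame's rows are the analysis units (patients, epochs, or
    reviewer-epoch assessments); ``n`` of the table equals ``len(frame)``.
    """
    if frame.empty:
        raise ValidationError("cannot build a contingency table from an empty frame")
    for col in (exposure, outcome):
        if col not in frame.columns:
            raise ValidationError(f"column {col!r} not present in analysis frame")
        if frame[col].isna().any():
            raise ValidationError(f"column {col!r} contains missing values")
    e = frame[exposure].astype(bool)
    o = frame[outcome].astype(bool)
    return ContingencyTable2x2(
        a=int((e & o).sum()),
        b=int((e & ~o).sum()),
        c=int((~e & o).sum()),
        d=int((~e & ~o).sum()),
        row_labels=row_labels or (exposure, f"not_{exposure}"),
        col_labels=col_labels or (outcome, f"not_{outcome}"),
    )


def chi2_pearson(table: ContingencyTable2x2, correction: bool = False) -> TestResult:
    """Pearson chi-square on a 2x2 table (1 df), default without Yates
    continuity correction; p from the upper tail of chi-square(1)."""
    obs = table.to_array().astype(float)
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    n = obs.sum()
    if (row == 0).any() or (col == 0).any():
        raise DegenerateTableError(
            "a zero marginal leaves expected counts of 0; use fisher_exact"
        )
    expected = np.outer(row, col) / n
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float((diff ** 2 / expected).sum())
    p = float(chi2_dist.sf(stat, df=1))
    return TestResult(method=TestMethod.CHI2_PEARSON, statistic=stat, dof=1, p_value=p)


def fisher_exact(table: ContingencyTable2x2) -> TestResult:
    """Two-sided Fisher exact test by full enumeration (small-p rule).

    With margins fixed, table probabilities are hypergeometric:
    P(a') = C(r1, a') C(r2, c1 - a') / C(n, c1). All arithmetic is on the
    integer numerators, so the comparison "P(table) <= P(observed)" is exact.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    r1, r2 = a + b, c + d
    c1 = a + c
    n = table.n
    lo = max(0, c1 - r2)
    hi = min(c1, r1)
    weights = [math.comb(r1, x) * math.comb(r2, c1 - x) for x in range(lo, hi + 1)]
    observed = math.comb(r1, a) * math.comb(r2, c)
    numer = sum(w for w in weights if w <= observed)
    denom = math.comb(n, c1)
    p = min(1.0, numer / denom)
    return TestResult(method=TestMethod.FISHER_EXACT, p_value=p)


def _table_from_vectors(outcome, predictor) -> ContingencyTable2x2:
    o = np.asarray(outcome, dtype=bool)
    e = np.asarray(predictor, dtype=bool)
    return ContingencyTable2x2(
        a=int((e & o).sum()), b=int((e & ~o).sum()),
        c=int((~e & o).sum()), d=int((~e & ~o).sum()),
    )


def bivariable_logistic(
    outcome: Sequence,
    predictor: Sequence,
    alpha: float = 0.05,
) -> TestResult:
    """Single-predictor logistic regression: odds ratio, Wald CI, Wald p.

    For a binary predictor the maximum-likelihood odds ratio equals the
    cross-product ratio ad/bc of the implied 2x2 table. A zero cell
    (complete or quasi-complete separation on a binary predictor) makes the
    odds ratio non-estimable; the result is flagged rather than raising.
    """
    y = np.asarray(outcome)
    x = np.asarray(predictor)
    if y.shape != x.shape or y.ndim != 1:
        raise ValidationError("outcome and predictor must be equal-length vectors")
    y = y.astype(float)
    uniq = np.unique(y)
    if not np.isin(uniq, [0.0, 1.0]).all() or len(uniq) != 2:
        raise ValidationError("outcome must be binary with both classes present")

    x_bool = None
    ux = np.unique(x)
    if len(ux) == 2 and set(np.asarray(ux, dtype=object)) <= {0, 1, 0.0, 1.0, True, False}:
        x_bool = x.astype(bool)
    if x_bool is not None:
        t = _table_from_vectors(y.astype(bool), x_bool)
        if min(t.a, t.b, t.c, t.d) == 0:
            return TestResult(
                method=TestMethod.LOGISTIC, p_value=float("nan"),
                estimable=False, flags=("separation_zero_cell",),
            )
    X = sm.add_constant(x.astype(float))
    try:
        fit = sm.Logit(y, X).fit(disp=0)
    except Exception:
        return TestResult(method=TestMethod.LOGISTIC, p_value=float("nan"),
                          estimable=False, flags=("fit_failed",))
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(beta) or not np.isfinite(se) or se > 1e3:
        return TestResult(method=TestMethod.LOGISTIC, p_value=float("nan"),
                          estimable=False, flags=("separation",))
    z = norm.ppf(1 - alpha / 2)
    return TestResult(
        method=TestMethod.LOGISTIC,
        statistic=float((beta / se) ** 2),
        dof=1,
        p_value=float(fit.pvalues[1]),
        odds_ratio=float(math.exp(beta)),
        or_ci=(float(math.exp(beta - z * se)), float(math.exp(beta + z * se))),
    )


def format_p(p: float) -> str:
    """Journal-style p formatting for reports: 3 dp with '<.001' floor."""
    if math.isnan(p):
        return "NA"
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") if p < 1 else "1.000"


def run_prespecified_associations(
    frames: dict,
    config: Sequence[dict],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run a batch of prespecified bivariable association tests.

    ``frames`` maps unit name ("patient", "epoch", "reviewer_assessment") to
    an analysis frame with boolean columns; ``config`` is a list of
    ``{"exposure": ..., "outcome": ..., "unit": ..., "method": ...}`` with
    method one of chi2_pearson / fisher_exact / logistic. A degenerate
    chi-square table falls back to Fisher; per-row failures are collected in
    a ``flags`` column rather than aborting the batch.
    """
    rows = []
    for item in config:
        unit = item.get("unit", "patient")
        exposure = item["exposure"]
        outcome = item["outcome"]
        method = TestMethod(item.get("method", "chi2_pearson"))
        row = {
            "exposure": exposure, "outcome": outcome, "unit": unit,
            "method": method.value, "statistic": None, "p_value": None,
            "p_formatted": None, "odds_ratio": None, "ci_low": None,
            "ci_high": None, "flags": "",
        }
        try:
            frame = frames[unit]
        except KeyError:
            row["flags"] = f"unknown_unit:{unit}"
            rows.append(row)
            continue
        try:
            if method is TestMethod.LOGISTIC:
                res = bivariable_logistic(
                    frame[outcome].astype(bool).to_numpy(),
                    frame[exposure].astype(bool).to_numpy(),
                    alpha=alpha,
                )
            else:
                tab = build_table(frame, exposure, outcome)
                if method is TestMethod.CHI2_PEARSON:
                    try:
                        res = chi2_pearson(tab)
                    except DegenerateTableError:
                        res = fisher_exact(tab)
                        row["flags"] = "degenerate_chi2_fell_back_to_fisher"
                else:
                    res = fisher_exact(tab)
        except ValidationError as exc:
            row["flags"] = f"error:{exc}"
            rows.append(row)
            continue
        row.update(
            method=res.method.value,
            statistic=res.statistic,
            p_value=res.p_value,
            p_formatted=format_p(res.p_value),
            odds_ratio=res.odds_ratio,
            ci_low=res.or_ci[0] if res.or_ci else None,
            ci_high=res.or_ci[1] if res.or_ci else None,
        )
        if not res.estimable:
            row["flags"] = ";".join(filter(None, [row["flags"], *res.flags]))
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["exposure", "outcome", "unit", "method", "statistic", "p_value",
                 "p_formatted", "odds_ratio", "ci_low", "ci_high", "flags"],
    )
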