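"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a hospital cohort of seriously ill adults with a
50%-or-higher predicted 6-month mortality risk: admissions stratified
across two risk strata, a minority dying during follow-up, documented
goals-of-care (GOC) discussions arriving at heavy-tailed intervals, and
paired blinded reviewer assessments of the care received during each
epoch. Defaults are calibrated to the published cohort's marginal
statistics (category mix, discussion frequency, epoch durations, reviewer
agreement); they are not a reconstruction of any patient-level data.

Each patient draws from an independent substream keyed by (seed, patient
index), so enlarging the cohort never perturbs earlier patients' draws.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort import (
    CATEGORY_ORDER,
    AdmittingService,
    CareAssessment,
    CategoryLabel,
    CohortBundle,
    DiscussionSetting,
    GOCDiscussion,
    Patient,
    RiskStratum,
    ValidationError,
)
from .epochs import Epoch, FollowupWindow, build_epochs
from .reliability import reconcile_all

__all__ = ["SimConfig", "SimulatedCohort", "simulate_cohort", "recovery_report",
           "analytic_agreement", "analytic_kappa"]

_REVIEWER_POOL = ("R1", "R2", "R3", "R4")


def _default_confusion() -> np.ndarray:
    # diagonal 0.975 -> expected raw agreement ~= 0.951 for any label mix
    m = np.full((4, 4), 0.025 / 3)
    np.fill_diagonal(m, 0.975)
    return m


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; every default is a cohort-level calibration.

    Probability vectors are ordered (comfort, function, life_extension,
    unclear). ``concordance_coupling`` is the probability that the true
    care label copies a *clear* governing goals label; otherwise the care
    label is drawn from ``care_category_probs``.
    """

    n_patients: int = 109
    seed: int = 0
    p_very_high_risk: float = 0.5
    p_any_discussion: float = 0.76
    p_baseline_discussion: float = 0.45
    p_death: float = 0.46
    p_medical_service: float = 0.83
    p_palliative_consult: float = 0.39
    covariate_probs: dict = field(default_factory=lambda: {
        "metastatic_cancer": 0.46,
        "cardiac_disease": 0.70,
        "chronic_kidney_disease": 0.39,
    })
    # shifted negative binomial: discussions-per-discussing-patient = 1 + NB(r, p)
    discussion_count_r: float = 3.0
    discussion_count_p: float = 0.30
    # log-normal inter-discussion gap, days
    gap_log_median_days: float = 7.0
    gap_log_sigma: float = 3.0
    # truncated log-normal death time, days from admission
    death_log_median_days: float = 45.0
    death_log_sigma: float = 1.0
    goc_category_probs: tuple = (0.18, 0.30, 0.39, 0.13)
    care_category_probs: tuple = (0.18, 0.32, 0.46, 0.04)
    reviewer_confusion: np.ndarray = field(default_factory=_default_confusion)
    confidence_probs: tuple = (0.03, 0.07, 0.25, 0.40, 0.25)
    concordance_coupling: float = 0.55
    p_consensus_reached: float = 0.9
    confidence_error_coupling: bool = False
    window: FollowupWindow = field(default_factory=FollowupWindow)
    start_date: dt.date = dt.date(2019, 4, 1)
    enrollment_span_days: int = 120

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be positive")
        for name in ("p_very_high_risk", "p_any_discussion", "p_baseline_discussion",
                     "p_death", "p_medical_service", "p_palliative_consult",
                     "concordance_coupling", "p_consensus_reached"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")
        for name in ("goc_category_probs", "care_category_probs", "confidence_probs"):
            v = np.asarray(getattr(self, name), dtype=float)
            if abs(v.sum() - 1.0) > 1e-9 or (v < 0).any():
                raise ValidationError(f"{name} must be a probability vector summing to 1")
        m = np.asarray(self.reviewer_confusion, dtype=float)
        if m.shape != (4, 4) or (m < 0).any() or np.abs(m.sum(axis=1) - 1).max() > 1e-9:
            raise ValidationError("reviewer_confusion must be 4x4 row-stochastic")


@dataclass
class SimulatedCohort:
    """Generated bundle plus the ground truth the pipeline never sees."""

    bundle: CohortBundle
    epochs_by_patient: dict[str, list[Epoch]]
    truth: pd.DataFrame          # patient_id, epoch_index, goc_category, true_care
    resolutions: dict            # (patient_id, epoch_index) -> consensus/adjudicator
    config: SimConfig


def _trunc_lognormal(rng, median: float, sigma: float, upper: float) -> float:
    """Inverse-CDF draw from log-normal(log median, sigma) truncated to (0, upper]."""
    mu = np.log(median)
    cap = norm.cdf((np.log(upper) - mu) / sigma)
    u = rng.uniform(0, cap)
    return float(np.exp(norm.ppf(u) * sigma + mu))


def _draw_category(rng, probs) -> CategoryLabel:
    return CATEGORY_ORDER[int(rng.choice(4, p=np.asarray(probs, dtype=float)))]


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full cohort bundle deterministically from ``config.seed``."""
    config.validate()
    window = config.window
    patients: dict[str, Patient] = {}
    discussions: dict[str, list[GOCDiscussion]] = {}
    assessments: dict[str, list[CareAssessment]] = {}
    epochs_by_patient: dict[str, list[Epoch]] = {}
    truth_rows = []
    resolutions: dict = {}
    confusion = np.asarray(config.reviewer_confusion, dtype=float)
    care_probs = np.asarray(config.care_category_probs, dtype=float)
    cat_index = {lab: i for i, lab in enumerate(CATEGORY_ORDER)}
    width = len(str(config.n_patients - 1))

    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        pid = f"P{i:0{width}d}"
        admission = config.start_date + dt.timedelta(
            days=int(rng.integers(0, config.enrollment_span_days + 1))
        )
        stratum = (RiskStratum.VERY_HIGH_GE_75
                   if rng.random() < config.p_very_high_risk
                   else RiskStratum.HIGH_50_74)
        service = (AdmittingService.MEDICAL
                   if rng.random() < config.p_medical_service
                   else AdmittingService.SURGICAL)
        pall = bool(rng.random() < config.p_palliative_consult)
        covs = {k: bool(rng.random() < p) for k, p in config.covariate_probs.items()}

        death_date = None
        if rng.random() < config.p_death:
            day = max(1, int(np.ceil(_trunc_lognormal(
                rng, config.death_log_median_days, config.death_log_sigma,
                window.followup_days,
            ))))
            death_date = admission + dt.timedelta(days=min(day, window.followup_days - 1))

        plist: list[GOCDiscussion] = []
        if rng.random() < config.p_baseline_discussion:
            back = int(rng.integers(1, window.baseline_lookback_days + 1))
            plist.append(GOCDiscussion(
                patient_id=pid,
                discussion_date=admission - dt.timedelta(days=back),
                category=_draw_category(rng, config.goc_category_probs),
                setting=DiscussionSetting.PREHOSPITAL,
            ))
        horizon_days = (min(
            admission + dt.timedelta(days=window.followup_days),
            death_date + dt.timedelta(days=1) if death_date else dt.date.max,
        ) - admission).days
        if rng.random() < config.p_any_discussion:
            count = 1 + int(rng.negative_binomial(config.discussion_count_r,
                                                  config.discussion_count_p))
            day = 0.0
            for _ in range(count):
                gap = max(1.0, _trunc_lognormal(
                    rng, config.gap_log_median_days, config.gap_log_sigma,
                    upper=4 * window.followup_days,
                ))
                day += gap
                if day >= horizon_days:
                    break
                plist.append(GOCDiscussion(
                    patient_id=pid,
                    discussion_date=admission + dt.timedelta(days=int(np.floor(day))),
                    category=_draw_category(rng, config.goc_category_probs),
                    setting=DiscussionSetting.INDEX_ADMISSION,
                ))
        plist.sort(key=lambda d: d.discussion_date)

        patient = Patient(
            patient_id=pid,
            admission_date=admission,
            death_date=death_date,
            mortality_risk_stratum=stratum,
            admitting_service=service,
            palliative_consult=pall,
            covariates=covs,
        )
        eps = build_epochs(patient, plist, window)

        pair = sorted(rng.choice(len(_REVIEWER_POOL), size=2, replace=False))
        rev_a, rev_b = _REVIEWER_POOL[pair[0]], _REVIEWER_POOL[pair[1]]

        alist: list[CareAssessment] = []
        for e in eps:
            goc = e.goc_category
            if goc.is_clear and rng.random() < config.concordance_coupling:
                true_care = goc
            else:
                true_care = _draw_category(rng, care_probs)
            truth_rows.append({
                "patient_id": pid,
                "epoch_index": e.epoch_index,
                "goc_category": goc.value,
                "goc_source": e.goc_source.value,
                "true_care": true_care.value,
            })
            row = confusion[cat_index[true_care]]
            obs = []
            for rev in (rev_a, rev_b):
                lab = CATEGORY_ORDER[int(rng.choice(4, p=row))]
                if config.confidence_error_coupling and lab != true_care:
                    conf = int(rng.integers(1, 3))  # errors come with low confidence
                else:
                    conf = 1 + int(rng.choice(5, p=np.asarray(config.confidence_probs)))
                obs.append(lab)
                alist.append(CareAssessment(
                    patient_id=pid, epoch_index=e.epoch_index, reviewer_id=rev,
                    category=lab, confidence=conf,
                ))
            if obs[0] != obs[1]:
                if rng.random() < config.p_consensus_reached:
                    resolutions[(pid, e.epoch_index)] = {"consensus": true_care,
                                                         "adjudicator": None}
                else:
                    resolutions[(pid, e.epoch_index)] = {"consensus": None,
                                                         "adjudicator": true_care}

        patients[pid] = patient
        discussions[pid] = plist
        assessments[pid] = alist
        epochs_by_patient[pid] = eps

    bundle = CohortBundle(patients=patients, discussions=discussions,
                          assessments=assessments)
    truth = pd.DataFrame(truth_rows, columns=["patient_id", "epoch_index",
                                              "goc_category", "goc_source", "true_care"])
    return SimulatedCohort(bundle=bundle, epochs_by_patient=epochs_by_patient,
                           truth=truth, resolutions=resolutions, config=config)


# ---------------------------------------------------------------------------
# Analytic expectations implied by the generating process


def analytic_agreement(confusion: np.ndarray, true_mix: np.ndarray) -> float:
    """Expected raw agreement of two independent reviewers: sum_c pi_c sum_k M[c,k]^2."""
    m = np.asarray(confusion, dtype=float)
    pi = np.asarray(true_mix, dtype=float)
    return float(pi @ (m ** 2).sum(axis=1))


def analytic_kappa(confusion: np.ndarray, true_mix: np.ndarray) -> float:
    """Kappa of the population confusion table P(i,j) = sum_c pi_c M[c,i] M[c,j]."""
    m = np.asarray(confusion, dtype=float)
    pi = np.asarray(true_mix, dtype=float)
    joint = np.einsum("c,ci,cj->ij", pi, m, m)
    p_o = np.trace(joint)
    marg = joint.sum(axis=0)  # symmetric: row and column marginals coincide
    p_e = float(marg @ marg)
    return float((p_o - p_e) / (1 - p_e))


def _expected_care_mix(sim: SimulatedCohort) -> np.ndarray:
    """Per-category expected true-care mix given the realized epoch goals."""
    cfg = sim.config
    care = np.asarray(cfg.care_category_probs, dtype=float)
    probs = np.zeros(4)
    n = len(sim.truth)
    idx = {lab.value: i for i, lab in enumerate(CATEGORY_ORDER)}
    for goc in sim.truth["goc_category"]:
        if goc != CategoryLabel.UNCLEAR.value:
            row = (1 - cfg.concordance_coupling) * care
            row = row.copy()
            row[idx[goc]] += cfg.concordance_coupling
        else:
            row = care
        probs += row
    return probs / n


def recovery_report(config: SimConfig, n_replicates: int = 1) -> pd.DataFrame:
    """Simulate, run the measurement pipeline, and compare realized summary
    statistics against their configured/analytic expectations.

    One row per (replicate, statistic): realized value, expected value, the
    Monte-Carlo standard error of the realized value, and the z-score.
    """
    from .reliability import cohen_kappa, confusion_matrix

    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    rows = []
    for rep in range(n_replicates):
        cfg = replace(config, seed=config.seed + rep)
        sim = simulate_cohort(cfg)
        truth = sim.truth
        n_ep = len(truth)
        realized_mix = (
            truth["true_care"].value_counts(normalize=True)
            .reindex([l.value for l in CATEGORY_ORDER]).fillna(0.0).to_numpy()
        )
        expected_mix = _expected_care_mix(sim)
        for lab, real, exp in zip(CATEGORY_ORDER, realized_mix, expected_mix):
            se = float(np.sqrt(max(exp * (1 - exp), 1e-12) / n_ep))
            rows.append({"replicate": rep, "statistic": f"care_mix_{lab.value}",
                         "realized": float(real), "expected": float(exp),
                         "mc_se": se, "z": (real - exp) / se})

        kr = cohen_kappa(confusion_matrix(sim.bundle.all_assessments()))
        exp_agree = analytic_agreement(cfg.reviewer_confusion, realized_mix)
        se_agree = float(np.sqrt(exp_agree * (1 - exp_agree) / n_ep))
        rows.append({"replicate": rep, "statistic": "percent_agreement",
                     "realized": kr.percent_agreement, "expected": exp_agree,
                     "mc_se": se_agree,
                     "z": (kr.percent_agreement - exp_agree) / se_agree})
        exp_kappa = analytic_kappa(cfg.reviewer_confusion, realized_mix)
        se_kappa = max(kr.se, 1e-12)
        rows.append({"replicate": rep, "statistic": "kappa",
                     "realized": kr.kappa, "expected": exp_kappa,
                     "mc_se": se_kappa, "z": (kr.kappa - exp_kappa) / se_kappa})

        n_per_patient = truth.groupby("patient_id")["epoch_index"].size()
        rows.append({"replicate": rep, "statistic": "median_epochs_per_patient",
                     "realized": float(n_per_patient.median()), "expected": 3.0,
                     "mc_se": float("nan"), "z": float("nan")})
    return pd.DataFrame(rows)
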