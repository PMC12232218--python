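"""Model/Results interface for the goal-concordant-care measurement pipeline.

:class:`GCCStudy` wraps a validated cohort bundle (patients, goals-of-care
discussions, paired care-received assessments) together with the follow-up
window configuration; :meth:`GCCStudy.fit` runs the full measurement
pipeline — epoch construction, reviewer reconciliation, concordance
classification, patient and cohort aggregation — and returns a
:class:`GCCResults` carrying every derived table plus reliability
statistics, association tests, a text ``summary()`` and the longitudinal
tile plot.

Example
-------
>>> from gccm import SimConfig, simulate_cohort, GCCStudy
>>> sim = simulate_cohort(SimConfig(n_patients=50, seed=7))
>>> res = GCCStudy.from_simulation(sim).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import CohortBundle, load_cohort
from .concordance import (
    ConcordanceRecord,
    classify_cohort,
    records_to_frame,
    uncertainty_breakdown,
)
from .epochs import Epoch, FollowupWindow, build_cohort_epochs, epochs_to_frame
from .metrics import (
    PatientSummary,
    cohort_summary,
    summaries_to_frame,
    summarize_cohort_patients,
    transition_summary,
)
from .reliability import (
    FinalCareCall,
    KappaResult,
    cohen_kappa,
    confusion_matrix,
    final_calls_to_frame,
    kappa_by_confidence,
    reconcile_all,
)
from .stats import run_prespecified_associations

__all__ = ["GCCStudy", "GCCResults", "DEFAULT_ASSOCIATIONS"]

#: Prespecified bivariable associations mirroring the published analysis plan.
DEFAULT_ASSOCIATIONS = [
    {"exposure": "palliative_consult", "outcome": "high_gcc",
     "unit": "patient", "method": "chi2_pearson"},
    {"exposure": "metastatic_cancer", "outcome": "high_gcc",
     "unit": "patient", "method": "chi2_pearson"},
    {"exposure": "very_high_risk", "outcome": "has_any_discussion",
     "unit": "patient", "method": "chi2_pearson"},
    {"exposure": "medical_service", "outcome": "has_any_discussion",
     "unit": "patient", "method": "chi2_pearson"},
    {"exposure": "palliative_consult", "outcome": "any_uncertain",
     "unit": "patient", "method": "chi2_pearson"},
    {"exposure": "metastatic_cancer", "outcome": "any_uncertain",
     "unit": "patient", "method": "chi2_pearson"},
    {"exposure": "medical_service", "outcome": "any_discordant",
     "unit": "patient", "method": "fisher_exact"},
    {"exposure": "palliative_consult", "outcome": "high_gcc",
     "unit": "patient", "method": "logistic"},
]


class GCCStudy:
    """Goal-concordant-care measurement model over one cohort."""

    def __init__(
        self,
        bundle: CohortBundle,
        window: FollowupWindow = FollowupWindow(),
        censor_at_ltfu: bool = False,
        resolutions: Optional[dict] = None,
    ) -> None:
        self.bundle = bundle
        self.window = window
        self.censor_at_ltfu = censor_at_ltfu
        self.resolutions = resolutions or {}

    @classmethod
    def from_files(
        cls,
        patients_path: Union[str, Path],
        discussions_path: Union[str, Path],
        assessments_path: Union[str, Path],
        window: FollowupWindow = FollowupWindow(),
        censor_at_ltfu: bool = False,
        resolutions: Optional[dict] = None,
    ) -> "GCCStudy":
        bundle = load_cohort(patients_path, discussions_path, assessments_path)
        return cls(bundle, window=window, censor_at_ltfu=censor_at_ltfu,
                   resolutions=resolutions)

    @classmethod
    def from_simulation(cls, sim, **kw) -> "GCCStudy":
        """Build from a :class:`gccm.simulate.SimulatedCohort`."""
        return cls(sim.bundle, window=sim.config.window,
                   resolutions=sim.resolutions, **kw)

    def fit(self, associations: Optional[Sequence[dict]] = None,
            alpha: float = 0.05) -> "GCCResults":
        epochs_by_patient = build_cohort_epochs(
            self.bundle.patients.values(), self.bundle.discussions,
            self.window, self.censor_at_ltfu,
        )
        all_assess = self.bundle.all_assessments()
        final_calls = reconcile_all(all_assess, self.resolutions)
        all_epochs = [e for pid in self.bundle.patients
                      for e in epochs_by_patient[pid]]
        records = classify_cohort(all_epochs, final_calls)
        summaries = summarize_cohort_patients(
            self.bundle.patients.values(), epochs_by_patient, records)
        reliability = cohen_kappa(confusion_matrix(all_assess), alpha=alpha)
        by_conf = kappa_by_confidence(all_assess, alpha=alpha)

        res = GCCResults(
            study=self,
            epochs_by_patient=epochs_by_patient,
            final_calls=final_calls,
            records=records,
            summaries=summaries,
            reliability=reliability,
            reliability_by_confidence=by_conf,
            cohort=cohort_summary(summaries, epochs_by_patient),
            transitions=transition_summary(records),
        )
        if associations is None:
            associations = DEFAULT_ASSOCIATIONS
        if associations:
            res.associations = run_prespecified_associations(
                {"patient": res.patient_frame()}, associations, alpha=alpha)
        return res


@dataclass
class GCCResults:
    """Fitted pipeline outputs; every attribute is a plain table or dict."""

    study: GCCStudy
    epochs_by_patient: dict[str, list[Epoch]]
    final_calls: list[FinalCareCall]
    records: list[ConcordanceRecord]
    summaries: list[PatientSummary]
    reliability: KappaResult
    reliability_by_confidence: dict
    cohort: dict
    transitions: dict
    associations: pd.DataFrame = field(default_factory=pd.DataFrame)

    # -- tidy frames -------------------------------------------------------
    def epochs_frame(self) -> pd.DataFrame:
        return epochs_to_frame(
            e for pid in self.study.bundle.patients
            for e in self.epochs_by_patient[pid]
        )

    def final_calls_frame(self) -> pd.DataFrame:
        return final_calls_to_frame(self.final_calls)

    def records_frame(self) -> pd.DataFrame:
        return records_to_frame(self.records)

    def summaries_frame(self) -> pd.DataFrame:
        return summaries_to_frame(self.summaries)

    def uncertainty_frame(self) -> pd.DataFrame:
        return uncertainty_breakdown(self.records)

    def patient_frame(self) -> pd.DataFrame:
        """Patient-level analysis frame: outcomes joined to baseline covariates."""
        from .cohort import AdmittingService, RiskStratum

        sdf = summaries_to_frame(self.summaries).set_index("patient_id")
        rows = []
        for pid, p in self.study.bundle.patients.items():
            row = {
                "patient_id": pid,
                "very_high_risk": p.mortality_risk_stratum is RiskStratum.VERY_HIGH_GE_75,
                "medical_service": p.admitting_service is AdmittingService.MEDICAL,
                "palliative_consult": p.palliative_consult,
            }
            for k, v in p.covariates.items():
                row[k] = v
            rows.append(row)
        pdf = pd.DataFrame(rows).set_index("patient_id")
        return pdf.join(sdf).reset_index()

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        c = self.cohort
        k = self.reliability
        tot = c["epoch_totals"]
        n_ep = c["n_epochs"]
        lines = [
            "Goal-concordant care measurement",
            "=" * 48,
            f"Patients: {c['n_patients']}   Epochs: {n_ep}",
            (f"Epochs/patient median (IQR): {c['epochs_per_patient']['median']:.0f} "
             f"({c['epochs_per_patient']['q1']:.0f}-{c['epochs_per_patient']['q3']:.0f})"),
            (f"Interrater agreement: {k.percent_agreement:.1%}  "
             f"kappa {k.kappa:.2f} (95% CI {k.ci_low:.2f}-{k.ci_high:.2f})"),
            "",
            "Epoch-level concordance:",
            f"  concordant {tot['concordant']} ({tot['concordant'] / n_ep:.0%})",
            f"  discordant {tot['discordant']} ({tot['discordant'] / n_ep:.0%})",
            f"  uncertain  {tot['uncertain']} ({tot['uncertain'] / n_ep:.0%})",
            "",
            (f"High rate of GCC (>=75% of epochs): {c['high_gcc']['count']} "
             f"({c['high_gcc']['proportion']:.0%}) patients"),
            (f"Any goal-discordant epoch: {c['any_discordant']['count']} "
             f"({c['any_discordant']['proportion']:.0%}) patients"),
            (f"Variable concordance over time: {c['variable_concordance']['count']} "
             f"({c['variable_concordance']['proportion']:.0%}) patients"),
        ]
        dec = c["at_death"]
        if dec["n_decedents"]:
            conc = dec["counts"]["concordant"]
            lines.append(
                f"Concordant at time of death: {conc}/{dec['n_decedents']} "
                f"({conc / dec['n_decedents']:.0%}) decedents"
            )
        if not self.associations.empty:
            lines += ["", "Prespecified associations (alpha=0.05, unadjusted):"]
            for _, r in self.associations.iterrows():
                stat = f" stat={r['statistic']:.2f}" if pd.notna(r["statistic"]) else ""
                lines.append(
                    f"  {r['exposure']} ~ {r['outcome']} [{r['method']}]"
                    f"{stat} p={r['p_formatted']}"
                )
            lines.append("  (no multiple-testing adjustment; per-test alpha)")
        return "\n".join(lines)

    def tile_plot(self, out_path=None, color_by: str = "concordance", **kw):
        from .plotting import tile_plot

        return tile_plot(
            self.records, self.epochs_by_patient,
            self.study.bundle, out_path=out_path, color_by=color_by,
            final_calls=self.final_calls, **kw,
        )
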