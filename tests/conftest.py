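import datetime as dt

import pytest

from gccm.cohort import (
    AdmittingService,
    CareAssessment,
    CategoryLabel,
    DiscussionSetting,
    GOCDiscussion,
    Patient,
    RiskStratum,
)

ADMISSION = dt.date(2019, 4, 1)


def make_patient(pid="P1", admission=ADMISSION, death=None, **kw):
    return Patient(
        patient_id=pid,
        admission_date=admission,
        death_date=death,
        mortality_risk_stratum=kw.pop("stratum", RiskStratum.HIGH_50_74),
        admitting_service=kw.pop("service", AdmittingService.MEDICAL),
        palliative_consult=kw.pop("palliative_consult", False),
        covariates=kw.pop("covariates", {}),
        **kw,
    )


def make_discussion(pid="P1", day_offset=0, category=CategoryLabel.LIFE_EXTENSION,
                    admission=ADMISSION):
    date = admission + dt.timedelta(days=day_offset)
    setting = (DiscussionSetting.PREHOSPITAL if day_offset < 0
               else DiscussionSetting.INDEX_ADMISSION)
    return GOCDiscussion(patient_id=pid, discussion_date=date,
                         category=category, setting=setting)


def make_assessment(pid="P1", epoch=0, reviewer="R1",
                    category=CategoryLabel.COMFORT, confidence=4):
    return CareAssessment(patient_id=pid, epoch_index=epoch, reviewer_id=reviewer,
                          category=category, confidence=confidence)


@pytest.fixture
def patient():
    return make_patient()


@pytest.fixture(scope="session")
def small_sim():
    """Seeded 80-patient synthetic cohort shared across tests."""
    from gccm.simulate import SimConfig, simulate_cohort

    return simulate_cohort(SimConfig(n_patients=80, seed=11))
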