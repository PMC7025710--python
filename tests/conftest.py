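import numpy as np
import pytest

from gada_discrim.cohort_model import Cohort, Gender, Group, PatientRecord
from gada_discrim.synthetic_cohort import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Synthetic cohort at the published group sizes (152 / 358), seed 0."""
    return generate_cohort(default_config(seed=0))


def make_record(group=Group.GADA_POS, **overrides) -> PatientRecord:
    base = dict(
        group=group,
        gender=Gender.F,
        age_onset=40.0,
        bmi=24.0,
        total_chol=190.0,
        tg=120.0,
        hdl=50.0,
        hba1c=9.0,
        gpt=30.0,
        creatinine=0.8,
        smoking=False,
        statin=False,
        fibrate=False,
    )
    base.update(overrides)
    return PatientRecord(**base)


@pytest.fixture()
def tiny_balanced_cohort():
    """Hand-built 8-record cohort with within-group variation in every field."""
    rng = np.random.default_rng(42)
    records = []
    for group in (Group.GADA_POS, Group.T2DM):
        for i in range(4):
            records.append(
                make_record(
                    group=group,
                    gender=Gender.M if i % 2 else Gender.F,
                    age_onset=30.0 + 5 * i + (2 if group is Group.T2DM else 0),
                    bmi=21.0 + i + rng.uniform(0, 0.5),
                    tg=90.0 + 10 * i,
                    hba1c=8.0 + 0.5 * i,
                    hdl=45.0 + i,
                    smoking=i == 0,
                    statin=i == 1,
                    fibrate=i == 2,
                )
            )
    return Cohort(records=records, provenance="fixture")
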