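import numpy as np
import pytest

from milsurv.cohort import PatientRecord, SurvivalLabel
from milsurv.encoding import InstanceFeature, PatientBag


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_cohort(composition):
    """Cohort from [(n_patients, n_cores), ...], deterministic labels."""
    records = []
    i = 0
    for n_patients, n_cores in composition:
        for _ in range(n_patients):
            records.append(
                PatientRecord(
                    patient_id=f"P{i:04d}",
                    core_ids=tuple(f"P{i:04d}_c{j}" for j in range(n_cores)),
                    label=SurvivalLabel(time=1.0 + 0.01 * i, event=i % 2),
                )
            )
            i += 1
    return records


def make_bag(n_instances, d=8, pid="P0", time=1.0, event=1, seed=0):
    r = np.random.default_rng(seed)
    return PatientBag(
        patient_id=pid,
        instances=tuple(
            InstanceFeature(vector=r.standard_normal(d), source=(f"{pid}_core", 0, j))
            for j in range(n_instances)
        ),
        label=SurvivalLabel(time=time, event=event),
    )


@pytest.fixture
def published_cohort():
    """The published composition: 236 x 3 cores, 7 x 2 cores, 1 x 1 core."""
    return make_cohort([(236, 3), (7, 2), (1, 1)])
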