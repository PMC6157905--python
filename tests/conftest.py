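import numpy as np
import pytest

from cogtraj.cohort import Cohort, SubjectRecord, VisitRecord, default_roi_names
from cogtraj.simulate import (
    SimulationConfig,
    TrajectoryClassSpec,
    mmse_two_class_spec,
    simulate_cohort,
)


def make_subject(sid="S1", months=(0, 6, 12, 24), mmse=None, adas13=None,
                 ct=None, apoe4=0, age=72.0, sex="M", dx="MCI", cohort="T"):
    """Hand-build a subject; per-visit score lists may contain None."""
    visits = []
    for i, m in enumerate(months):
        visits.append(VisitRecord(
            month=m,
            mmse=None if mmse is None else mmse[i],
            adas13=None if adas13 is None else adas13[i],
            ct=None if ct is None or ct[i] is None else np.asarray(ct[i], dtype=float),
        ))
    return SubjectRecord(subject_id=sid, age=age, sex=sex, apoe4=apoe4,
                         diagnosis=dx, cohort=cohort, visits=visits)


@pytest.fixture
def toy_cohort():
    """Two subjects, three visits each, tiny 3-ROI atlas."""
    ct = [[2.5, 2.4, 2.6]] * 3
    s1 = make_subject("A", months=(0, 6, 18), mmse=[29, 28, 27], ct=ct)
    s2 = make_subject("B", months=(0, 12, 24), mmse=[28, 25, 20], apoe4=1, sex="F")
    return Cohort(subjects=[s1, s2], roi_names=default_roi_names(3))


@pytest.fixture(scope="session")
def noisy_mmse_cohort():
    """Moderate-noise two-class MMSE cohort with missingness, shared by tests."""
    cfg = SimulationConfig(
        n_subjects=150, class_spec=mmse_two_class_spec(), scale="mmse",
        visit_missing_prob=0.2, ct_missing_prob=0.1, seed=42,
    )
    cohort, truth = simulate_cohort(cfg)
    return cfg, cohort, truth


def zero_noise_spec(label, proportion, start, end, shape="linear", **kw):
    return TrajectoryClassSpec(
        label=label, proportion=proportion, shape=shape,
        score_start=start, score_end=end,
        score_noise_sd=0.0, ct_noise_sd=0.0, ct_baseline_sd=0.0, **kw,
    )
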