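import numpy as np
import pandas as pd
import pytest

from opiscore.opi import extract_opis
from opiscore.scoring import fit_expert_norms, score_cohort
from opiscore.synth import make_reference_cohort


@pytest.fixture(scope="session")
def reference_cohort():
    return make_reference_cohort(seed=7)


@pytest.fixture(scope="session")
def cohort_opis(reference_cohort):
    trainee = {
        r.subject_id: extract_opis(r.stream, r.events) for r in reference_cohort.trainees
    }
    expert = {
        r.subject_id: extract_opis(r.stream, r.events) for r in reference_cohort.experts
    }
    return trainee, expert


@pytest.fixture(scope="session")
def cohort_matrix(reference_cohort, cohort_opis):
    trainee, expert = cohort_opis
    norms = fit_expert_norms(list(expert.values()))
    opis = pd.DataFrame({sid: v.as_dict() for sid, v in trainee.items()}).T
    opis.index.name = "subject_id"
    video = {r.subject_id: r.video for r in reference_cohort.trainees}
    groups = {r.subject_id: r.group for r in reference_cohort.trainees}
    return score_cohort(opis, video, norms, group=groups)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
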