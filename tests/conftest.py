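import numpy as np
import pytest

from micclust.cohort import PairedCohort, default_patient_ids


def make_cohort(n=5, m=10, seed=0, chromosome_id="chrT"):
    rng = np.random.default_rng(seed)
    return PairedCohort(
        chromosome_id=chromosome_id,
        patient_ids=default_patient_ids(n),
        loci=list(range(1, m + 1)),
        cancer_cn=2.0 + 0.3 * rng.standard_normal((n, m)),
        blood_cn=2.0 + 0.3 * rng.standard_normal((n, m)),
    )


@pytest.fixture
def cohort():
    return make_cohort()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
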