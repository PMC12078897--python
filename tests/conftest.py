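import logging

import numpy as np
import pytest

from habitatmri.features import FeatureConfig
from habitatmri.synthetic import CohortConfig, generate_cohort

logging.getLogger("habitatmri").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Eight clean patients (default study conditions, fixed seed)."""
    return generate_cohort(CohortConfig(n_patients=8, seed=11))


@pytest.fixture(scope="session")
def one_patient(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def fast_config():
    return FeatureConfig.original_only()


@pytest.fixture(scope="session")
def demo_study():
    """One shared end-to-end study (n=60, reduced filter bank, K=2)."""
    from habitatmri.pipeline import run_study

    cfg = CohortConfig(n_patients=60, seed=21)
    cohort, features, records, result, k = run_study(
        cfg, FeatureConfig.original_only(), k=2, seed=21
    )
    return {
        "cohort": cohort,
        "features": features,
        "records": records,
        "result": result,
        "k": k,
        "labels": records["grade"].to_numpy(dtype=int),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
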