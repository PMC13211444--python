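import numpy as np
import pytest

from pcrfusion import CohortSpec, PhantomSpec, generate_cohort
from pcrfusion.preprocessing import ClinicalEncoder, VolumeNormalizer


@pytest.fixture(scope="session")
def small_cohort():
    """A 60-patient phantom cohort shared by the fast tests."""
    volumes, clinical, labels, truth = generate_cohort(
        CohortSpec(n=60, seed=7), PhantomSpec()
    )
    return {"volumes": volumes, "clinical": clinical, "labels": labels,
            "truth": truth}


@pytest.fixture(scope="session")
def encoded_cohort(small_cohort):
    """The same cohort with volumes normalized and the table encoded."""
    encoder = ClinicalEncoder().fit(small_cohort["clinical"])
    normalizer = VolumeNormalizer()
    X = {
        "image": normalizer.transform(small_cohort["volumes"]),
        "clinical": encoder.transform(small_cohort["clinical"]),
    }
    return X, small_cohort["labels"]


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
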