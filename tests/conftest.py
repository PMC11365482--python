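import numpy as np
import pandas as pd
import pytest

from linecross import build_cmatrix, study_pedigree

# The five-cohort reference coefficient table for the two-founder design
# (P1, P2, F2 = selfed F1, backcross to P1, reciprocal backcross to P2),
# on the parental +-1 scale.  Frozen from hand application of the
# theta/heterozygosity recursion and the maternal/cytotype lineage rules.
REFERENCE_CMATRIX = pd.DataFrame(
    [
        [1.0, 0.0, 1.0, 1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        [-1.0, 0.0, -1.0, -1.0, 0.0, 1.0, 0.0, 0.0, 1.0, 0.0],
        [0.0, 0.5, -1.0, 0.0, 1.0, 0.0, 0.0, 0.25, 0.0, -0.5],
        [0.5, 0.5, -1.0, 0.0, 1.0, 0.25, 0.25, 0.25, -0.5, -0.5],
        [-0.5, 0.5, -1.0, -1.0, 0.0, 0.25, -0.25, 0.25, 0.5, -0.5],
    ],
    index=pd.Index(["P1", "P2", "F2", "BC1", "rBC2"], name="cohort"),
    columns=["Aa", "Ad", "Ca", "Mea", "Med", "AaAa", "AaAd", "AdAd", "AaCa", "AdCa"],
)


@pytest.fixture(scope="session")
def study_cohorts():
    return study_pedigree()


@pytest.fixture(scope="session")
def study_cmatrix(study_cohorts):
    return build_cmatrix(list(study_cohorts.values()))


@pytest.fixture(scope="session")
def reference_cmatrix():
    return REFERENCE_CMATRIX.copy()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
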