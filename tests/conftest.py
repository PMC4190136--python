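import numpy as np
import pytest

from palliscore import Cohort, PatientRecord


@pytest.fixture
def tiny_cohort() -> Cohort:
    """Six courses covering events, censoring and a missing covariate."""
    return Cohort(
        [
            PatientRecord("a", 1.0, True, kps=90, steroids=False, liver_mets=False,
                          pleural_effusion=False, primary_site="prostate", bone_mets_only=True),
            PatientRecord("b", 2.0, True, kps=50, steroids=True, liver_mets=True,
                          pleural_effusion=False, primary_site="nsclc", bone_mets_only=False),
            PatientRecord("c", 3.0, False, kps=70, steroids=None, liver_mets=False,
                          pleural_effusion=False, primary_site="breast", bone_mets_only=True),
            PatientRecord("d", 4.0, True, kps=60, steroids=True, liver_mets=False,
                          pleural_effusion=True, primary_site="other", bone_mets_only=False),
            PatientRecord("e", 5.5, False, kps=100, steroids=False, liver_mets=False,
                          pleural_effusion=False, primary_site="prostate", bone_mets_only=True,
                          extra_covariates={"opioids": "yes"}),
            PatientRecord("f", 8.0, True, kps=80, steroids=False, liver_mets=True,
                          pleural_effusion=False, primary_site="kidney", bone_mets_only=False),
        ],
        provenance="fixture",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
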