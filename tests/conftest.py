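import numpy as np
import pytest

from desmopk import dataset_io as dio
from desmopk import synthetic_cohort as sc
from desmopk.kinetics import StructuralParams
from desmopk.popmodel import piglet_model


@pytest.fixture(scope="session")
def ref_model():
    """The published piglet population model (generating truth)."""
    return piglet_model()


@pytest.fixture(scope="session")
def typical_params():
    """Typical-value structural parameters (BW 10 kg subject)."""
    return StructuralParams(CL=395.0, V1=131.0, Q=32.0, V2=436.0,
                            Ka1=0.275, Ka2=0.399, Bio=0.86, Tlag=1.0, D1=0.16)


@pytest.fixture(scope="session")
def study():
    """One full synthetic study (32 piglets, LOQ-excluded) plus its truth."""
    return sc.generate_study(seed=20180131)


@pytest.fixture(scope="session")
def log_study(study):
    ds, _ = study
    return dio.log_transform(ds)


@pytest.fixture(scope="session")
def uncensored_study():
    """Same design without LOQ exclusion (every nominal sample retained)."""
    return sc.generate_study(design=sc.StudyDesign(censor="none"), seed=20180131)
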