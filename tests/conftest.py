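import pytest
from hypothesis import settings

from hepasafe import GeneratorConfig, PatientRecord, generate_cohort

settings.register_profile("repeatable", derandomize=True)
settings.load_profile("repeatable")


@pytest.fixture(scope="session")
def cohort52():
    """A labelled synthetic cohort at the study scale (n=52)."""
    return generate_cohort(GeneratorConfig(n=52, seed=7))


@pytest.fixture
def example_record():
    return PatientRecord(
        patient_id="P001", age=57.0, sex="male", weight=70.0, bmi=24.4,
        asa_class=2, htn=False, dm=False, hbv=True, hcv=False,
        alcoholism=False, diagnosis="HCC", wbc=6271.0, neutrophil=3852.0,
        plt=236.0, pt_inr=0.99, pt_pct=103.1, tb=0.78, albumin=4.1,
        ast=31.9, alt=26.2, cr=0.76, hs_crp=1.1, rt_volume=736.0,
        lt_volume=544.0, resected_volume=750.0, pod5_pt_pct=80.0,
        pod5_sb=20.0, phlf=False,
    )
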