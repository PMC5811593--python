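import numpy as np
import pytest

from iarisk import ClinicalRecord, GleasonInfo, ImagingRecord


@pytest.fixture
def low_risk_clinical():
    return ClinicalRecord(
        patient_id="p1",
        age_years=55,
        psa_ng_ml=5.0,
        gleason=GleasonInfo(3, 3),
        pct_positive_cores=20.0,
        clinical_t_stage="T1c",
    )


@pytest.fixture
def risk_increase_case():
    """Risk-increase worked example: CAPRA 2 (low), ADC 629, Likert 4."""
    clinical = ClinicalRecord(
        patient_id="case-up",
        age_years=62,
        psa_ng_ml=4.6,
        gleason=GleasonInfo(3, 4),
        pct_positive_cores=25.0,
        clinical_t_stage="T1c",
    )
    imaging = ImagingRecord(adc_value=629.0, repe_likert=4)
    return clinical, imaging


@pytest.fixture
def risk_decrease_case():
    """Risk-reduction worked example: CAPRA 6 (high), ADC 1006, Likert 3."""
    clinical = ClinicalRecord(
        patient_id="case-down",
        age_years=65,
        psa_ng_ml=9.8,
        gleason=GleasonInfo(4, 5),
        pct_positive_cores=90.0,
        clinical_t_stage="T1c",
    )
    imaging = ImagingRecord(adc_value=1006.0, repe_likert=3)
    return clinical, imaging


@pytest.fixture
def survival_data():
    """Simulated single-covariate PH data with beta = 0.7."""
    rng = np.random.default_rng(42)
    n = 400
    x = rng.normal(size=n)
    t = rng.exponential(np.exp(-0.7 * x))
    c = rng.exponential(2.0, size=n)
    return x, np.minimum(t, c), t <= c
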