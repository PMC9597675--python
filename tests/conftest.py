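import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

# Published per-cohort UTR haplotype counts (controls over 2N=420, patients
# over 2N=410), reused across the association and generator tests.
CONTROL_UTR_COUNTS = {
    "UTR-1": 144, "UTR-2": 107, "UTR-5": 67, "UTR-3": 34, "UTR-7": 28,
    "UTR-4": 26, "UTR-18": 7, "UTR-10": 5, "UTR-6": 2,
}
PATIENT_UTR_COUNTS = {
    "UTR-1": 165, "UTR-2": 105, "UTR-5": 35, "UTR-3": 30, "UTR-7": 25,
    "UTR-4": 35, "UTR-18": 0, "UTR-10": 5, "UTR-6": 10,
}


@pytest.fixture(scope="session")
def utr_tables():
    from utrld.haplotypes import CohortHaplotypeTable

    return (
        CohortHaplotypeTable("controls", 420, dict(CONTROL_UTR_COUNTS)),
        CohortHaplotypeTable("patients", 410, dict(PATIENT_UTR_COUNTS)),
    )


@pytest.fixture(scope="session")
def default_dataset():
    from utrld.synthetic import simulate

    return simulate(seed=1)
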