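from datetime import date

import pytest
from hypothesis import settings

import ctri_audit as ca

settings.register_profile("suite", derandomize=True, max_examples=200)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def worked_fixture():
    """Three ambiguous worked-example records plus one Indian and one multinational."""
    return ca.generate_worked_fixture()


@pytest.fixture(scope="session")
def zero_error_dataset():
    """n=1000 synthetic snapshot with every error rate at zero, plus truth."""
    cfg = ca.GeneratorConfig(n_records=1000, seed=20210).zero_error()
    records, truth = ca.generate(cfg)
    return records, truth


@pytest.fixture(scope="session")
def default_dataset():
    """n=1000 synthetic snapshot at default settings (errors injected)."""
    records, truth = ca.generate(ca.GeneratorConfig(n_records=1000, seed=11))
    return records, truth


@pytest.fixture
def consistent_multinational():
    """A minimal record every classifier pair agrees is multinational."""
    return ca.TrialRecord(
        ctri_number="CTRI/2016/03/999001",
        registration_date=date(2016, 3, 5),
        trial_type="Interventional",
        phase="Phase 3",
        total_sample_size=200,
        sample_size_india=50,
        recruitment_status_global="Completed",
        recruitment_status_india="Completed",
        first_enrollment_global=date(2016, 5, 1),
        first_enrollment_india=date(2016, 7, 1),
        completion_date_india=date(2018, 7, 1),
        completion_date_global=date(2018, 8, 1),
        final_enrollment_total=200,
        final_enrollment_india=60,
        estimated_duration=ca.Duration(2, 0, 0),
    )
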