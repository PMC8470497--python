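import pytest

import gbmtyper as gt


@pytest.fixture(scope="session")
def fixture_cohort():
    cohort, truth = gt.deterministic_fixture()
    return cohort, truth


@pytest.fixture(scope="session")
def fixture_calls(fixture_cohort):
    cohort, _ = fixture_cohort
    return gt.classify_cohort(cohort)


@pytest.fixture(scope="session")
def fixture_summary(fixture_cohort, fixture_calls):
    cohort, _ = fixture_cohort
    return gt.frequency_matrix(cohort, fixture_calls)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    d = tmp_path_factory.mktemp("fixture_cohort")
    gt.write_fixture(d)
    return d
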