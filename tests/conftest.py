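import pytest

from osteorisk.registry import apply_eligibility_filters, deduplicate
from osteorisk.synthetic import STUDY_WINDOW, make_district_fixture
from osteorisk.tableio import cases_from_frame


@pytest.fixture(scope="session")
def fixture_frame():
    frame, _ = make_district_fixture()
    return frame


@pytest.fixture(scope="session")
def fixture_population():
    _, pop = make_district_fixture()
    return pop


@pytest.fixture(scope="session")
def raw_cases(fixture_frame):
    return cases_from_frame(fixture_frame)


@pytest.fixture(scope="session")
def eligible_cases(raw_cases):
    kept, _ = apply_eligibility_filters(raw_cases, STUDY_WINDOW, min_age=40)
    kept, _ = deduplicate(kept)
    return kept
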