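import pytest

import etamu


@pytest.fixture(scope="session")
def battery():
    return etamu.default_battery()


@pytest.fixture(scope="session")
def worked_example():
    return etamu.load_example_session()


@pytest.fixture(scope="session")
def pilot_pre():
    return {s.subject_id: s for s in etamu.load_pilot_cohort("pre")}


@pytest.fixture(scope="session")
def pilot_post():
    return {s.subject_id: s for s in etamu.load_pilot_cohort("post")}


@pytest.fixture(scope="session")
def pilot_post_corrected():
    return {s.subject_id: s for s in etamu.load_pilot_cohort("post_corrected")}
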