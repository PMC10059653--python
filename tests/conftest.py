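import warnings

import pytest

from serj.pipeline import judge_session, preprocess_session
from serj.synth import make_subject_session

# selection emits benign constant-column warnings on small tables
warnings.filterwarnings("ignore", message="excluding .* constant")


@pytest.fixture(scope="session")
def default_session():
    """One canonical 12-window benchmark session (LANV-HANV-LAPV-HAPV cycle)."""
    return make_subject_session(seed=1)


@pytest.fixture(scope="session")
def default_clean(default_session):
    """The same session after the full preprocessing chain."""
    eda, ppg = preprocess_session(default_session.eda, default_session.ppg)
    return eda, ppg


@pytest.fixture(scope="session")
def default_decisions(default_session):
    return judge_session(default_session)
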