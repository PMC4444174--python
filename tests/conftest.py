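import pytest
from hypothesis import HealthCheck, settings

from movelead import datasets
from movelead.events import BehavioralEvent, EventLog
from movelead.segmentation import SegmentationParams

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bo():
    return datasets.BO


@pytest.fixture(scope="session")
def ad():
    return datasets.AD


@pytest.fixture(scope="session")
def bo_roster():
    return datasets.BO.roster


@pytest.fixture
def params():
    return SegmentationParams()


def make_log(events, group_id="BO", session_id="s1"):
    evs = tuple(sorted(events, key=lambda e: e.time_s))
    return EventLog(group_id=group_id, session_id=session_id, events=evs)


def dep(t, actor, kind="departure"):
    return BehavioralEvent(time_s=t, actor_id=actor, kind=kind)


@pytest.fixture
def simple_movement_log(bo_roster):
    """Six of twelve members depart in one tight cluster."""
    ids = bo_roster.ids[:6]
    events = [dep(100.0 + 30 * k, i, "departure" if k == 0 else "joining")
              for k, i in enumerate(ids)]
    return make_log(events)
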