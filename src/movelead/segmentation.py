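"""Segment event logs into collective-movement episodes.

A collective movement begins with the departure of the first moving
individual and ends when the last individual arrives; an episode only
qualifies when at least half the group (configurable) commits to it.
Followers' ``joining`` events are treated as their departures, which is
how recruitment (joining-process) duration is timed: last departure
minus first departure.

Operational choices the field protocol leaves open are parameters here:
how close two departures must be to count as simultaneous
(``simultaneity_window_s``), the pre-departure observation window, and
the quiet gaps that separate bouts within a movement and distinct
movements from each other.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from typing import Optional, Sequence

from .events import (
    PREDEPARTURE_KINDS,
    BehavioralEvent,
    CollectiveMovement,
    EventLog,
    Roster,
    ValidationError,
)

__all__ = [
    "SegmentationParams",
    "segment_movements",
    "detect_first_movers",
    "extract_predeparture_participants",
    "joining_duration",
    "front_at_midtravel",
    "count_bouts",
]

#: Event kinds that commit an individual to the movement.
_MOVER_KINDS = ("departure", "joining")


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable thresholds for movement segmentation.

    participation_fraction
        Minimum fraction of the group that must move for an episode to
        count as a collective movement (the 50% rule).
    simultaneity_window_s
        Departures within this many seconds of the earliest one are
        simultaneous first movers.
    predeparture_window_s
        Length of the pre-departure observation window (20 min).
    bout_gap_s
        Minimum quiet gap after a group pause before renewed departures
        open a new bout within the same movement.
    movement_gap_s
        Minimum gap between mover events that separates two distinct
        movements.
    """

    participation_fraction: float = 0.5
    simultaneity_window_s: float = 10.0
    predeparture_window_s: float = 1200.0
    bout_gap_s: float = 60.0
    movement_gap_s: float = 600.0

    def __post_init__(self) -> None:
        if not (0 < self.participation_fraction <= 1):
            raise ValidationError("participation_fraction must be in (0, 1]")
        if self.simultaneity_window_s < 0:
            raise ValidationError("simultaneity_window_s must be >= 0")
        if self.predeparture_window_s <= 0 or self.bout_gap_s <= 0 or self.movement_gap_s <= 0:
            raise ValidationError("window/gap parameters must be positive")
        if not (self.simultaneity_window_s < self.bout_gap_s < self.movement_gap_s):
            raise ValidationError(
                "expected simultaneity_window_s < bout_gap_s < movement_gap_s, got "
                f"{self.simultaneity_window_s} / {self.bout_gap_s} / {self.movement_gap_s}"
            )


def _mover_clusters(
    events: Sequence[BehavioralEvent], gap_s: float
) -> list[list[BehavioralEvent]]:
    """Maximal runs of mover events separated by >= gap_s of quiet."""
    clusters: list[list[BehavioralEvent]] = []
    for ev in events:
        if clusters and ev.time_s - clusters[-1][-1].time_s < gap_s:
            clusters[-1].append(ev)
        else:
            clusters.append([ev])
    return clusters


def _departures_of(
    movement: "CollectiveMovement | Sequence[tuple[str, float]]",
) -> Sequence[tuple[str, float]]:
    if isinstance(movement, CollectiveMovement):
        return movement.departures
    return movement


def detect_first_movers(
    movement: CollectiveMovement | Sequence[tuple[str, float]],
    params: SegmentationParams,
) -> frozenset[str]:
    """Individuals departing within the simultaneity window of the earliest.

    Accepts a movement or a raw ``(id, time)`` departure sequence.  The
    boundary is inclusive: a departure exactly ``simultaneity_window_s``
    after the first still counts as simultaneous.  The result is
    insensitive to the ordering of equal-timestamp records.
    """
    departures = _departures_of(movement)
    if not departures:
        raise ValidationError("detect_first_movers needs at least one departure")
    t0 = min(t for _, t in departures)
    return frozenset(d for d, t in departures if t - t0 <= params.simultaneity_window_s)


def extract_predeparture_participants(
    log: EventLog,
    movement: CollectiveMovement | float,
    params: SegmentationParams,
) -> frozenset[str]:
    """Actors with >= 1 pre-departure act in [t0 - window, t0).

    ``movement`` may be a movement (its first departure time is used) or
    the first departure time itself.  The window is half-open: an act at
    exactly the departure time is the departure itself, not a
    pre-departure display.
    """
    first_departure_time = (
        movement.start_time if isinstance(movement, CollectiveMovement) else movement
    )
    lo = first_departure_time - params.predeparture_window_s
    return frozenset(
        e.actor_id
        for e in log.events
        if e.kind in PREDEPARTURE_KINDS and lo <= e.time_s < first_departure_time
    )


def joining_duration(
    movement: CollectiveMovement | Sequence[tuple[str, float]],
) -> Optional[float]:
    """Time from the first mover's departure to the last mover's departure.

    Undefined (``None``) when only one individual departed — a single
    departure has no joining process, which is not the same as an
    instantaneous one.
    """
    departures = _departures_of(movement)
    if len(departures) < 2:
        return None
    times = [t for _, t in departures]
    return max(times) - min(times)


def front_at_midtravel(
    log: EventLog,
    start_time: float | CollectiveMovement,
    end_time: float | None = None,
) -> Optional[str]:
    """The unique individual holding the front record at the temporal midpoint.

    Front-position annotations (`front` events) within the movement are
    examined at the record time closest to the midpoint; if no record
    exists, or two or more individuals share that closest time (horses
    walking abreast), the front is undefined and the movement is dropped
    from front-position tallies only.
    """
    if isinstance(start_time, CollectiveMovement):
        start_time, end_time = start_time.start_time, start_time.end_time
    assert end_time is not None
    return _front_in(log.events, start_time, end_time)


def _front_in(
    events: Sequence[BehavioralEvent], start_time: float, end_time: float
) -> Optional[str]:
    mid = 0.5 * (start_time + end_time)
    records = [
        e for e in events if e.kind == "front" and start_time <= e.time_s <= end_time
    ]
    if not records:
        return None
    best = min(abs(e.time_s - mid) for e in records)
    at_mid = {e.actor_id for e in records if abs(e.time_s - mid) == best}
    if len(at_mid) == 1:
        return next(iter(at_mid))
    return None


def count_bouts(
    movement: CollectiveMovement | Sequence[BehavioralEvent],
    log: EventLog | frozenset[str],
    params: SegmentationParams,
) -> int:
    """Number of moving periods within one movement.

    A bout boundary is a group pause — pause events by at least the
    participation fraction of the movers, clustered within
    ``bout_gap_s`` of each other — followed by renewed departure or
    joining events at least ``bout_gap_s`` after the pause.  Movements
    with a single uninterrupted moving period have one bout; downstream
    leadership analyses keep only those.

    Accepts either ``(movement, log, params)`` or, internally, the
    movement's event window plus the mover-id set.
    """
    if isinstance(movement, CollectiveMovement):
        assert isinstance(log, EventLog)
        t0, t1 = movement.start_time, movement.end_time
        cluster_events: Sequence[BehavioralEvent] = [
            e for e in log.events if t0 <= e.time_s <= t1
        ]
        mover_ids = frozenset(movement.departure_ids)
    else:
        cluster_events = movement
        mover_ids = log  # type: ignore[assignment]
    threshold = math.ceil(params.participation_fraction * len(mover_ids))
    pauses = [e for e in cluster_events if e.kind == "pause" and e.actor_id in mover_ids]
    if not pauses:
        return 1
    # group pause events into episodes separated by >= bout_gap_s
    episodes: list[list[BehavioralEvent]] = []
    for ev in pauses:
        if episodes and ev.time_s - episodes[-1][-1].time_s < params.bout_gap_s:
            episodes[-1].append(ev)
        else:
            episodes.append([ev])
    bouts = 1
    for ep in episodes:
        pausers = {e.actor_id for e in ep}
        if len(pausers) < threshold:
            continue
        ep_end = ep[-1].time_s
        resumed = any(
            e.kind in _MOVER_KINDS and e.time_s >= ep_end + params.bout_gap_s
            for e in cluster_events
        )
        if resumed:
            bouts += 1
    return bouts


def segment_movements(
    log: EventLog,
    roster: Roster,
    params: SegmentationParams | None = None,
) -> list[CollectiveMovement]:
    """Convert an event log into collective-movement episodes.

    Mover events (departure/joining) are clustered greedily: a quiet gap
    of at least ``movement_gap_s`` between consecutive mover events
    separates episodes.  A cluster qualifies as a collective movement
    iff the number of distinct movers reaches
    ``ceil(participation_fraction * N)``; each individual's departure
    time is its earliest mover event in the cluster.  Every departure
    event belongs to at most one movement; non-qualifying clusters are
    discarded entirely.
    """
    if params is None:
        params = SegmentationParams()
    log.validate_actors(roster)
    movers = [e for e in log.events if e.kind in _MOVER_KINDS]
    need = math.ceil(params.participation_fraction * roster.size)
    movements: list[CollectiveMovement] = []
    all_events = log.events
    times = [e.time_s for e in all_events]

    def window(lo: float, hi: float) -> Sequence[BehavioralEvent]:
        return all_events[bisect_left(times, lo) : bisect_right(times, hi)]

    for cluster in _mover_clusters(movers, params.movement_gap_s):
        dep_time: dict[str, float] = {}
        for e in cluster:
            if e.actor_id not in dep_time:
                dep_time[e.actor_id] = e.time_s
        if len(dep_time) < need:
            continue
        departures = tuple(sorted(dep_time.items(), key=lambda kv: (kv[1], kv[0])))
        t_start = departures[0][1]
        t_last_dep = departures[-1][1]
        # arrivals of the movers between movement start and the next cluster
        arr = tuple(
            (e.actor_id, e.time_s)
            for e in window(t_start, t_last_dep + params.movement_gap_s * 2)
            if e.kind == "arrival" and e.actor_id in dep_time
        )
        t_end = arr[-1][1] if arr else t_last_dep
        cluster_window = tuple(window(t_start, t_end))
        mover_ids = frozenset(dep_time)
        pre_window = window(t_start - params.predeparture_window_s, t_start)
        participants = frozenset(
            e.actor_id
            for e in pre_window
            if e.kind in PREDEPARTURE_KINDS and e.time_s < t_start
        )
        movements.append(
            CollectiveMovement(
                movement_id=f"m{len(movements) + 1:04d}",
                departures=departures,
                first_movers=detect_first_movers(departures, params),
                predeparture_participants=participants,
                front_at_midtravel=_front_in(cluster_window, t_start, t_end),
                n_bouts=count_bouts(cluster_window, mover_ids, params),
                joining_duration_s=joining_duration(departures),
                arrivals=arr if arr else None,
            )
        )
    return movements
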