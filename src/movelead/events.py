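"""Domain types and delimited-text I/O for behavioral event logs.

The atomic observation unit is a time-stamped behavioral act by one
individual (a :class:`BehavioralEvent`).  Sessions of such acts form an
:class:`EventLog`; segmentation turns logs into
:class:`CollectiveMovement` episodes.  Timestamps are seconds from the
start of the observation session — the field protocol (continuous focal
recording on tape) yields relative time only, so no wall-clock or date
handling is attempted.

Files are comma-separated with a required header; there is no standard
ethology interchange format, so the CSV schema here is this package's
own convention (documented in the README).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

__all__ = [
    "EVENT_KINDS",
    "PREDEPARTURE_KINDS",
    "AGE_CLASSES",
    "Individual",
    "Roster",
    "BehavioralEvent",
    "EventLog",
    "CollectiveMovement",
    "FormatError",
    "ValidationError",
    "read_roster",
    "write_roster",
    "read_events",
    "write_events",
    "write_report",
]

#: Recognized behavioral event kinds.  The five pre-departure acts signal
#: moving intent; ``departure``/``joining`` are the locomotor commitment
#: events; ``front`` is a walking-order annotation naming the individual
#: heading the progression at the time of record; ``agonistic`` carries a
#: winner (actor) and loser (target).
EVENT_KINDS = frozenset(
    {
        "move_away",
        "stay_peripheral",
        "follow_mover",
        "join_peripheral",
        "pause",
        "departure",
        "joining",
        "arrival",
        "front",
        "agonistic",
    }
)

#: Kinds counting as pre-departure behavior (intention movements).
PREDEPARTURE_KINDS = frozenset(
    {"move_away", "stay_peripheral", "follow_mover", "join_peripheral", "pause"}
)

AGE_CLASSES = ("adult", "subadult", "foal")

#: Default mapping from age in years to age class: foals are yearlings,
#: subadults two-year-olds, adults three years and older.
DEFAULT_AGE_CLASS_BOUNDS = {"foal_max": 1.0, "subadult_max": 2.0}


class FormatError(ValueError):
    """A file does not conform to the expected delimited-text schema."""


class ValidationError(ValueError):
    """Structurally well-formed input violates a domain invariant."""


def age_class_for(age_years: float, bounds: Mapping[str, float] | None = None) -> str:
    b = DEFAULT_AGE_CLASS_BOUNDS if bounds is None else bounds
    if age_years <= b["foal_max"]:
        return "foal"
    if age_years <= b["subadult_max"]:
        return "subadult"
    return "adult"


@dataclass(frozen=True)
class Individual:
    """One group member.

    ``dominance_rank`` is 1 for the top-ranking individual and, when
    present on every member of a roster, must form a permutation of
    ``1..N``.
    """

    id: str
    sex: str
    age_years: float
    age_class: str
    dominance_rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"individual {self.id!r}: sex must be female/male, got {self.sex!r}")
        if self.age_years < 0:
            raise ValidationError(f"individual {self.id!r}: negative age")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(f"individual {self.id!r}: unknown age class {self.age_class!r}")
        if self.dominance_rank is not None and self.dominance_rank < 1:
            raise ValidationError(f"individual {self.id!r}: rank must be >= 1")


@dataclass(frozen=True)
class Roster:
    """The members of one social group (N >= 2, unique ids)."""

    group_id: str
    members: tuple[Individual, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValidationError("a roster needs at least 2 members")
        ids = [m.id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate member ids: {dupes}")
        ranks = [m.dominance_rank for m in self.members if m.dominance_rank is not None]
        if ranks and sorted(ranks) != list(range(1, len(self.members) + 1)):
            raise ValidationError(
                f"dominance ranks must be a permutation of 1..{len(self.members)}, got {sorted(ranks)}"
            )

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.members)

    @property
    def size(self) -> int:
        return len(self.members)

    def __getitem__(self, member_id: str) -> Individual:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    def ages(self) -> dict[str, float]:
        return {m.id: m.age_years for m in self.members}

    def ranks(self) -> dict[str, int]:
        out = {m.id: m.dominance_rank for m in self.members}
        if any(r is None for r in out.values()):
            raise ValidationError(f"roster {self.group_id!r} has members without ranks")
        return out  # type: ignore[return-value]

    def validate_age_classes(self, bounds: Mapping[str, float] | None = None) -> None:
        """Check every member's age class against the age-years mapping."""
        for m in self.members:
            expect = age_class_for(m.age_years, bounds)
            if m.age_class != expect:
                raise ValidationError(
                    f"individual {m.id!r}: age {m.age_years} maps to class "
                    f"{expect!r} but roster says {m.age_class!r}"
                )


@dataclass(frozen=True)
class BehavioralEvent:
    time_s: float
    actor_id: str
    kind: str
    target_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.time_s < 0:
            raise ValidationError(f"event at t={self.time_s}: negative timestamp")
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")
        if self.kind == "agonistic" and self.target_id is None:
            raise ValidationError(f"agonistic event by {self.actor_id!r} requires a target_id")
        if self.target_id is not None and self.target_id == self.actor_id:
            raise ValidationError(f"event by {self.actor_id!r}: target equals actor")


@dataclass(frozen=True)
class EventLog:
    group_id: str
    session_id: str
    events: tuple[BehavioralEvent, ...]

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValidationError("events must be sorted by time_s")

    def of_kind(self, *kinds: str) -> tuple[BehavioralEvent, ...]:
        ks = set(kinds)
        return tuple(e for e in self.events if e.kind in ks)

    def validate_actors(self, roster: Roster) -> None:
        known = set(roster.ids)
        for e in self.events:
            if e.actor_id not in known:
                raise ValidationError(f"event actor {e.actor_id!r} not in roster {roster.group_id!r}")
            if e.target_id is not None and e.target_id not in known:
                raise ValidationError(f"event target {e.target_id!r} not in roster {roster.group_id!r}")


@dataclass(frozen=True)
class CollectiveMovement:
    """A segmented movement episode.

    ``departures`` holds one (member id, time) pair per mover, ordered by
    time; the joining events of followers count as their departures.
    ``joining_duration_s`` is last minus first departure time and is
    ``None`` when fewer than two individuals departed.
    ``front_at_midtravel`` is ``None`` when zero or several individuals
    shared the front record at the episode's temporal midpoint; such
    movements are excluded from front-position tallies only.
    """

    movement_id: str
    departures: tuple[tuple[str, float], ...]
    first_movers: frozenset[str]
    predeparture_participants: frozenset[str]
    front_at_midtravel: Optional[str] = None
    n_bouts: int = 1
    joining_duration_s: Optional[float] = None
    arrivals: Optional[tuple[tuple[str, float], ...]] = None

    def __post_init__(self) -> None:
        if not self.departures:
            raise ValidationError(f"movement {self.movement_id!r}: no departures")
        dep_ids = {d for d, _ in self.departures}
        if not self.first_movers:
            raise ValidationError(f"movement {self.movement_id!r}: empty first-mover set")
        if not self.first_movers <= dep_ids:
            raise ValidationError(f"movement {self.movement_id!r}: first movers not among departures")
        if self.n_bouts < 1:
            raise ValidationError(f"movement {self.movement_id!r}: n_bouts must be >= 1")
        if self.joining_duration_s is not None and self.joining_duration_s < 0:
            raise ValidationError(f"movement {self.movement_id!r}: negative joining duration")

    @property
    def departure_ids(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.departures)

    @property
    def start_time(self) -> float:
        return self.departures[0][1]

    @property
    def end_time(self) -> float:
        if self.arrivals:
            return self.arrivals[-1][1]
        return self.departures[-1][1]

    @property
    def sole_first_mover(self) -> Optional[str]:
        """The unique initiator, or ``None`` for simultaneous departures."""
        if len(self.first_movers) == 1:
            return next(iter(self.first_movers))
        return None


# ---------------------------------------------------------------------------
# delimited-text readers / writers


def _float_repr(x) -> str:
    """Shortest decimal that round-trips the float exactly."""
    return repr(float(x))


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")


def read_roster(path: str | Path, age_class_bounds: Mapping[str, float] | None = None) -> Roster:
    """Read a group roster from CSV.

    Required columns: ``id, sex, age_years, age_class``; optional
    ``rank``.  The file stem is used as group id unless a ``group_id``
    column is present.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str}, float_precision="round_trip")
    _require_columns(df, ["id", "sex", "age_years", "age_class"], path)
    ids = df["id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicate member ids {dupes}")
    members = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            rank = None
            if "rank" in df.columns and not pd.isna(getattr(row, "rank")):
                rank = int(getattr(row, "rank"))
            members.append(
                Individual(
                    id=str(row.id),
                    sex=str(row.sex),
                    age_years=float(row.age_years),
                    age_class=str(row.age_class),
                    dominance_rank=rank,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    group_id = str(df["group_id"].iloc[0]) if "group_id" in df.columns else path.stem
    roster = Roster(group_id=group_id, members=tuple(members))
    roster.validate_age_classes(age_class_bounds)
    return roster


def write_roster(roster: Roster, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "group_id": [roster.group_id] * roster.size,
            "id": [m.id for m in roster.members],
            "sex": [m.sex for m in roster.members],
            "age_years": [m.age_years for m in roster.members],
            "age_class": [m.age_class for m in roster.members],
            "rank": [m.dominance_rank for m in roster.members],
        }
    )
    df.to_csv(path, index=False, float_format=_float_repr)


def read_events(path: str | Path, roster: Roster, session_id: str | None = None) -> EventLog:
    """Read a behavioral event log from CSV, validating against a roster.

    Required columns: ``time_s, actor_id, kind``; optional ``target_id``.
    Rows out of time order are sorted with a warning (tape transcriptions
    are occasionally written down out of order); unknown kinds or actors
    are hard errors with line numbers.
    """
    path = Path(path)
    df = pd.read_csv(
        path, dtype={"actor_id": str, "target_id": str}, float_precision="round_trip"
    )
    _require_columns(df, ["time_s", "actor_id", "kind"], path)
    events = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        target = None
        if "target_id" in df.columns and not pd.isna(getattr(row, "target_id")):
            target = str(row.target_id)
        try:
            events.append(
                BehavioralEvent(
                    time_s=float(row.time_s),
                    actor_id=str(row.actor_id),
                    kind=str(row.kind),
                    target_id=target,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    times = [e.time_s for e in events]
    if any(b < a for a, b in zip(times, times[1:])):
        warnings.warn(f"{path}: events not in time order; sorting", stacklevel=2)
        events.sort(key=lambda e: e.time_s)
    log = EventLog(
        group_id=roster.group_id,
        session_id=session_id or path.stem,
        events=tuple(events),
    )
    log.validate_actors(roster)
    return log


def write_events(log: EventLog, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": [e.time_s for e in log.events],
            "actor_id": [e.actor_id for e in log.events],
            "kind": [e.kind for e in log.events],
            "target_id": [e.target_id for e in log.events],
        }
    )
    df.to_csv(path, index=False, float_format=_float_repr)


def write_report(results, out_dir: str | Path) -> None:
    """Write pipeline results as a JSON report plus CSV tables.

    ``results`` is a :class:`movelead.pipeline.PipelineResults` (or any
    object with ``to_dict()`` and ``tables()``).  The JSON is written
    with sorted keys so identical inputs give byte-identical reports.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = results.to_dict() if hasattr(results, "to_dict") else dict(results)
    with open(out_dir / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
    tables: Mapping[str, pd.DataFrame] = results.tables() if hasattr(results, "tables") else {}
    for name, table in tables.items():
        table.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.2f")
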