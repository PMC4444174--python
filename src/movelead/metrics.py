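"""Per-individual leadership tallies, concordance between definitions,
joining-efficiency grouping, and count reconstruction from published
percentage tables.

Three operational definitions of leadership are tallied per individual:

* first mover — departed first, counted only over movements with a
  single (non-simultaneous) first mover;
* front position — headed the walking order at mid-travel, counted only
  over movements where a unique front individual was scored;
* pre-departure involvement — displayed at least one pre-departure act
  in the window before departure, counted over all movements.

The concordance table asks, per individual, whether displaying
pre-departure behavior predicted subsequently departing first or
walking in front (forward conditionals) and, retrospectively, whether
first movers / front individuals had announced their departure
(retrospective conditionals).  Cells with a zero denominator are
undefined — genuinely different from 0%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .events import CollectiveMovement, Roster

__all__ = [
    "ProxyCounts",
    "ConcordanceCell",
    "ConcordanceTable",
    "JoiningEfficiency",
    "ReconstructionError",
    "tally_proxies",
    "concordance",
    "joining_efficiency",
    "reconstruct_counts",
    "proportion_summaries",
]

CONCORDANCE_COLUMNS = (
    "first_given_predep",
    "front_given_predep",
    "first_and_front_given_predep",
    "predep_given_first",
    "predep_given_front",
)

FORWARD_COLUMNS = CONCORDANCE_COLUMNS[:3]
RETROSPECTIVE_COLUMNS = CONCORDANCE_COLUMNS[3:]


class ReconstructionError(ValueError):
    """No (or no unique) denominator reproduces a percentage column."""


@dataclass(frozen=True)
class ProxyCounts:
    """Per-individual leadership-proxy tallies with their denominators."""

    ids: tuple[str, ...]
    predeparture_count: dict[str, int]
    first_mover_count: dict[str, int]
    front_count: dict[str, int]
    n_single_first_mover_movements: int
    n_simultaneous_movements: int
    n_front_scored_movements: int
    n_total_movements: int

    def counts(self, proxy: str) -> list[int]:
        table = {
            "predeparture": self.predeparture_count,
            "first_mover": self.first_mover_count,
            "front": self.front_count,
        }[proxy]
        return [table[i] for i in self.ids]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "predeparture_count": self.counts("predeparture"),
                "first_mover_count": self.counts("first_mover"),
                "front_count": self.counts("front"),
            }
        )

    def to_dict(self) -> dict:
        return {
            "ids": list(self.ids),
            "predeparture_count": dict(self.predeparture_count),
            "first_mover_count": dict(self.first_mover_count),
            "front_count": dict(self.front_count),
            "n_single_first_mover_movements": self.n_single_first_mover_movements,
            "n_simultaneous_movements": self.n_simultaneous_movements,
            "n_front_scored_movements": self.n_front_scored_movements,
            "n_total_movements": self.n_total_movements,
        }


@dataclass(frozen=True)
class ConcordanceCell:
    numerator: int
    denominator: int

    @property
    def percent(self) -> Optional[float]:
        if self.denominator == 0:
            return None
        return 100.0 * self.numerator / self.denominator


@dataclass(frozen=True)
class ConcordanceTable:
    """Per-individual conditional percentages linking the proxies.

    Forward conditionals condition on the individual having displayed
    pre-departure behavior; retrospective conditionals condition on it
    having been sole first mover (or the scored front individual).
    Column means are taken over defined cells only — an individual that
    never qualified for the denominator carries no information, whereas
    a defined 0% does and is included.
    """

    ids: tuple[str, ...]
    cells: dict[str, dict[str, ConcordanceCell]]  # column -> id -> cell

    def percent(self, column: str, individual: str) -> Optional[float]:
        return self.cells[column][individual].percent

    def column_mean(self, column: str) -> Optional[float]:
        vals = [c.percent for c in self.cells[column].values() if c.percent is not None]
        if not vals:
            return None
        return float(np.mean(vals))

    def column_sem(self, column: str) -> Optional[float]:
        vals = [c.percent for c in self.cells[column].values() if c.percent is not None]
        if len(vals) < 2:
            return None
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))

    @classmethod
    def from_percentages(
        cls,
        ids: Sequence[str],
        columns: Mapping[str, Sequence[Optional[float]]],
    ) -> "ConcordanceTable":
        """Build a table from published percentage columns (no raw counts).

        Blank cells are ``None``.  Numerators/denominators are stored as
        the percentage over 100 so that ``percent`` round-trips; such
        synthetic cells support column means but not count recovery.
        """
        cells: dict[str, dict[str, ConcordanceCell]] = {}
        for col, values in columns.items():
            cells[col] = {}
            for ind, v in zip(ids, values):
                if v is None:
                    cells[col][ind] = ConcordanceCell(0, 0)
                else:
                    cells[col][ind] = ConcordanceCell(int(round(v * 100)), 10000)
        return cls(ids=tuple(ids), cells=cells)

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, list] = {"id": list(self.ids)}
        for col in self.cells:
            data[col] = [self.percent(col, i) for i in self.ids]
        return pd.DataFrame(data)

    def to_dict(self) -> dict:
        return {
            "ids": list(self.ids),
            "columns": {
                col: {
                    i: {
                        "numerator": c.numerator,
                        "denominator": c.denominator,
                        "percent": c.percent,
                    }
                    for i, c in by_id.items()
                }
                for col, by_id in self.cells.items()
            },
            "means": {col: self.column_mean(col) for col in self.cells},
            "sems": {col: self.column_sem(col) for col in self.cells},
        }


@dataclass(frozen=True)
class JoiningEfficiency:
    """Joining durations grouped by (qualifying) sole first mover."""

    groups: dict[str, tuple[float, ...]]
    min_departures: int
    omnibus_applicable: bool

    def to_dict(self) -> dict:
        return {
            "groups": {k: list(v) for k, v in self.groups.items()},
            "min_departures": self.min_departures,
            "omnibus_applicable": self.omnibus_applicable,
        }


def tally_proxies(
    movements: Sequence[CollectiveMovement], roster: Roster
) -> ProxyCounts:
    """Count the three leadership proxies per individual.

    First-mover counts accrue only for movements with exactly one first
    mover — simultaneous departures have no single initiator to credit
    and are excluded from the departure analysis.  Front counts accrue
    only when a unique front individual was scored.  Pre-departure
    counts accrue for every movement whose participant set contains the
    individual.  The result is independent of movement ordering.
    """
    ids = roster.ids
    pre = {i: 0 for i in ids}
    first = {i: 0 for i in ids}
    front = {i: 0 for i in ids}
    n_single = n_simul = n_front = 0
    for mv in movements:
        if mv.sole_first_mover is not None:
            n_single += 1
            first[mv.sole_first_mover] += 1
        else:
            n_simul += 1
        if mv.front_at_midtravel is not None:
            n_front += 1
            front[mv.front_at_midtravel] += 1
        for i in mv.predeparture_participants:
            pre[i] += 1
    return ProxyCounts(
        ids=ids,
        predeparture_count=pre,
        first_mover_count=first,
        front_count=front,
        n_single_first_mover_movements=n_single,
        n_simultaneous_movements=n_simul,
        n_front_scored_movements=n_front,
        n_total_movements=len(movements),
    )


def concordance(
    movements: Sequence[CollectiveMovement], roster: Roster
) -> ConcordanceTable:
    """Movement-level concordance between pre-departure display and leading."""
    ids = roster.ids
    cells: dict[str, dict[str, ConcordanceCell]] = {c: {} for c in CONCORDANCE_COLUMNS}
    for i in ids:
        displayed = [mv for mv in movements if i in mv.predeparture_participants]
        was_first = [mv for mv in movements if mv.sole_first_mover == i]
        was_front = [mv for mv in movements if mv.front_at_midtravel == i]
        n_disp = len(displayed)
        cells["first_given_predep"][i] = ConcordanceCell(
            sum(1 for mv in displayed if mv.sole_first_mover == i), n_disp
        )
        cells["front_given_predep"][i] = ConcordanceCell(
            sum(1 for mv in displayed if mv.front_at_midtravel == i), n_disp
        )
        cells["first_and_front_given_predep"][i] = ConcordanceCell(
            sum(
                1
                for mv in displayed
                if mv.sole_first_mover == i and mv.front_at_midtravel == i
            ),
            n_disp,
        )
        cells["predep_given_first"][i] = ConcordanceCell(
            sum(1 for mv in was_first if i in mv.predeparture_participants),
            len(was_first),
        )
        cells["predep_given_front"][i] = ConcordanceCell(
            sum(1 for mv in was_front if i in mv.predeparture_participants),
            len(was_front),
        )
    return ConcordanceTable(ids=ids, cells=cells)


def joining_efficiency(
    movements: Sequence[CollectiveMovement],
    roster: Roster,
    min_departures: int = 3,
) -> JoiningEfficiency:
    """Group joining durations by first mover for the efficiency comparison.

    Only movements with a sole first mover and a defined joining
    duration contribute; only movers who initiated at least
    ``min_departures`` such movements are kept.  With fewer than two
    qualifying movers the omnibus (Kruskal-Wallis) comparison is not
    applicable and the result says so.
    """
    by_mover: dict[str, list[float]] = {}
    for mv in movements:
        i = mv.sole_first_mover
        if i is None or mv.joining_duration_s is None:
            continue
        by_mover.setdefault(i, []).append(mv.joining_duration_s)
    groups = {
        i: tuple(v) for i, v in by_mover.items() if len(v) >= min_departures
    }
    # deterministic ordering by roster position
    ordered = {i: groups[i] for i in roster.ids if i in groups}
    return JoiningEfficiency(
        groups=ordered,
        min_departures=min_departures,
        omnibus_applicable=len(ordered) >= 2,
    )


def reconstruct_counts(
    percentages: Sequence[float],
    candidate_denominators: Sequence[int],
    expected_total: Optional[int] = None,
    tol: float = 0.005,
) -> tuple[list[int], int]:
    """Recover integer counts from a published percentage column.

    For each candidate denominator ``d`` the counts are
    ``round(p_i * d / 100)``; a candidate survives iff the recomputed
    percentages ``100 * c_i / d`` reproduce every input to the printed
    precision (within ``tol``) and, when ``expected_total`` is given,
    the counts sum to it.  Exactly one candidate must survive.

    Published tables sometimes mix denominators within one layout (a
    percentage column may be over the movements scored for that proxy
    rather than the column's nominal total), which is why the
    denominator is searched rather than assumed.
    """
    p = np.asarray(percentages, dtype=float)
    if np.any((p < 0) | (p > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    if not candidate_denominators:
        raise ValueError("need at least one candidate denominator")
    survivors: list[tuple[int, list[int]]] = []
    residuals: dict[int, float] = {}
    for d in sorted(set(int(d) for d in candidate_denominators)):
        if d <= 0:
            raise ValueError("denominators must be positive")
        counts = np.rint(p * d / 100.0).astype(int)
        recomputed = 100.0 * counts / d
        resid = float(np.max(np.abs(recomputed - p)))
        residuals[d] = resid
        if resid > tol + 1e-9:
            continue
        if expected_total is not None and int(counts.sum()) != expected_total:
            continue
        survivors.append((d, counts.tolist()))
    if not survivors:
        raise ReconstructionError(
            f"no candidate denominator reproduces the column; max residuals {residuals}"
        )
    if len(survivors) > 1:
        if np.all(p == 0) and expected_total == 0:
            return survivors[0][1], survivors[0][0]
        raise ReconstructionError(
            f"ambiguous denominators {[d for d, _ in survivors]} all reproduce the column"
        )
    d, counts = survivors[0]
    return counts, d


def proportion_summaries(counts: ProxyCounts) -> dict[str, float]:
    """Headline shares: simultaneous departures and the top first mover.

    Percentages of the totality of movements started simultaneously, and
    the largest share of single-first-mover movements attributable to
    one individual.
    """
    out: dict[str, float] = {}
    if counts.n_total_movements:
        out["simultaneous_pct_of_total"] = (
            100.0 * counts.n_simultaneous_movements / counts.n_total_movements
        )
    if counts.n_single_first_mover_movements:
        top = max(counts.first_mover_count.values())
        out["top_first_mover_pct_of_single"] = (
            100.0 * top / counts.n_single_first_mover_movements
        )
    return out
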