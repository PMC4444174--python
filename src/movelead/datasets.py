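"""Published summary data for the two study groups.

A field study of two semi-free-ranging Przewalski horse families (the
"BO" group, 12 animals observed in 2004, and the "AD" group, 6 animals
observed in 2006) published per-individual percentages and per-group
movement totals but not the raw event logs.  Those printed summaries
are reproduced here verbatim: together with
:func:`movelead.metrics.reconstruct_counts` they let every headline
statistic of the study be recomputed from integer counts.

Individual codes encode rank and age: the leading digit is the
dominance rank, the letter gives sex and maturity (F/M adult female /
stallion, f/m immature), and the trailing digits the age in years — so
``7f2`` is a 2-year-old female of rank 7.

Percentages are over group-specific denominators that differ by
column: departure columns are over the movements with a single first
mover (28 BO / 35 AD); front-position percentages are over the same
nominal totals but only 11 (BO) / 21 (AD) movements carried a unique
front score, which is why reconstruction searches candidate
denominators instead of assuming one.
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType
from typing import Mapping, Optional

from .events import Individual, Roster, age_class_for

__all__ = ["GroupSummary", "BO", "AD", "GROUPS"]


@dataclass(frozen=True)
class GroupSummary:
    """Printed per-group summary: roster, movement totals, percentage table."""

    roster: Roster
    #: movement totals by type
    n_single_first_mover: int
    n_simultaneous: int
    n_collective_predeparture: int
    n_front_scored: int
    n_total: int
    #: per-individual percentage columns, in roster order; None = blank cell
    predeparture_pct: tuple[float, ...]
    departed_first_pct: tuple[float, ...]
    front_pct: tuple[float, ...]
    first_given_predep_pct: tuple[Optional[float], ...]
    front_given_predep_pct: tuple[Optional[float], ...]
    first_and_front_given_predep_pct: tuple[Optional[float], ...]
    predep_given_first_pct: tuple[Optional[float], ...]
    predep_given_front_pct: tuple[Optional[float], ...]

    @property
    def ages(self) -> tuple[float, ...]:
        return tuple(m.age_years for m in self.roster.members)

    def concordance_columns(self) -> Mapping[str, tuple[Optional[float], ...]]:
        return {
            "first_given_predep": self.first_given_predep_pct,
            "front_given_predep": self.front_given_predep_pct,
            "first_and_front_given_predep": self.first_and_front_given_predep_pct,
            "predep_given_first": self.predep_given_first_pct,
            "predep_given_front": self.predep_given_front_pct,
        }


def _member(code: str, sex: str, age: float, rank: int) -> Individual:
    return Individual(
        id=code,
        sex=sex,
        age_years=age,
        age_class=age_class_for(age),
        dominance_rank=rank,
    )


_BO_ROSTER = Roster(
    group_id="BO",
    members=(
        _member("1F16", "female", 16, 1),
        _member("2M8", "male", 8, 2),
        _member("3F15", "female", 15, 3),
        _member("4F4", "female", 4, 4),
        _member("5F5", "female", 5, 5),
        _member("6F4", "female", 4, 6),
        _member("7f2", "female", 2, 7),
        _member("8f2", "female", 2, 8),
        _member("9f1", "female", 1, 9),
        _member("10m1", "male", 1, 10),
        _member("11f1", "female", 1, 11),
        _member("12m1", "male", 1, 12),
    ),
)

BO = GroupSummary(
    roster=_BO_ROSTER,
    n_single_first_mover=28,
    n_simultaneous=14,
    n_collective_predeparture=33,
    n_front_scored=11,
    n_total=42,
    predeparture_pct=(
        17.86, 10.71, 28.57, 17.86, 46.43, 21.43,
        3.57, 14.29, 21.43, 14.29, 28.57, 10.71,
    ),
    departed_first_pct=(
        21.43, 7.14, 39.29, 0.00, 28.57, 0.00,
        3.57, 0.00, 0.00, 0.00, 0.00, 0.00,
    ),
    front_pct=(
        18.18, 0.00, 27.27, 0.00, 45.45, 9.09,
        0.00, 0.00, 0.00, 0.00, 0.00, 0.00,
    ),
    first_given_predep_pct=(
        80.00, 66.67, 50.00, 0.00, 53.85, 0.00,
        0.00, 0.00, 0.00, 0.00, 0.00, 0.00,
    ),
    front_given_predep_pct=(
        20.00, 0.00, 0.00, 0.00, 23.08, 0.00,
        0.00, 0.00, 0.00, 0.00, 0.00, 0.00,
    ),
    first_and_front_given_predep_pct=(
        20.00, 0.00, 0.00, 0.00, 15.38, 0.00,
        0.00, 0.00, 0.00, 0.00, 0.00, 0.00,
    ),
    predep_given_first_pct=(
        66.67, 100.00, 36.36, None, 87.50, None,
        0.00, None, None, None, None, None,
    ),
    predep_given_front_pct=(
        16.67, 0.00, 0.00, None, 37.50, 0.00,
        0.00, None, None, None, None, None,
    ),
)

_AD_ROSTER = Roster(
    group_id="AD",
    members=(
        _member("1M12", "male", 12, 1),
        _member("2F9", "female", 9, 2),
        _member("3F9", "female", 9, 3),
        _member("4F8", "female", 8, 4),
        _member("5m1", "male", 1, 5),
        _member("6m1", "male", 1, 6),
    ),
)

AD = GroupSummary(
    roster=_AD_ROSTER,
    n_single_first_mover=35,
    n_simultaneous=8,
    n_collective_predeparture=32,
    n_front_scored=21,
    n_total=43,
    predeparture_pct=(51.43, 37.14, 37.14, 40.00, 31.43, 28.57),
    departed_first_pct=(17.14, 17.14, 31.43, 22.86, 2.86, 8.57),
    front_pct=(2.86, 14.29, 11.43, 31.43, 0.00, 0.00),
    first_given_predep_pct=(22.22, 15.38, 30.77, 28.57, 9.09, 20.00),
    front_given_predep_pct=(5.56, 15.38, 15.38, 35.71, 0.00, 0.00),
    first_and_front_given_predep_pct=(5.56, 7.69, 0.00, 7.14, 0.00, 0.00),
    predep_given_first_pct=(66.67, 33.33, 36.36, 50.00, 100.00, 66.67),
    predep_given_front_pct=(16.67, 33.33, 18.18, 62.50, 0.00, 0.00),
)

GROUPS: Mapping[str, GroupSummary] = MappingProxyType({"BO": BO, "AD": AD})
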