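"""Synthetic behavioral event streams with known ground truth.

The generator realizes the statistical structure the analysis assumes:
each collective movement has per-individual first-mover propensities
(drawn once from a symmetric Dirichlet, or fixed), optional
simultaneous departures, per-individual pre-departure display
probabilities with a tunable coupling between displaying and departing
first, an exponential joining process, a front-position record at
mid-travel, and optional multi-bout structure and transitive agonistic
interactions.  Every realized latent quantity is recorded in a
:class:`GroundTruth` object consistent record-for-record with the
emitted :class:`~movelead.events.EventLog`, so segmentation and
tallying can be tested against exact bookkeeping, and statistical
power / type-I error can be measured by replication.

The single interpretable axis of leadership concentration runs from
large Dirichlet concentration (everyone equally likely to depart first
— shared decisions) through small concentration or an explicit spike
(one habitual initiator — despotic).  Randomness flows from one root
seed through per-movement substreams, so editing one movement's draw
does not perturb the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .events import BehavioralEvent, EventLog, Roster
from . import datasets

__all__ = ["SyntheticConfig", "GroundTruth", "MovementTruth", "generate", "preset", "PRESETS"]

_PRE_KINDS = ("move_away", "stay_peripheral", "follow_mover", "join_peripheral", "pause")


class ConfigError(ValueError):
    """Infeasible generator configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic movement process.

    All probabilities are per movement.  ``propensities`` (summing to
    1, one per roster member) overrides the Dirichlet draw governed by
    ``kappa``.  ``coupling`` is the probability that the first mover is
    drawn from the movement's pre-departure participant set rather than
    from the whole group.  When ``exact_rates`` is set, the
    simultaneity / front-scored / two-bout rates are realized as exact
    per-run allocations (round(rate * n_movements) movements, positions
    shuffled) instead of independent Bernoulli draws, so short runs
    reproduce the configured frequencies exactly.
    """

    roster: Roster
    n_movements: int = 42
    kappa: float = 10.0
    propensities: Optional[tuple[float, ...]] = None
    predeparture_rates: tuple[float, ...] | float = 0.25
    coupling: float = 0.5
    simultaneity_prob: float = 0.25
    simultaneity_spread_s: float = 8.0
    joining_mean_s: float = 400.0
    joining_guard_s: float = 11.0
    max_joining_gap_s: float = 540.0
    front_scored_prob: float = 0.5
    front_follows_first_prob: float = 0.3
    two_bout_prob: float = 0.0
    predeparture_window_s: float = 1200.0
    intermovement_gap_s: float = 600.0
    travel_time_range_s: tuple[float, float] = (300.0, 600.0)
    n_agonistic: int = 0
    exact_rates: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        n = self.roster.size
        if self.n_movements < 1:
            raise ConfigError("n_movements must be >= 1")
        if self.kappa <= 0:
            raise ConfigError("kappa must be > 0")
        for name in (
            "coupling",
            "simultaneity_prob",
            "front_scored_prob",
            "front_follows_first_prob",
            "two_bout_prob",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ConfigError(f"{name} must be in [0, 1]")
        if self.propensities is not None:
            p = np.asarray(self.propensities, dtype=float)
            if p.size != n or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
                raise ConfigError("propensities must be a length-N simplex vector")
        rates = self.rates_vector()
        if np.any((rates < 0) | (rates > 1)):
            raise ConfigError("predeparture_rates must be probabilities")
        if self.simultaneity_prob > 0 and self.simultaneity_spread_s <= 0:
            raise ConfigError(
                "simultaneous departures need a positive simultaneity_spread_s"
            )
        if self.joining_mean_s <= self.joining_guard_s:
            raise ConfigError("joining_mean_s must exceed joining_guard_s")

    def rates_vector(self) -> np.ndarray:
        n = self.roster.size
        if isinstance(self.predeparture_rates, (int, float)):
            return np.full(n, float(self.predeparture_rates))
        r = np.asarray(self.predeparture_rates, dtype=float)
        if r.size != n:
            raise ConfigError("predeparture_rates length must match roster size")
        return r


@dataclass(frozen=True)
class MovementTruth:
    """Latent state of one generated movement."""

    index: int
    first_movers: frozenset[str]
    primary_first_mover: str
    predeparture_participants: frozenset[str]
    front_id: Optional[str]
    n_bouts: int
    departure_times: tuple[tuple[str, float], ...]
    joining_duration_s: Optional[float]

    @property
    def simultaneous(self) -> bool:
        return len(self.first_movers) > 1


@dataclass(frozen=True)
class GroundTruth:
    propensities: dict[str, float]
    movements: tuple[MovementTruth, ...]

    def first_mover_frequencies(self) -> dict[str, float]:
        """Empirical frequency of each individual as primary first mover."""
        n = len(self.movements)
        out = {i: 0.0 for i in self.propensities}
        for mv in self.movements:
            out[mv.primary_first_mover] += 1.0 / n
        return out

    def to_dict(self) -> dict:
        return {
            "propensities": dict(self.propensities),
            "movements": [
                {
                    "index": m.index,
                    "first_movers": sorted(m.first_movers),
                    "primary_first_mover": m.primary_first_mover,
                    "predeparture_participants": sorted(m.predeparture_participants),
                    "front_id": m.front_id,
                    "n_bouts": m.n_bouts,
                    "departure_times": [list(d) for d in m.departure_times],
                    "joining_duration_s": m.joining_duration_s,
                }
                for m in self.movements
            ],
        }


def _allocate_flags(
    rng: np.random.Generator, n: int, prob: float, exact: bool
) -> np.ndarray:
    if exact:
        k = int(round(prob * n))
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:k]] = True
        return flags
    return rng.random(n) < prob


def _weighted_pick(
    rng: np.random.Generator, ids: Sequence[str], weights: np.ndarray
) -> str:
    total = weights.sum()
    if total <= 0:
        return ids[int(rng.integers(len(ids)))]
    return ids[int(rng.choice(len(ids), p=weights / total))]


def generate(config: SyntheticConfig) -> tuple[EventLog, GroundTruth]:
    """Generate an event log and the latent truth that produced it.

    Identical configs (including seed) give identical outputs.  The
    inter-movement spacing guarantees that no event of one movement
    falls inside another movement's pre-departure window, so the
    segmentation defaults recover the latent structure exactly.
    """
    roster = config.roster
    ids = list(roster.ids)
    n_ind = len(ids)
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_movements + 1)
    g_rng = np.random.default_rng(streams[0])

    if config.propensities is not None:
        prop = np.asarray(config.propensities, dtype=float)
    else:
        prop = g_rng.dirichlet(np.full(n_ind, config.kappa))
    rates = config.rates_vector()

    sim_flags = _allocate_flags(g_rng, config.n_movements, config.simultaneity_prob, config.exact_rates)
    front_flags = _allocate_flags(g_rng, config.n_movements, config.front_scored_prob, config.exact_rates)
    bout_flags = _allocate_flags(g_rng, config.n_movements, config.two_bout_prob, config.exact_rates)

    events: list[BehavioralEvent] = []
    truths: list[MovementTruth] = []
    # first window must fit entirely at non-negative times
    cursor = config.predeparture_window_s + 60.0

    for m in range(config.n_movements):
        rng = np.random.default_rng(streams[m + 1])
        t0 = cursor + float(rng.exponential(config.intermovement_gap_s))

        # pre-departure displays
        participants = [i for i, r in zip(ids, rates) if rng.random() < r]
        for i in participants:
            for _ in range(int(rng.integers(1, 4))):
                t = t0 - float(rng.uniform(5.0, config.predeparture_window_s))
                kind = _PRE_KINDS[int(rng.integers(len(_PRE_KINDS)))]
                events.append(BehavioralEvent(time_s=t, actor_id=i, kind=kind))

        # first mover(s)
        part_set = frozenset(participants)
        use_coupled = participants and rng.random() < config.coupling
        if use_coupled:
            w = np.array([prop[ids.index(i)] for i in participants])
            primary = _weighted_pick(rng, participants, w)
        else:
            primary = _weighted_pick(rng, ids, prop)
        first_movers = [primary]
        if sim_flags[m]:
            n_extra = int(rng.integers(1, 3))  # 2 or 3 total
            others = [i for i in ids if i != primary]
            w = np.array([prop[ids.index(i)] for i in others])
            for _ in range(n_extra):
                pick = _weighted_pick(rng, others, w)
                k = others.index(pick)
                others.pop(k)
                w = np.delete(w, k)
                first_movers.append(pick)

        dep_times: dict[str, float] = {primary: t0}
        for extra in first_movers[1:]:
            dep_times[extra] = t0 + float(rng.uniform(0.5, config.simultaneity_spread_s))
        for i in first_movers:
            events.append(BehavioralEvent(time_s=dep_times[i], actor_id=i, kind="departure"))

        # joining process: remaining members follow within duration D.
        # Joiners are spread evenly with jitter over the joining span and
        # the span is capped so no within-movement quiet gap can reach
        # the segmentation movement gap and split the episode.
        joiners = [i for i in ids if i not in dep_times]
        D = config.joining_guard_s + float(
            rng.exponential(config.joining_mean_s - config.joining_guard_s)
        )
        if joiners:
            n_j = len(joiners)
            cap = config.joining_guard_s + n_j * config.max_joining_gap_s / 1.8
            D = min(D, cap)
            span = D - config.joining_guard_s
            offsets = np.sort(
                (np.arange(1, n_j + 1) + rng.uniform(-0.4, 0.4, size=n_j)) / n_j * span
            )
            offsets[-1] = span
            for i, off in zip(joiners, offsets):
                t = t0 + config.joining_guard_s + float(off)
                dep_times[i] = t
                events.append(BehavioralEvent(time_s=t, actor_id=i, kind="joining"))
        last_dep = max(dep_times.values())

        # optional second bout: group pause, then renewed departures
        n_bouts = 1
        if bout_flags[m]:
            n_bouts = 2
            t_pause = last_dep + float(rng.uniform(30.0, 60.0))
            for i in ids:
                events.append(
                    BehavioralEvent(
                        time_s=t_pause + float(rng.uniform(0.0, 15.0)),
                        actor_id=i,
                        kind="pause",
                    )
                )
            t_resume = t_pause + 15.0 + 75.0
            for i in first_movers:
                events.append(BehavioralEvent(time_s=t_resume, actor_id=i, kind="departure"))
            travel_base = t_resume
        else:
            travel_base = last_dep

        # arrivals
        lo, hi = config.travel_time_range_s
        arrivals = {
            i: travel_base + float(rng.uniform(lo, hi)) for i in ids
        }
        for i, t in sorted(arrivals.items(), key=lambda kv: kv[1]):
            events.append(BehavioralEvent(time_s=t, actor_id=i, kind="arrival"))
        t_end = max(arrivals.values())

        # front-position record at the temporal midpoint
        front_id: Optional[str] = None
        t_mid = 0.5 * (t0 + t_end)
        if front_flags[m]:
            if rng.random() < config.front_follows_first_prob:
                front_id = primary
            else:
                front_id = ids[int(rng.integers(n_ind))]
            events.append(BehavioralEvent(time_s=t_mid, actor_id=front_id, kind="front"))
        elif rng.random() < 0.5:
            # abreast: two individuals share the front record
            a, b = rng.choice(n_ind, size=2, replace=False)
            events.append(BehavioralEvent(time_s=t_mid, actor_id=ids[int(a)], kind="front"))
            events.append(BehavioralEvent(time_s=t_mid, actor_id=ids[int(b)], kind="front"))

        dep_sorted = tuple(sorted(dep_times.items(), key=lambda kv: (kv[1], kv[0])))
        truths.append(
            MovementTruth(
                index=m,
                first_movers=frozenset(first_movers),
                primary_first_mover=primary,
                predeparture_participants=part_set,
                front_id=front_id,
                n_bouts=n_bouts,
                departure_times=dep_sorted,
                joining_duration_s=(last_dep - t0) if len(dep_times) > 1 else None,
            )
        )
        # keep the next movement's pre-departure window clear of this
        # movement's events (pause is also a pre-departure kind)
        cursor = t_end + config.predeparture_window_s + 60.0

    # transitive agonistic interactions (winner = higher-ranked)
    if config.n_agonistic > 0:
        ranks = roster.ranks()
        for _ in range(config.n_agonistic):
            a, b = g_rng.choice(n_ind, size=2, replace=False)
            i, j = ids[int(a)], ids[int(b)]
            winner, loser = (i, j) if ranks[i] < ranks[j] else (j, i)
            t = float(g_rng.uniform(0.0, cursor))
            events.append(
                BehavioralEvent(time_s=t, actor_id=winner, kind="agonistic", target_id=loser)
            )

    events.sort(key=lambda e: (e.time_s, e.actor_id, e.kind))
    log = EventLog(
        group_id=roster.group_id,
        session_id=f"synthetic-seed{config.seed}",
        events=tuple(events),
    )
    truth = GroundTruth(
        propensities={i: float(p) for i, p in zip(ids, prop)},
        movements=tuple(truths),
    )
    return log, truth


def _bo_like(seed: int, n_movements: Optional[int]) -> SyntheticConfig:
    g = datasets.BO
    counts = np.rint(np.asarray(g.departed_first_pct) * g.n_single_first_mover / 100.0)
    return SyntheticConfig(
        roster=g.roster,
        n_movements=n_movements or g.n_total,
        propensities=tuple(counts / counts.sum()),
        predeparture_rates=tuple(p / 100.0 for p in g.predeparture_pct),
        coupling=0.58,
        simultaneity_prob=g.n_simultaneous / g.n_total,
        joining_mean_s=471.0,
        front_scored_prob=g.n_front_scored / g.n_total,
        front_follows_first_prob=0.3,
        n_agonistic=120,
        exact_rates=True,
        seed=seed,
    )


def _ad_like(seed: int, n_movements: Optional[int]) -> SyntheticConfig:
    g = datasets.AD
    counts = np.rint(np.asarray(g.departed_first_pct) * g.n_single_first_mover / 100.0)
    return SyntheticConfig(
        roster=g.roster,
        n_movements=n_movements or g.n_total,
        propensities=tuple(counts / counts.sum()),
        predeparture_rates=tuple(p / 100.0 for p in g.predeparture_pct),
        coupling=0.59,
        simultaneity_prob=g.n_simultaneous / g.n_total,
        joining_mean_s=249.0,
        front_scored_prob=g.n_front_scored / g.n_total,
        front_follows_first_prob=0.3,
        n_agonistic=80,
        exact_rates=True,
        seed=seed,
    )


def _null_uniform(seed: int, n_movements: Optional[int]) -> SyntheticConfig:
    return SyntheticConfig(
        roster=datasets.BO.roster,
        n_movements=n_movements or 42,
        kappa=1e6,
        coupling=0.0,
        simultaneity_prob=0.0,
        front_scored_prob=0.5,
        front_follows_first_prob=0.0,
        seed=seed,
    )


def _concentrated(seed: int, n_movements: Optional[int]) -> SyntheticConfig:
    n = datasets.BO.roster.size
    spike = 0.8
    rest = (1.0 - spike) / (n - 1)
    return SyntheticConfig(
        roster=datasets.BO.roster,
        n_movements=n_movements or 42,
        propensities=(spike,) + (rest,) * (n - 1),
        coupling=0.0,
        simultaneity_prob=0.0,
        front_scored_prob=0.5,
        front_follows_first_prob=0.8,
        seed=seed,
    )


PRESETS = {
    "paper_BO_like": _bo_like,
    "shared_AD_like": _ad_like,
    "null_uniform": _null_uniform,
    "concentrated": _concentrated,
}


def preset(name: str, seed: int = 0, n_movements: Optional[int] = None) -> SyntheticConfig:
    """A documented configuration by name.

    ``paper_BO_like`` / ``shared_AD_like`` are calibrated to the
    published group summaries (movement totals, simultaneous-departure
    and front-scored shares, first-mover distribution, pre-departure
    rates, joining durations); ``null_uniform`` has near-uniform
    propensities and no display/departure coupling; ``concentrated``
    gives one individual a 0.8 first-mover propensity (despotic).
    """
    try:
        factory = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    return factory(seed, n_movements)
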