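"""End-to-end analysis: segment, tally, test, concordance, hierarchy.

Two entry points mirror the two kinds of available input.
:func:`run_pipeline` starts from a raw event log and roster and runs
every enabled analysis; :func:`run_from_summary` starts from a
published percentage table plus movement totals, reconstructs integer
counts, and runs the inference layer on them — the reproduction path
for studies that printed summaries but deposited no raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import dominance as dom
from . import inference, metrics
from .datasets import GroupSummary
from .events import EventLog, Roster
from .segmentation import SegmentationParams, segment_movements

__all__ = ["PipelineConfig", "PipelineResults", "run_pipeline", "run_from_summary"]

PROXIES = ("first_mover", "front", "predeparture")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs besides the data itself."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    mc_reps: int = 2000
    linearity_randomizations: int = 10000
    alpha: float = 0.05
    seed: int = 0
    min_departures_for_efficiency: int = 3
    # analysis toggles
    departure: bool = True
    front: bool = True
    predeparture: bool = True
    joining: bool = True
    concordance: bool = True
    hierarchy: bool = True


@dataclass
class PipelineResults:
    """Structured results of one run; JSON- and CSV-serializable."""

    group_id: str
    n_movements: int
    n_single_bout: int
    manifest: dict
    proxy_counts: Optional[metrics.ProxyCounts] = None
    g_tests: dict[str, inference.GTestResult] = field(default_factory=dict)
    posthoc: dict[str, inference.PosthocResult] = field(default_factory=dict)
    age_correlations: dict[str, tuple[float, float]] = field(default_factory=dict)
    joining: Optional[metrics.JoiningEfficiency] = None
    kruskal: Optional[tuple[float, float]] = None
    concordance: Optional[metrics.ConcordanceTable] = None
    linearity: Optional[dom.LinearityResult] = None
    rank_age: Optional[tuple[float, float]] = None
    proportions: dict[str, float] = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "group_id": self.group_id,
            "n_movements": self.n_movements,
            "n_single_bout": self.n_single_bout,
            "manifest": self.manifest,
            "proxy_counts": self.proxy_counts.to_dict() if self.proxy_counts else None,
            "g_tests": {k: v.to_dict() for k, v in self.g_tests.items()},
            "posthoc": {k: v.to_dict() for k, v in self.posthoc.items()},
            "age_correlations": {
                k: {"rs": v[0], "p": v[1]} for k, v in self.age_correlations.items()
            },
            "joining": self.joining.to_dict() if self.joining else None,
            "kruskal_wallis": (
                None if self.kruskal is None else {"H": self.kruskal[0], "p": self.kruskal[1]}
            ),
            "concordance": self.concordance.to_dict() if self.concordance else None,
            "linearity": self.linearity.to_dict() if self.linearity else None,
            "rank_age": (
                None if self.rank_age is None else {"rs": self.rank_age[0], "p": self.rank_age[1]}
            ),
            "proportions": dict(self.proportions),
            "notes": list(self.notes),
        }

    def tables(self) -> dict[str, pd.DataFrame]:
        out: dict[str, pd.DataFrame] = {}
        if self.proxy_counts is not None:
            out["proxy_counts"] = self.proxy_counts.to_frame()
        if self.concordance is not None:
            out["concordance"] = self.concordance.to_frame()
        return out


def _test_proxy(
    results: PipelineResults,
    name: str,
    counts: Sequence[int],
    n: int,
    labels: Sequence[str],
    config: PipelineConfig,
    seed_offset: int,
) -> None:
    if n == 0 or sum(counts) == 0:
        results.notes.append(f"{name}: no qualifying movements, test not applicable")
        return
    results.g_tests[name] = inference.mc_uniform_test(
        counts, B=config.mc_reps, seed=config.seed + seed_offset
    )
    results.posthoc[name] = inference.posthoc_chance_tests(
        counts, n, labels=labels, alpha=config.alpha
    )


def run_pipeline(
    log: EventLog,
    roster: Roster,
    config: PipelineConfig | None = None,
) -> PipelineResults:
    """Full analysis of an event log.

    Movements are segmented, multi-bout episodes are dropped, and the
    enabled analyses run on the single-bout movements.  With zero
    single-bout movements every section carries an explicit
    not-applicable marker instead of silently vanishing.
    """
    if config is None:
        config = PipelineConfig()
    movements = segment_movements(log, roster, config.segmentation)
    single = [m for m in movements if m.n_bouts == 1]
    results = PipelineResults(
        group_id=roster.group_id,
        n_movements=len(movements),
        n_single_bout=len(single),
        manifest={
            "segmentation": vars(config.segmentation).copy(),
            "mc_reps": config.mc_reps,
            "linearity_randomizations": config.linearity_randomizations,
            "alpha": config.alpha,
            "seed": config.seed,
            "session_id": log.session_id,
        },
    )
    ages = roster.ages()
    age_vec = [ages[i] for i in roster.ids]
    if not single:
        results.notes.append("0 movements: leadership analyses not applicable")
    else:
        counts = metrics.tally_proxies(single, roster)
        results.proxy_counts = counts
        results.proportions = metrics.proportion_summaries(counts)
        if config.departure:
            _test_proxy(
                results,
                "first_mover",
                counts.counts("first_mover"),
                counts.n_single_first_mover_movements,
                roster.ids,
                config,
                1,
            )
            rs_p = inference.spearman(age_vec, counts.counts("first_mover"))
            if rs_p[0] is not None:
                results.age_correlations["first_mover"] = rs_p  # type: ignore[assignment]
        if config.front:
            _test_proxy(
                results,
                "front",
                counts.counts("front"),
                counts.n_front_scored_movements,
                roster.ids,
                config,
                2,
            )
            rs_p = inference.spearman(age_vec, counts.counts("front"))
            if rs_p[0] is not None:
                results.age_correlations["front"] = rs_p  # type: ignore[assignment]
        if config.predeparture:
            pre_counts = counts.counts("predeparture")
            _test_proxy(
                results, "predeparture", pre_counts, sum(pre_counts), roster.ids, config, 3
            )
            rs_p = inference.spearman(age_vec, pre_counts)
            if rs_p[0] is not None:
                results.age_correlations["predeparture"] = rs_p  # type: ignore[assignment]
        if config.joining:
            eff = metrics.joining_efficiency(
                single, roster, config.min_departures_for_efficiency
            )
            results.joining = eff
            if eff.omnibus_applicable:
                results.kruskal = inference.kruskal_wallis(list(eff.groups.values()))
            else:
                results.notes.append(
                    "joining: fewer than 2 qualifying first movers, omnibus not applicable"
                )
        if config.concordance:
            results.concordance = metrics.concordance(single, roster)
    if config.hierarchy:
        matrix = dom.build_matrix(log, roster)
        if matrix.wins.sum() > 0 and roster.size >= 3:
            results.linearity = dom.linearity(
                matrix,
                randomizations=config.linearity_randomizations,
                seed=config.seed + 4,
            )
        else:
            results.notes.append("hierarchy: no agonistic interactions recorded")
        try:
            results.rank_age = dom.rank_age_correlation(roster)
        except Exception:
            results.notes.append("hierarchy: rank-age correlation not available")
    return results


def run_from_summary(
    summary: GroupSummary,
    config: PipelineConfig | None = None,
) -> PipelineResults:
    """Recompute the inference layer from a published percentage table.

    Integer counts are reconstructed from each percentage column by
    denominator search (the single-first-mover total, the front-scored
    total and the overall total are the candidates), then tested
    exactly as in the event-log path.  The result carries a provenance
    note that the inputs were summary-derived.
    """
    if config is None:
        config = PipelineConfig()
    roster = summary.roster
    candidates = {
        summary.n_single_first_mover,
        summary.n_front_scored,
        summary.n_collective_predeparture,
        summary.n_total,
    }
    results = PipelineResults(
        group_id=roster.group_id,
        n_movements=summary.n_total,
        n_single_bout=summary.n_total,
        manifest={
            "mode": "summary_reconstruction",
            "mc_reps": config.mc_reps,
            "alpha": config.alpha,
            "seed": config.seed,
        },
    )
    results.notes.append(
        "inputs reconstructed from published percentage tables, not raw events"
    )
    ages = roster.ages()
    age_vec = [ages[i] for i in roster.ids]

    spec = {
        "first_mover": (summary.departed_first_pct, summary.n_single_first_mover),
        "front": (summary.front_pct, summary.n_front_scored),
        "predeparture": (summary.predeparture_pct, None),
    }
    enabled = {
        "first_mover": config.departure,
        "front": config.front,
        "predeparture": config.predeparture,
    }
    recon: dict[str, list[int]] = {}
    for offset, (name, (pcts, expected_total)) in enumerate(spec.items(), start=1):
        if not enabled[name]:
            continue
        if all(p == 0 for p in pcts):
            results.notes.append(f"{name}: all-zero column, G undefined")
            continue
        counts, denom = metrics.reconstruct_counts(
            list(pcts), sorted(candidates), expected_total=expected_total
        )
        recon[name] = counts
        n = expected_total if expected_total is not None else sum(counts)
        results.manifest[f"{name}_denominator"] = denom
        _test_proxy(results, name, counts, n, roster.ids, config, offset)
        rs_p = inference.spearman(age_vec, counts)
        if rs_p[0] is not None:
            results.age_correlations[name] = rs_p  # type: ignore[assignment]

    if recon:
        pre = recon.get("predeparture")
        first = recon.get("first_mover")
        front = recon.get("front")
        results.proxy_counts = metrics.ProxyCounts(
            ids=roster.ids,
            predeparture_count=dict(zip(roster.ids, pre or [0] * roster.size)),
            first_mover_count=dict(zip(roster.ids, first or [0] * roster.size)),
            front_count=dict(zip(roster.ids, front or [0] * roster.size)),
            n_single_first_mover_movements=summary.n_single_first_mover,
            n_simultaneous_movements=summary.n_simultaneous,
            n_front_scored_movements=summary.n_front_scored,
            n_total_movements=summary.n_total,
        )
        results.proportions = metrics.proportion_summaries(results.proxy_counts)

    if config.concordance:
        results.concordance = metrics.ConcordanceTable.from_percentages(
            roster.ids, summary.concordance_columns()
        )
    try:
        results.rank_age = dom.rank_age_correlation(roster)
    except Exception:
        results.notes.append("rank-age correlation not available")
    return results
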