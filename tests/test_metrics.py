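"""Proxy tallies, concordance conditionals, joining-efficiency grouping,
and count reconstruction from percentage columns."""

import pytest
from hypothesis import given, strategies as st

from movelead import datasets, synthetic
from movelead.events import CollectiveMovement
from movelead.metrics import (
    ReconstructionError,
    concordance,
    joining_efficiency,
    proportion_summaries,
    reconstruct_counts,
    tally_proxies,
)
from movelead.segmentation import segment_movements


def mk_movement(idx, departures, first=None, pre=(), front=None):
    first = frozenset(first if first is not None else [departures[0][0]])
    return CollectiveMovement(
        movement_id=f"m{idx}",
        departures=tuple(departures),
        first_movers=first,
        predeparture_participants=frozenset(pre),
        front_at_midtravel=front,
        joining_duration_s=(departures[-1][1] - departures[0][1]
                            if len(departures) > 1 else None),
    )


@pytest.fixture
def tiny_roster():
    from movelead.events import Individual, Roster

    return Roster(
        group_id="T",
        members=tuple(
            Individual(id=i, sex="female", age_years=5, age_class="adult")
            for i in ("a", "b", "c")
        ),
    )


class TestTally:
    def test_simultaneous_movements_credit_nobody(self, tiny_roster):
        movs = [
            mk_movement(1, [("a", 0.0), ("b", 2.0), ("c", 100.0)], first=["a", "b"]),
            mk_movement(2, [("b", 0.0), ("a", 50.0), ("c", 90.0)]),
        ]
        counts = tally_proxies(movs, tiny_roster)
        assert counts.first_mover_count == {"a": 0, "b": 1, "c": 0}
        assert counts.n_single_first_mover_movements == 1
        assert counts.n_simultaneous_movements == 1

    def test_front_counts_only_when_scored(self, tiny_roster):
        movs = [
            mk_movement(1, [("a", 0.0), ("b", 10.0)], front="b"),
            mk_movement(2, [("a", 0.0), ("b", 10.0)], front=None),
        ]
        counts = tally_proxies(movs, tiny_roster)
        assert counts.front_count == {"a": 0, "b": 1, "c": 0}
        assert counts.n_front_scored_movements == 1

    def test_order_invariant(self, tiny_roster):
        movs = [
            mk_movement(1, [("a", 0.0), ("b", 10.0)], pre=["a"]),
            mk_movement(2, [("b", 0.0), ("c", 10.0)], pre=["b", "c"]),
            mk_movement(3, [("c", 0.0), ("a", 10.0)], front="a"),
        ]
        assert tally_proxies(movs, tiny_roster) == tally_proxies(movs[::-1], tiny_roster)

    def test_matches_generator_bookkeeping_exactly(self):
        cfg = synthetic.preset("paper_BO_like", seed=11)
        log, truth = synthetic.generate(cfg)
        roster = datasets.BO.roster
        movs = segment_movements(log, roster)
        counts = tally_proxies(movs, roster)
        for i in roster.ids:
            assert counts.first_mover_count[i] == sum(
                1 for m in truth.movements
                if not m.simultaneous and m.primary_first_mover == i
            )
            assert counts.front_count[i] == sum(
                1 for m in truth.movements if m.front_id == i
            )
            assert counts.predeparture_count[i] == sum(
                1 for m in truth.movements if i in m.predeparture_participants
            )


class TestConcordance:
    def test_forward_conditional_from_constructed_movements(self, tiny_roster):
        # "a" displays pre-departure in 5 movements and departs first in 4
        movs = [
            mk_movement(k, [("a", 0.0), ("b", 10.0)], pre=["a"]) for k in range(4)
        ]
        movs.append(mk_movement(5, [("b", 0.0), ("a", 10.0)], pre=["a"]))
        table = concordance(movs, tiny_roster)
        assert table.percent("first_given_predep", "a") == pytest.approx(80.0)
        cell = table.cells["first_given_predep"]["a"]
        assert (cell.numerator, cell.denominator) == (4, 5)

    def test_never_first_mover_has_undefined_retrospective(self, tiny_roster):
        movs = [mk_movement(1, [("a", 0.0), ("b", 10.0)], pre=["c"])]
        table = concordance(movs, tiny_roster)
        assert table.percent("predep_given_first", "c") is None
        assert table.percent("predep_given_first", "c") != 0.0

    def test_numerators_bounded_by_denominators(self, tiny_roster):
        cfg = synthetic.SyntheticConfig(
            roster=datasets.BO.roster, n_movements=60, coupling=0.7, seed=21
        )
        log, _ = synthetic.generate(cfg)
        roster = datasets.BO.roster
        movs = segment_movements(log, roster)
        table = concordance(movs, roster)
        for col in table.cells:
            for cell in table.cells[col].values():
                assert 0 <= cell.numerator <= cell.denominator or cell.denominator == 0

    def test_full_coupling_gives_certain_retrospective(self):
        cfg = synthetic.SyntheticConfig(
            roster=datasets.BO.roster, n_movements=80, coupling=1.0,
            predeparture_rates=0.4, simultaneity_prob=0.0, seed=13,
        )
        log, _ = synthetic.generate(cfg)
        roster = datasets.BO.roster
        movs = segment_movements(log, roster)
        table = concordance(movs, roster)
        for i in roster.ids:
            pct = table.percent("predep_given_first", i)
            if pct is not None:
                assert pct == pytest.approx(100.0)

    def test_published_column_means(self, bo):
        from movelead.metrics import ConcordanceTable

        table = ConcordanceTable.from_percentages(
            bo.roster.ids, bo.concordance_columns()
        )
        assert table.column_mean("first_given_predep") == pytest.approx(20.88, abs=0.005)
        assert table.column_mean("predep_given_first") == pytest.approx(58.11, abs=0.005)


class TestJoiningEfficiency:
    def test_bo_reconstruction_has_three_qualifying_movers(self, tiny_roster):
        # movers with 6, 11, 8 sole-first departures qualify at threshold 3
        movs = []
        idx = 0
        for mover, n in (("a", 6), ("b", 11), ("c", 8)):
            for _ in range(n):
                other = "a" if mover != "a" else "b"
                movs.append(mk_movement(idx, [(mover, 0.0), (other, 100.0)]))
                idx += 1
        movs.append(mk_movement(idx, [("a", 0.0), ("b", 50.0)], first=["a", "b"]))
        eff = joining_efficiency(movs, tiny_roster, min_departures=3)
        assert {k: len(v) for k, v in eff.groups.items()} == {"a": 6, "b": 11, "c": 8}
        assert eff.omnibus_applicable

    def test_threshold_one_keeps_every_mover(self, tiny_roster):
        movs = [
            mk_movement(1, [("a", 0.0), ("b", 10.0)]),
            mk_movement(2, [("c", 0.0), ("b", 10.0)]),
        ]
        eff = joining_efficiency(movs, tiny_roster, min_departures=1)
        assert set(eff.groups) == {"a", "c"}

    def test_single_qualifying_mover_flags_omnibus(self, tiny_roster):
        movs = [mk_movement(k, [("a", 0.0), ("b", 10.0)]) for k in range(4)]
        eff = joining_efficiency(movs, tiny_roster)
        assert not eff.omnibus_applicable


class TestReconstruction:
    def test_bo_departure_column(self, bo):
        counts, d = reconstruct_counts(bo.departed_first_pct, [28])
        assert counts == [6, 2, 11, 0, 8, 0, 1, 0, 0, 0, 0, 0]
        assert d == 28
        assert sum(counts) == 28

    def test_ad_front_column_picks_percentage_base(self, ad):
        counts, d = reconstruct_counts(ad.front_pct, [21, 35], expected_total=21)
        assert d == 35
        assert counts == [1, 5, 4, 11, 0, 0]

    def test_zero_column_ambiguous_unless_total_zero(self):
        with pytest.raises(ReconstructionError, match="ambiguous"):
            reconstruct_counts([0.0, 0.0], [5, 7])
        counts, _ = reconstruct_counts([0.0, 0.0], [5, 7], expected_total=0)
        assert counts == [0, 0]

    def test_inconsistent_column_reports_residuals(self):
        with pytest.raises(ReconstructionError, match="residual"):
            reconstruct_counts([33.33, 66.67], [5])

    @given(st.integers(5, 60), st.data())
    def test_round_trip_reproduces_percentages(self, d, data):
        counts = data.draw(
            st.lists(st.integers(0, d), min_size=3, max_size=8).filter(
                lambda c: sum(c) <= 3 * d
            )
        )
        pcts = [round(100.0 * c / d, 2) for c in counts]
        got, chosen = reconstruct_counts(pcts, [d])
        assert chosen == d
        assert got == counts
        back = [round(100.0 * c / d, 2) for c in got]
        assert back == pcts


class TestProportions:
    def test_published_totals(self, bo, ad):
        from movelead.pipeline import run_from_summary

        r = run_from_summary(bo)
        assert round(r.proportions["simultaneous_pct_of_total"]) == 33
        assert round(r.proportions["top_first_mover_pct_of_single"]) == 39
        r = run_from_summary(ad)
        assert round(r.proportions["simultaneous_pct_of_total"]) == 19
        assert round(r.proportions["top_first_mover_pct_of_single"]) == 31
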