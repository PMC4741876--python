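"""Branching simulator: conservation, mean-field oracle, ancestry attribution."""

import math

import numpy as np
import pytest

from ploidysim import (
    ClassEpochRates,
    ConfigurationError,
    InputError,
    LineageForest,
    PopulationState,
    RateTable,
    attribute_ancestry,
    simulate,
)
from ploidysim.calibration import SIZE_CLASSES
from ploidysim.popsim import WINDOW_DAYS, step_fate_probs


def flat_table(**kwargs) -> RateTable:
    """Same rates for every class and epoch."""
    defaults = dict(
        p_death=0.0, p_divide=0.0, p_rest=1.0, p_multi=0.0,
        multi_daughter_dist={3: 2 / 3, 4: 1 / 3},
        p_fusion_per_daughter=0.0, bud_rate=0.0,
    )
    defaults.update(kwargs)
    rates = {
        (sc, ep): ClassEpochRates(**defaults)
        for sc in SIZE_CLASSES
        for ep in ("day14", "day30", "day49plus")
    }
    return RateTable(rates=rates)


class TestSimulateBasics:
    def test_absorbing_rest_keeps_counts_constant(self):
        init = PopulationState(14.0, {"S": 3, "M": 5, "G": 7})
        res = simulate(init, flat_table(), horizon=40.0, seed=1)
        for st in res.states:
            assert st.counts == {"S": 3, "M": 5, "G": 7}

    def test_bad_step_and_horizon_rejected(self):
        init = PopulationState(14.0, {"S": 1, "M": 0, "G": 0})
        with pytest.raises(ConfigurationError):
            simulate(init, flat_table(), horizon=20.0, step=0.0)
        with pytest.raises(ConfigurationError):
            simulate(init, flat_table(), horizon=10.0)

    def test_missing_epoch_rejected(self, default_rates):
        table = RateTable(rates={("G", "day14"): default_rates.get("G", "day14")})
        init = PopulationState(14.0, {"S": 0, "M": 0, "G": 10})
        with pytest.raises(ConfigurationError):
            simulate(init, table, horizon=40.0, seed=1)

    @pytest.mark.parametrize("track_lineage", [False, True])
    def test_seeded_reproducibility(self, default_rates, track_lineage):
        init = PopulationState(14.0, {"S": 20, "M": 20, "G": 50})
        a = simulate(init, default_rates, 30.0, seed=9, track_lineage=track_lineage)
        b = simulate(init, default_rates, 30.0, seed=9, track_lineage=track_lineage)
        assert [s.counts for s in a.states] == [s.counts for s in b.states]


class TestConservation:
    """live(t+1) = live(t) - deaths - dividing parents + daughters + buds - fused pairs."""

    @pytest.mark.parametrize("track_lineage", [False, True])
    def test_bookkeeping_each_step(self, default_rates, track_lineage):
        init = PopulationState(14.0, {"S": 100, "M": 100, "G": 500})
        res = simulate(
            init, default_rates, 45.0, seed=13, track_lineage=track_lineage
        )
        for before, after, ev in zip(res.states, res.states[1:], res.events):
            expected = (
                before.total() - ev.deaths - ev.dividers
                + ev.daughters + ev.buds - ev.fused_pairs
            )
            assert after.total() == expected

    def test_forest_counts_match_trajectory(self, default_rates):
        init = PopulationState(14.0, {"S": 10, "M": 10, "G": 40})
        res = simulate(init, default_rates, 35.0, seed=4, track_lineage=True)
        for st in res.states:
            alive = res.forest.alive_at(st.time)
            per_class = {c: 0 for c in SIZE_CLASSES}
            for node in alive:
                per_class[res.forest.klass[node]] += 1
            assert per_class == st.counts


class TestMeanField:
    def test_matrix_product_oracle(self):
        """Mean-field counts equal the initial vector pushed through the
        hand-computed per-step expectation matrix."""
        table = flat_table()
        table.rates[("S", "day14")] = ClassEpochRates(
            p_death=0.1, p_divide=0.4, p_rest=0.5, p_multi=0.0
        )
        table.rates[("M", "day14")] = ClassEpochRates(
            p_death=0.0, p_divide=0.0, p_rest=1.0, p_multi=0.0
        )
        table.rates[("G", "day14")] = ClassEpochRates(
            p_death=0.2, p_divide=0.3, p_rest=0.5, p_multi=0.1,
            multi_daughter_dist={3: 1.0}, p_fusion_per_daughter=0.2, bud_rate=0.5,
        )
        # expectation matrix over (S, M, G), entries derived by hand:
        # S: rest 0.5 + bipolar 0.4*2 = 1.3 (no fusion)
        # G diagonal: rest 0.5 + bipolar 0.3*0.9*2*0.8 = 0.932, + bipolar-fusion
        #   promotion G->G 0.3*0.9*0.2 = 0.054  => 0.986
        # G -> S: multi 0.3*0.1*(3*0.8 + 0.5) = 0.087
        # G -> M: multi-fusion 0.3*0.1*3*0.2/2 = 0.009
        a = np.array([
            [1.3, 0.0, 0.087],
            [0.0, 1.0, 0.009],
            [0.0, 0.0, 0.986],
        ])
        n0 = np.array([10.0, 5.0, 100.0])
        init = PopulationState(14.0, {"S": 10, "M": 5, "G": 100})
        res = simulate(init, table, 14.0 + 2 * WINDOW_DAYS, mode="meanfield")
        expected = a @ (a @ n0)
        got = np.array([res.states[-1].counts[c] for c in ("S", "M", "G")])
        np.testing.assert_allclose(got, expected, rtol=1e-12)

    def test_reduces_to_binary_branching_closed_form(self):
        # with fusion, budding and multi-daughter division off, each class is an
        # independent Galton-Watson process with mean p_rest + 2 p_divide
        table = flat_table(p_death=0.2, p_divide=0.3, p_rest=0.5)
        init = PopulationState(14.0, {"S": 1000, "M": 0, "G": 0})
        steps = 4
        res = simulate(init, table, 14.0 + steps * WINDOW_DAYS, mode="meanfield")
        assert res.states[-1].counts["S"] == pytest.approx(1000 * (0.5 + 0.6) ** steps)

    def test_stochastic_mean_matches_closed_form(self):
        table = flat_table(p_death=0.2, p_divide=0.3, p_rest=0.5)
        init = PopulationState(14.0, {"S": 500, "M": 0, "G": 0})
        steps = 3
        finals = []
        for r in range(200):
            res = simulate(init, table, 14.0 + steps * WINDOW_DAYS, seed=1000 + r)
            finals.append(res.states[-1].counts["S"])
        finals = np.array(finals, dtype=float)
        expected = 500 * 1.1 ** steps
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - expected) < 3 * se

    def test_stochastic_agrees_with_meanfield_under_default_rates(self, default_rates):
        init = PopulationState(14.0, {"S": 800, "M": 1600, "G": 7600})
        mf = simulate(init, default_rates, 29.0, mode="meanfield")
        finals = {c: [] for c in SIZE_CLASSES}
        for r in range(100):
            res = simulate(init, default_rates, 29.0, seed=5000 + r)
            for c in SIZE_CLASSES:
                finals[c].append(res.states[-1].counts[c])
        for c in SIZE_CLASSES:
            arr = np.array(finals[c], dtype=float)
            se = arr.std(ddof=1) / 10.0
            assert abs(arr.mean() - mf.states[-1].counts[c]) < 3 * se, c


class TestStepRescaling:
    """Competing-risk conversion leaves window-level fate probabilities invariant."""

    @pytest.mark.parametrize(
        "probs", [(0.6, 0.15, 0.25), (0.1, 0.4, 0.5), (0.0, 0.3, 0.7)]
    )
    def test_half_steps_compose_exactly(self, probs):
        cer = ClassEpochRates(p_death=probs[0], p_divide=probs[1], p_rest=probs[2])
        d_h, v_h, r_h = step_fate_probs(cer, 0.5)
        # no-event probability composes multiplicatively
        assert r_h ** 2 == pytest.approx(cer.p_rest)
        # probability that the first event over the window is a death is preserved
        assert d_h * (1 + r_h) == pytest.approx(cer.p_death)
        assert v_h * (1 + r_h) == pytest.approx(cer.p_divide)

    def test_full_window_is_identity(self):
        cer = ClassEpochRates(p_death=0.6, p_divide=0.15, p_rest=0.25)
        assert step_fate_probs(cer, 1.0) == pytest.approx((0.6, 0.15, 0.25))


def build_forest(spec):
    """spec: list of (klass, birth, end, parents) tuples; returns forest."""
    forest = LineageForest()
    for klass, birth, end, parents in spec:
        node = forest.new_node(klass, birth, tuple(parents))
        if end is not None:
            forest.close(node, end, "event")
    return forest


def brute_force_ancestry(forest, final_time, final_class, founder_time):
    """Exhaustive path enumeration: walk every ancestry path of every final
    cell, multiplying 1/#parents at each hop, and accumulate at founders."""
    acc = {c: 0.0 for c in SIZE_CLASSES}
    finals = [
        i for i in forest.alive_at(final_time) if forest.klass[i] == final_class
    ]
    for node in finals:
        stack = [(node, 1.0)]
        while stack:
            i, w = stack.pop()
            is_founder = forest.birth[i] <= founder_time and (
                forest.end[i] is None or forest.end[i] > founder_time
            )
            if is_founder:
                acc[forest.klass[i]] += w
            else:
                parents = forest.parents[i]
                for p in parents:
                    stack.append((p, w / len(parents)))
    total = sum(acc.values())
    return {c: v / total for c, v in acc.items()}, len(finals)


class TestAncestry:
    def test_single_founder_takes_all(self):
        forest = build_forest(
            [("G", 0.0, 1.0, [])] + [("S", 1.0, None, [0]) for _ in range(5)]
        )
        report = attribute_ancestry(forest, 1.0, "S", 0.0)
        assert report.fractions["G"] == pytest.approx(1.0)
        assert report.n_final == 5

    def test_two_founders_forced_arithmetic(self):
        spec = [("G", 0.0, 1.0, []), ("S", 0.0, 1.0, [])]
        spec += [("S", 1.0, None, [0]) for _ in range(3)]   # giant's descendants
        spec += [("S", 1.0, None, [1])]                      # small founder's child
        report = attribute_ancestry(build_forest(spec), 1.0, "S", 0.0)
        assert report.fractions["G"] == pytest.approx(0.75)
        assert report.fractions["S"] == pytest.approx(0.25)

    def test_fusion_node_splits_weight_between_parents(self):
        spec = [
            ("S", 0.0, 1.0, []),       # founder A (small)
            ("G", 0.0, 1.0, []),       # founder B (giant)
            ("S", 1.0, 1.0, [0]),      # daughter of A, fused
            ("S", 1.0, 1.0, [1]),      # daughter of B, fused
            ("M", 1.0, None, [2, 3]),  # fusion product
        ]
        report = attribute_ancestry(build_forest(spec), 2.0, "M", 0.0)
        assert report.fractions["S"] == pytest.approx(0.5)
        assert report.fractions["G"] == pytest.approx(0.5)

    def test_final_before_founder_rejected(self):
        forest = build_forest([("G", 0.0, None, [])])
        with pytest.raises(InputError):
            attribute_ancestry(forest, 1.0, "G", 2.0)

    def test_no_final_cells_flagged_empty(self):
        forest = build_forest([("G", 0.0, None, [])])
        report = attribute_ancestry(forest, 1.0, "S", 0.0)
        assert report.empty and report.n_final == 0

    def test_matches_brute_force_enumeration_on_simulated_forest(self, default_rates):
        init = PopulationState(14.0, {"S": 5, "M": 5, "G": 30})
        res = simulate(init, default_rates, 45.0, seed=7, track_lineage=True)
        final_time = res.states[-1].time
        assert len(res.forest) <= 400  # small forest; enumeration is exact
        for final_class in SIZE_CLASSES:
            alive = [
                i for i in res.forest.alive_at(final_time)
                if res.forest.klass[i] == final_class
            ]
            if not alive:
                continue
            expected, n_final = brute_force_ancestry(
                res.forest, final_time, final_class, 14.0
            )
            report = attribute_ancestry(res.forest, final_time, final_class, 14.0)
            assert report.n_final == n_final
            for c in SIZE_CLASSES:
                assert report.fractions[c] == pytest.approx(expected[c], abs=1e-9)

    def test_fractions_sum_to_one(self, default_rates):
        init = PopulationState(14.0, {"S": 20, "M": 20, "G": 100})
        res = simulate(init, default_rates, 50.0, seed=2, track_lineage=True)
        report = attribute_ancestry(res.forest, res.states[-1].time, "S", 14.0)
        if not report.empty:
            assert sum(report.fractions.values()) == pytest.approx(1.0, abs=1e-9)


class TestForestExport:
    def test_edgelist_and_networkx(self, default_rates):
        init = PopulationState(14.0, {"S": 0, "M": 0, "G": 20})
        res = simulate(init, default_rates, 30.0, seed=3, track_lineage=True)
        edges = res.forest.to_edgelist_frame()
        g = res.forest.to_networkx()
        assert g.number_of_nodes() == len(res.forest)
        assert g.number_of_edges() == len(edges)
        import networkx as nx

        assert nx.is_directed_acyclic_graph(g)
        # child birth times never precede parent birth times
        for p, c in g.edges:
            assert res.forest.birth[c] >= res.forest.birth[p]
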