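"""Deletion sequences, cascade classification, stability metrics, Monte Carlo."""

import math

import numpy as np
import pytest

import trophodyn as td
from trophodyn.experiment import DeletionStep, ExperimentResult


def synthetic_result(survivors, s_l, secondaries_per_step=0):
    """Assemble a result object from a survivor trajectory for metric tests."""
    steps = tuple(
        DeletionStep(step=p + 1, removed=f"n{p}", ranking=(),
                     secondary=tuple(
                         td.SecondaryExtinction(f"s{p}_{k}", 1.0,
                                                td.CascadeClass("bottom-up", "direct"),
                                                0.0, 0.0)
                         for k in range(secondaries_per_step)),
                     n_survivors=n)
        for p, n in enumerate(survivors))
    return ExperimentResult(steps=steps, s_initial_living=s_l, burnin_extinctions=(),
                            s_l=s_l, r50=math.nan, sa=math.nan,
                            draw=td.CENTRAL_DRAW, kind="max_d", fr_form="linear")


class TestStabilityMetrics:
    def test_r50_without_secondaries(self):
        res = synthetic_result([9, 8, 7, 6, 5, 4, 3, 2, 1, 0], s_l=10)
        assert td.r50(res) == pytest.approx(0.5)

    def test_r50_one_secondary_per_primary(self):
        # losses 2p: threshold 5 reached at p = 3
        res = synthetic_result([8, 6, 4, 2, 0], s_l=10, secondaries_per_step=1)
        assert td.r50(res) == pytest.approx(0.3)

    def test_r50_instant_collapse_is_one_over_sl(self):
        res = synthetic_result([0], s_l=8)
        assert td.r50(res) == pytest.approx(1 / 8)

    def test_sa_closed_form_no_secondaries(self):
        # SA = (3+2+1+0)/16 = (S_l - 1)/(2 S_l)
        res = synthetic_result([3, 2, 1, 0], s_l=4)
        assert td.survival_area(res) == pytest.approx(0.375)
        assert td.survival_area(res) == pytest.approx((4 - 1) / (2 * 4))

    def test_sa_zero_on_instant_collapse(self):
        res = synthetic_result([0], s_l=6)
        assert td.survival_area(res) == 0.0

    def test_sa_decreases_with_extra_secondary(self):
        base = synthetic_result([9, 8, 7, 6, 5, 4, 3, 2, 1, 0], s_l=10)
        worse = synthetic_result([9, 8, 6, 5, 4, 3, 2, 1, 0], s_l=10)
        assert td.survival_area(worse) < td.survival_area(base)

    def test_sa_plus_ea_is_one(self):
        res = synthetic_result([8, 6, 4, 2, 0], s_l=10, secondaries_per_step=1)
        assert td.survival_area(res) + td.extinction_area(res) == pytest.approx(1.0)


class TestCascadeClassification:
    def test_sole_resource_loss_is_bottom_up_direct(self):
        adj = np.zeros((3, 3))
        adj[0, 1] = 1.0  # removed node 0 feeds node 1
        c = td.classify_cascade(adj, 0, 1)
        assert (c.direction, c.proximity) == ("bottom-up", "direct")

    def test_consumer_of_consumer_is_top_down_indirect(self):
        # chain 0 -> 1 -> 2; removing 2 (top predator) starves nobody below,
        # but a loss of 0 upstream of it classifies top-down / indirect
        adj = np.zeros((3, 3))
        adj[0, 1] = 1.0
        adj[1, 2] = 1.0
        c = td.classify_cascade(adj, 2, 0)
        assert (c.direction, c.proximity) == ("top-down", "indirect")

    def test_cycle_fixture_documented_pair_is_mixed_indirect(self, cycle):
        removed, extinct = td.FIXTURE_CYCLE_MIXED_PAIR
        c = td.classify_cascade(cycle, removed, extinct)
        assert (c.direction, c.proximity) == ("mixed", "indirect")

    def test_direct_agrees_with_distance_one_exactly(self, cycle):
        adj = cycle.F > 0
        for r in range(cycle.S):
            for e in range(cycle.S):
                if r == e:
                    continue
                c = td.classify_cascade(cycle, cycle.node_ids[r], cycle.node_ids[e])
                assert (c.proximity == "direct") == bool(adj[r, e] or adj[e, r])


class TestRatios:
    def test_hand_computed_four_node_case(self):
        # snapshot: 0 -> 1 (2.0), 2 -> 1 (1.0), 2 -> 3 (1.0); extinct = 0
        F = np.zeros((4, 4))
        F[0, 1] = 2.0
        F[2, 1] = 1.0
        F[2, 3] = 1.0
        # degrees: node0 = 1, survivors 1,2,3 have degrees 2, 2, 1 (mean 5/3)
        # weights: node0 = 2, survivors carry 3, 2, 1 (mean 2)
        dr, wr = td.extinct_vs_survivor_ratios(F, 0, [1, 2, 3])
        assert dr == pytest.approx(np.log10(1 / (5 / 3)))
        assert wr == pytest.approx(np.log10(2 / 2))

    def test_equal_to_mean_gives_zero(self):
        F = np.zeros((3, 3))
        F[0, 1] = 1.0
        F[1, 2] = 1.0
        dr, wr = td.extinct_vs_survivor_ratios(F, 0, [2])
        assert dr == pytest.approx(0.0)  # degree 1 vs mean degree 1
        assert wr == pytest.approx(0.0)  # weight 1 vs mean weight 1


class TestDeletionSequence:
    def test_independent_producers_no_secondaries(self):
        # four producers sharing only the carrying capacity: S_l primary steps,
        # zero secondaries, SA at the no-cascade closed form
        n = 5
        ids = [f"p{k}" for k in range(4)] + ["det"]
        F = np.zeros((n, n))
        for k in range(4):
            F[k, 4] = 0.05
        net = td.make_network(ids, ids, ["producer"] * 4 + ["detritus"],
                              np.ones(n), [0.25] * 4 + [0.0], [0.2] * 4 + [0.0],
                              np.zeros(n), np.zeros(n), F)
        res = td.run_deletion_sequence(net, "max_d", "linear")
        assert len(res.steps) == 4
        assert all(not s.secondary for s in res.steps)
        assert res.s_l == 4
        assert res.sa == pytest.approx(0.375)
        assert res.r50 == pytest.approx(0.5)

    def test_specialist_starves_after_resource_removal(self, starvation_web):
        res = td.run_deletion_sequence(starvation_web, "max_d", "linear")
        assert res.s_l == 10
        # every primary producer removal starves exactly its specialist
        first = res.steps[0]
        assert first.removed == "a_pro0"
        assert [s.node_id for s in first.secondary] == ["z_con0"]
        sec = first.secondary[0]
        assert (sec.cascade.direction, sec.cascade.proximity) == ("bottom-up", "direct")
        assert res.r50 == pytest.approx(0.3)
        assert td.survival_area(res) + td.extinction_area(res) == pytest.approx(1.0)

    def test_survivors_non_increasing_and_losses_complete(self, balanced20):
        res = td.run_deletion_sequence(balanced20, "max_wdi", "nonlinear")
        survivors = [s.n_survivors for s in res.steps]
        assert all(a >= b for a, b in zip(survivors, survivors[1:]))
        assert survivors[-1] == 0
        losses = sum(1 + len(s.secondary) for s in res.steps)
        assert losses == res.s_l
        assert td.survival_area(res) + td.extinction_area(res) == pytest.approx(1.0)

    def test_removed_was_top_ranked(self, balanced20):
        res = td.run_deletion_sequence(balanced20, "max_wd", "nonlinear")
        for step in res.steps:
            assert step.removed == step.ranking[0]

    def test_deterministic_step_logs(self, balanced20):
        draw = td.draw_free_parameters(5)
        a = td.run_deletion_sequence(balanced20, "max_di", "nonlinear", draw)
        b = td.run_deletion_sequence(balanced20, "max_di", "nonlinear", draw)
        assert a.steps == b.steps
        assert (a.r50, a.sa) == (b.r50, b.sa)


@pytest.fixture(scope="module")
def small_web():
    return td.generate_web(td.GeneratorSpec(S=12, target_connectance=0.22, seed=7))


class TestMonteCarlo:
    def test_reproducible_tables(self, small_web):
        a = td.monte_carlo(small_web, ["max_d"], "linear", n_reps=3, base_seed=9)
        b = td.monte_carlo(small_web, ["max_d"], "linear", n_reps=3, base_seed=9)
        assert a.results.equals(b.results)
        assert a.events.equals(b.events)

    def test_metric_bounds_and_draw_columns(self, small_web):
        mc = td.monte_carlo(small_web, ["max_d", "max_wd"], "nonlinear",
                            n_reps=3, base_seed=2)
        df = mc.results
        assert len(df) == 6
        ok = df[~df.collapsed]
        assert ((ok.r50 > 0) & (ok.r50 <= 1)).all()
        assert ((ok.sa >= 0) & (ok.sa < 1)).all()
        assert ((df.h >= 1) & (df.h <= 2)).all()
        assert ((df.q >= 0) & (df.q <= 100)).all()

    def test_kinds_get_independent_draws(self, small_web):
        mc = td.monte_carlo(small_web, ["max_d", "max_di"], "linear",
                            n_reps=2, base_seed=5)
        by_kind = {k: g[["h", "k0", "b", "q"]].to_numpy()
                   for k, g in mc.results.groupby("kind")}
        assert not np.allclose(by_kind["max_d"], by_kind["max_di"])
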