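"""Dominance, Pareto filtering and epsilon-constraint sampling."""

import numpy as np
import pytest

from pareto_metab import (
    GridSpec,
    ObjectiveVector,
    ParetoSet,
    dominates,
    epsilon_constraint_sample,
    lexicographic_cleanup,
    pareto_filter,
)
from pareto_metab.lp import AffineConstraint
from pareto_metab.model import MetabolicNetwork, Metabolite, Reaction
from pareto_metab.gpr import Gpr
from pareto_metab.objectives import OBJECTIVE_SENSES, build_objectives


def _brute_force_front(points):
    """O(n^2) literal implementation of the dominance definition."""
    P = np.asarray(points) * OBJECTIVE_SENSES
    keep = []
    for i in range(len(P)):
        dominated = any(
            np.all(P[j] >= P[i]) and np.any(P[j] > P[i])
            for j in range(len(P))
            if j != i
        )
        if not dominated:
            keep.append(i)
    return keep


class TestDominance:
    def test_better_everywhere_dominates(self):
        a = ObjectiveVector(2, 2, 1, 1)
        b = ObjectiveVector(1, 1, 2, 2)
        assert dominates(a, b) and not dominates(b, a)

    def test_equal_points_do_not_dominate(self):
        a = ObjectiveVector(1, 1, 1, 1)
        assert not dominates(a, a)

    def test_trade_off_is_incomparable(self):
        a = ObjectiveVector(2, 1, 1, 1)
        b = ObjectiveVector(1, 2, 1, 1)
        assert not dominates(a, b) and not dominates(b, a)

    def test_minimized_axes_oriented_correctly(self):
        cheap = ObjectiveVector(1, 1, 0.5, 1)
        dear = ObjectiveVector(1, 1, 1.0, 1)
        assert dominates(cheap, dear)


class TestParetoFilter:
    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(11)
        pts = rng.uniform(0, 1, size=(50, 4))
        assert sorted(pareto_filter(pts).tolist()) == _brute_force_front(pts)

    def test_larger_random_set(self):
        rng = np.random.default_rng(5)
        pts = rng.uniform(0, 1, size=(300, 4))
        assert sorted(pareto_filter(pts).tolist()) == _brute_force_front(pts)

    def test_all_identical_points_retained(self):
        pts = np.ones((5, 4))
        assert len(pareto_filter(pts)) == 5

    def test_duplicates_of_survivors_retained(self):
        pts = np.array([[2, 2, 1, 1], [2, 2, 1, 1], [1, 1, 2, 2]], dtype=float)
        assert sorted(pareto_filter(pts).tolist()) == [0, 1]


class TestEpsilonConstraintSampling:
    def test_front_members_mutually_undominated(self, fr_front):
        P = fr_front.objectives
        idx = pareto_filter(P, tol=1e-6)
        assert len(idx) == len(P)

    def test_chain_net_front_is_one_ray(self, chain_net):
        ps = epsilon_constraint_sample(chain_net, grid=GridSpec(levels=5))
        # no trade-off: every solution proportional to the biomass-max ray
        fluxes = ps.flux_matrix()
        ref = fluxes[np.argmax(np.abs(fluxes).sum(axis=1))]
        for row in fluxes:
            scale = (row @ ref) / (ref @ ref)
            assert np.allclose(row, scale * ref, atol=1e-5)

    def test_front_stability_under_grid_refinement(self, y_net):
        coarse = epsilon_constraint_sample(y_net, grid=GridSpec(levels=4))
        fine = epsilon_constraint_sample(y_net, grid=GridSpec(levels=8))
        # refining never loses previously found non-dominated vectors:
        # each coarse point stays undominated within the pooled set
        pooled = np.vstack([coarse.objectives, fine.objectives])
        keep = set(pareto_filter(pooled, tol=1e-6).tolist())
        assert set(range(len(coarse.objectives))) <= keep

    def test_two_objective_restriction_matches_yield_line(self, y_net):
        # biomass/ATP trade-off of the Y-net: b + atp/2 = 10 on the
        # efficient line at full uptake
        ps = epsilon_constraint_sample(y_net, grid=GridSpec(levels=8))
        full = ps.objectives[ps.objectives[:, 3] > 60 - 1e-3]
        assert len(full) >= 3
        assert np.allclose(full[:, 0] + full[:, 1] / 2.0, 10.0, atol=1e-3)

    def test_infeasible_cells_counted_not_fatal(self, y_net):
        ps = epsilon_constraint_sample(y_net, grid=GridSpec(levels=5))
        assert ps.n_infeasible_cells > 0
        assert len(ps) > 0

    def test_persistence_roundtrip(self, tmp_path, y_front):
        out = y_front.to_dir(tmp_path / "front")
        again = ParetoSet.from_dir(out)
        assert np.allclose(again.objectives, y_front.objectives)
        assert np.allclose(again.flux_matrix(), y_front.flux_matrix())
        assert (out / "manifest.json").exists()


class TestLexicographicCleanup:
    def _cycle_net(self):
        # futile A<->B cycle rides along the biomass optimum for free
        mets = [Metabolite("s_e", is_extracellular=True), Metabolite("a_c"),
                Metabolite("b_c"), Metabolite("atp_c")]
        rxns = [
            Reaction("EX_s", {"s_e": -1.0}, -10, 0),
            Reaction("T", {"s_e": -1.0, "a_c": 1.0}, 0, 100, Gpr.from_string("gt")),
            Reaction("CYC1", {"a_c": -1.0, "b_c": 1.0}, 0, 100, Gpr.from_string("gc1")),
            Reaction("CYC2", {"b_c": -1.0, "a_c": 1.0}, 0, 100, Gpr.from_string("gc2")),
            Reaction("biomass", {"a_c": -1.0}, 0, 100, Gpr.from_string("gb")),
            Reaction("ATPM", {"atp_c": -1.0}, 0, 100),
        ]
        return MetabolicNetwork(mets, rxns, "biomass", "ATPM")

    def test_futile_cycle_driven_to_zero(self):
        net = self._cycle_net()
        objs = build_objectives(net)
        sol = lexicographic_cleanup(net, [objs["biomass"], objs["enzyme_cost"]])
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
        assert sol.flux["CYC1"] == pytest.approx(0.0, abs=1e-7)
        assert sol.flux["CYC2"] == pytest.approx(0.0, abs=1e-7)

    def test_unique_optimum_unchanged(self, chain_net):
        objs = build_objectives(chain_net)
        from pareto_metab import fba_solve

        plain = fba_solve(chain_net, objs["biomass"])
        cleaned = lexicographic_cleanup(
            chain_net, [objs["biomass"], objs["enzyme_cost"]]
        )
        for rid in chain_net.reaction_ids:
            assert cleaned.flux[rid] == pytest.approx(plain.flux[rid], abs=1e-6)

    def test_parallel_paths_concentrated_total_unchanged(self, parallel_net):
        objs = build_objectives(parallel_net)
        cons = [AffineConstraint(objs["atp"], ">=", 10.0)]
        sol = lexicographic_cleanup(
            parallel_net, [objs["biomass"], objs["enzyme_cost"]], cons
        )
        a, a2 = sol.flux["ATP_SYN"], sol.flux["ATP_SYN2"]
        assert a + a2 == pytest.approx(5.0, abs=1e-5)  # ATP 10 at yield 2
        assert min(a, a2) == pytest.approx(0.0, abs=1e-6)  # concentrated
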