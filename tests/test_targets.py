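"""Pareto-surface projection, monotonousness and target classification."""

import numpy as np
import pytest

from pareto_metab import (
    bh_adjust,
    boundary_proximity,
    category_overlap,
    classify_targets,
    monotonousness,
    project,
    warburg_metric,
)
from pareto_metab.errors import ConfigurationError
from pareto_metab.lp import OPTIMAL, FluxConfiguration
from pareto_metab.pareto import ParetoSet
from pareto_metab.targets import calls_table


class TestWarburgMetric:
    def test_simple_ratio(self, ferm_resp_net):
        flux = {rid: 0.0 for rid in ferm_resp_net.reaction_ids}
        flux.update(EX_lac=10.0, EX_o2=-5.0)
        assert warburg_metric(ferm_resp_net, flux) == pytest.approx(2.0)

    def test_zero_lactate_is_zero(self, ferm_resp_net):
        flux = {rid: 0.0 for rid in ferm_resp_net.reaction_ids}
        flux.update(EX_o2=-5.0)
        assert warburg_metric(ferm_resp_net, flux) == 0.0

    def test_anaerobic_secretion_capped(self, ferm_resp_net):
        flux = {rid: 0.0 for rid in ferm_resp_net.reaction_ids}
        flux.update(EX_lac=3.0)
        assert warburg_metric(ferm_resp_net, flux) == pytest.approx(1e3)

    def test_idle_configuration_undefined(self, ferm_resp_net):
        flux = {rid: 0.0 for rid in ferm_resp_net.reaction_ids}
        assert np.isnan(warburg_metric(ferm_resp_net, flux))

    def test_fermentation_vertex_exceeds_respiration_vertex(self, ferm_resp_net):
        from pareto_metab import build_objectives, fba_solve
        from pareto_metab.lp import AffineConstraint

        objs = build_objectives(ferm_resp_net)
        ferm = fba_solve(
            ferm_resp_net, objs["atp"],
            [AffineConstraint(objs["carbon_uptake"], "<=", 100.0)],
        )
        resp = fba_solve(ferm_resp_net, objs["carbon_uptake"],
                         [AffineConstraint(objs["atp"], ">=", 5.0)])
        assert warburg_metric(ferm_resp_net, ferm) > warburg_metric(ferm_resp_net, resp)

    def test_missing_exchange_is_configuration_error(self, y_net):
        flux = {rid: 0.0 for rid in y_net.reaction_ids}
        with pytest.raises(ConfigurationError):
            warburg_metric(y_net, flux)


def _front_from_points(pheno_flux):
    """Synthetic 'front' whose biomass is the phenotype and a reaction 'r'
    carries the projected flux (for envelope-geometry unit tests)."""
    fluxes = [
        FluxConfiguration({"r": float(f), "biomass": float(p)}, OPTIMAL)
        for p, f in pheno_flux
    ]
    objectives = np.array([[p, 0.0, 0.0, 0.0] for p, _ in pheno_flux])
    return ParetoSet(fluxes, objectives, reaction_ids=["biomass", "r"])


class TestProjection:
    def test_identity_band_collapses_to_identity_line(self, y_net, y_front):
        # biomass-path flux equals growth rate, so both envelopes trace the
        # identity: per bin they equal the phenotype extremes of that bin,
        # and both rise perfectly
        proj = project(y_front, y_net, "growth", "g_bio", n_bins=8)
        pheno = proj.points[:, 0]
        for b, (lo, hi) in enumerate(zip(proj.lower_envelope, proj.upper_envelope)):
            in_bin = np.array([proj.bin_of(p) == b for p in pheno])
            assert lo == pytest.approx(pheno[in_bin].min(), abs=1e-4)
            assert hi == pytest.approx(pheno[in_bin].max(), abs=1e-4)
        assert monotonousness(proj, "lower") == pytest.approx(1.0)
        assert monotonousness(proj, "upper") == pytest.approx(1.0)

    def test_free_flux_yields_flat_envelopes(self, parallel_net, parallel_front):
        # ATPM carries no gene; project its reaction flux against growth:
        # at any growth the ATP drain spans the full range, envelopes flat-ish
        proj = project(parallel_front, parallel_net, "growth", "ATPM", n_bins=5)
        assert monotonousness(proj, "lower") <= 0.1

    def test_envelope_containment(self, ferm_resp_net, fr_front):
        proj = project(fr_front, ferm_resp_net, "warburg", "g_resp", n_bins=10)
        for pheno, fluxval in proj.points:
            b = proj.bin_of(pheno)
            assert proj.lower_envelope[b] - 1e-9 <= fluxval <= proj.upper_envelope[b] + 1e-9

    def test_too_few_solutions_rejected(self, y_net, y_front):
        from pareto_metab.errors import InsufficientDataError

        small = ParetoSet(y_front.fluxes[:4], y_front.objectives[:4],
                          reaction_ids=y_front.reaction_ids)
        with pytest.raises(InsufficientDataError):
            project(small, y_net, "growth", "g_bio", n_bins=5)


class TestMonotonousness:
    def test_strictly_increasing_lower_envelope_is_plus_one(self):
        front = _front_from_points([(p, p) for p in np.linspace(0, 1, 40)])
        proj = project(front, _dummy_net(), "growth", "r", n_bins=8)
        assert monotonousness(proj, "lower") == pytest.approx(1.0)

    def test_strictly_decreasing_upper_envelope_is_minus_one(self):
        front = _front_from_points([(p, 1 - p) for p in np.linspace(0, 1, 40)])
        proj = project(front, _dummy_net(), "growth", "r", n_bins=8)
        assert monotonousness(proj, "upper") == pytest.approx(-1.0)

    def test_noise_envelope_scores_near_zero(self):
        rng = np.random.default_rng(17)
        pts = [(p, float(rng.uniform(0, 1))) for p in np.linspace(0, 1, 400)]
        front = _front_from_points(pts)
        proj = project(front, _dummy_net(), "growth", "r", n_bins=20)
        assert abs(monotonousness(proj, "upper")) < 0.5

    def test_constant_envelope_is_zero_by_convention(self):
        front = _front_from_points([(p, 1.0) for p in np.linspace(0, 1, 30)])
        proj = project(front, _dummy_net(), "growth", "r", n_bins=6)
        assert monotonousness(proj, "upper") == 0.0


def _dummy_net():
    from pareto_metab.model import MetabolicNetwork, Metabolite, Reaction

    mets = [Metabolite("x_c")]
    rxns = [
        Reaction("biomass", {"x_c": 1.0}, 0, 10),
        Reaction("r", {"x_c": -1.0}, 0, 10),
        Reaction("ATPM", {"x_c": -1.0}, 0, 10),
    ]
    return MetabolicNetwork(mets, rxns, "biomass", "ATPM")


class TestBoundaryProximity:
    def _band_projection(self):
        # band: flux free in [0, 1] at every phenotype in [0, 1]
        rng = np.random.default_rng(3)
        pts = [(p, float(rng.uniform(0, 1))) for p in np.linspace(0, 1, 300)]
        pts += [(p, 0.0) for p in np.linspace(0, 1, 30)]
        pts += [(p, 1.0) for p in np.linspace(0, 1, 30)]
        front = _front_from_points(pts)
        return project(front, _dummy_net(), "growth", "r", n_bins=10)

    def test_points_on_envelope_score_one(self):
        proj = self._band_projection()
        on_upper = np.array([[p, 1.0] for p in np.linspace(0.05, 0.95, 10)])
        assert boundary_proximity(proj, on_upper, "upper", tol=0.1) == 1.0

    def test_mid_band_points_score_zero(self):
        proj = self._band_projection()
        mid = np.array([[p, 0.5] for p in np.linspace(0.05, 0.95, 10)])
        assert boundary_proximity(proj, mid, "upper", tol=0.1) == 0.0

    def test_jitter_within_tolerance_still_counts(self):
        proj = self._band_projection()
        rng = np.random.default_rng(8)
        jittered = np.array(
            [[p, 1.0 - float(rng.uniform(0, 0.08))] for p in np.linspace(0.05, 0.95, 20)]
        )
        assert boundary_proximity(proj, jittered, "upper", tol=0.15) == 1.0


class TestClassification:
    def test_ynet_biomass_enzyme_growth_promoting(self, y_net, y_front):
        from pareto_metab.cellline import fit_cell_line
        from pareto_metab.synthetic import make_synthetic_panel

        panel = make_synthetic_panel(y_net, y_front, 20, 0.05, seed=2)
        models = [fit_cell_line(y_net, y_front, p, top_fraction=0.05) for p in panel.profiles]
        calls = {
            c.enzyme_id: c
            for c in classify_targets(y_net, y_front, models, phenotypes=("growth",), n_bins=10)
        }
        assert calls["g_bio"].direction == "promoting"
        assert calls["g_bio"].monotonousness == pytest.approx(1.0)

    def test_ferm_resp_warburg_calls(self, ferm_resp_net, fr_front, fr_models):
        calls = {
            (c.enzyme_id, c.phenotype): c
            for c in classify_targets(ferm_resp_net, fr_front, fr_models, n_bins=12)
        }
        assert calls[("g_resp", "warburg")].direction == "suppressing"
        assert calls[("g_ferm", "warburg")].direction == "promoting"

    def test_isolated_enzyme_gets_no_direction(self, parallel_net, parallel_front):
        from pareto_metab.cellline import fit_cell_line
        from pareto_metab.synthetic import make_synthetic_panel

        panel = make_synthetic_panel(parallel_net, parallel_front, 10, 0.05, seed=3)
        models = [
            fit_cell_line(parallel_net, parallel_front, p, top_fraction=0.05)
            for p in panel.profiles
        ]
        calls = {
            c.enzyme_id: c
            for c in classify_targets(
                parallel_net, parallel_front, models, phenotypes=("growth",), n_bins=6
            )
        }
        # the salvage path never carries flux on the front: flat envelopes
        assert calls["g_salv"].direction == "none"

    def test_overlap_report_structure(self, ferm_resp_net, fr_front, fr_models):
        calls = classify_targets(ferm_resp_net, fr_front, fr_models, n_bins=12)
        report = category_overlap(calls)
        assert set(report) == {"categories", "counts", "overlaps", "ambiguous"}
        for key, members in report["categories"].items():
            assert report["counts"][key] == len(members)


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        # 0.01*3/1=0.03, 0.02*3/2=0.03, 0.03*3/3=0.03
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_ten_element_hand_computation(self):
        p = [0.001, 0.008, 0.039, 0.041, 0.042, 0.06, 0.074, 0.205, 0.212, 0.216]
        # step-up: adj_i = min_{j>=i} p_j * n / j (sorted), hand-computed
        expected = [0.01, 0.04, 0.084, 0.084, 0.084, 0.1, 0.105714285714286,
                    0.216, 0.216, 0.216]
        assert bh_adjust(p) == pytest.approx(expected)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_equal_unchanged(self):
        assert bh_adjust([0.5] * 6) == pytest.approx([0.5] * 6)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.2])
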