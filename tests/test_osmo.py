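"""Osmoadaptation case studies on the mini-halophile fixture."""

import pytest

from halofba.errors import MediumError, PathwayError
from halofba.fba import set_medium, solve_fba
from halofba.model import knock_out
from halofba.osmo import (
    BETAINE_PATHWAY_ECS,
    ECTOINE_PATHWAY_ECS,
    alanine_scenario,
    choline_betaine_sweep,
    ectoine_production_sweep,
    production_flux,
    verify_pathway,
)


def _without(model, rxn_id):
    out = model.copy()
    out.reactions = [r for r in out.reactions if r.id != rxn_id]
    return out


class TestVerifyPathway:
    def test_fixture_contains_all_nine_osmolyte_enzymes(self, mini):
        for ecs in (ECTOINE_PATHWAY_ECS, BETAINE_PATHWAY_ECS):
            report = verify_pathway(mini, ecs)
            assert report.missing == [] and report.complete

    def test_removing_ectoine_synthase_is_detected(self, mini):
        report = verify_pathway(_without(mini, "ECTS"), ECTOINE_PATHWAY_ECS)
        assert report.missing == ["4.2.1.108"] and not report.complete

    def test_one_isoenzyme_suffices_for_the_transaminase_step(self, mini):
        report = verify_pathway(_without(mini, "DAT_ALA"), ECTOINE_PATHWAY_ECS)
        assert report.missing == ["2.6.1.46"] and report.complete


class TestCholineBetaineSweep:
    def test_no_choline_means_no_betaine(self, mini):
        sweep = choline_betaine_sweep(mini, choline_rates=[0.0], with_fva=False)
        assert sweep.rows[0]["product_flux"] == pytest.approx(0.0, abs=1e-9)

    def test_fluxes_match_direct_lp_solutions(self, mini):
        sweep = choline_betaine_sweep(mini, glucose_rate=3.0, choline_rates=[0.5, 1.0], with_fva=False)
        for row in sweep.rows:
            uptakes = {"glucose": 3.0}
            if row["choline_uptake"] > 0:
                uptakes["choline"] = row["choline_uptake"]
            sol = solve_fba(mini, extra_constraints=set_medium(mini, uptakes))
            assert row["biomass"] == pytest.approx(sol.objective_value, abs=1e-9)
            assert row["product_flux"] == pytest.approx(sol.fluxes["BADH"], abs=1e-9)
            # with a fixed choline uptake and no other fate, betaine
            # production equals the uptake (hand stoichiometric analysis)
            assert row["product_flux"] == pytest.approx(row["choline_uptake"], abs=1e-6)

    def test_growth_increases_monotonically_with_choline(self, mini):
        sweep = choline_betaine_sweep(mini)
        biomass = sweep.column("biomass")
        assert all(b > a + 1e-9 for a, b in zip(biomass, biomass[1:]))
        products = sweep.column("product_flux")
        assert all(b >= a - 1e-9 for a, b in zip(products, products[1:]))

    def test_headline_fluxes_are_fva_certified_unique(self, mini):
        sweep = choline_betaine_sweep(mini, choline_rates=[0.0, 2.0])
        assert all(row["max_variability_pct"] < 0.1 for row in sweep.rows)

    def test_missing_pathway_aborts_before_any_lp(self, mini):
        with pytest.raises(PathwayError, match="1.2.1.8"):
            choline_betaine_sweep(_without(mini, "BADH"))


class TestEctoineProductionSweep:
    def test_zero_glucose_means_zero_ectoine(self, mini):
        sweep = ectoine_production_sweep(mini, glucose_rates=[0.0], with_fva=False)
        assert sweep.rows[0]["product_flux"] == pytest.approx(0.0, abs=1e-9)

    def test_ectoine_and_biomass_rise_together_with_glucose(self, mini):
        sweep = ectoine_production_sweep(mini, glucose_rates=[3, 5, 7, 10], with_fva=False)
        biomass, product = sweep.column("biomass"), sweep.column("product_flux")
        assert all(b > a + 1e-9 for a, b in zip(biomass, biomass[1:]))
        assert all(b > a + 1e-9 for a, b in zip(product, product[1:]))

    def test_yield_never_exceeds_the_direct_maximization_bound(self, mini):
        at_growth = ectoine_production_sweep(mini, glucose_rates=[1, 3], with_fva=False)
        at_max = ectoine_production_sweep(mini, glucose_rates=[1, 3], objective="ectoine", with_fva=False)
        for grow_row, max_row in zip(at_growth.rows, at_max.rows):
            assert grow_row["yield"] <= max_row["yield"] + 1e-9

    def test_direct_maximization_hits_the_hand_computed_stoichiometric_yield(self, mini):
        # per glucose: glycolysis gives 2 pyruvate + 2 ATP + 2 NADH; the
        # ectoine route consumes 2 pyruvate, 2 ATP and nets -2 NADH, so the
        # theoretical yield is exactly 1 mol ectoine / mol glucose
        sweep = ectoine_production_sweep(mini, glucose_rates=[1.0], objective="ectoine", with_fva=False)
        assert sweep.rows[0]["yield"] == pytest.approx(1.0, abs=1e-9)

    def test_choline_oxidation_knockout_ignores_an_offered_choline_pool(self, mini):
        ko = knock_out(mini, ["CDH", "CMO"])
        overrides = set_medium(ko, {"glucose": 3.0})
        overrides["EX_chol"] = (-2.0, 0.0)  # choline offered but not forced
        sol = solve_fba(ko, extra_constraints=overrides).raise_for_status()
        assert production_flux(ko, sol.fluxes, "bet[c]") == pytest.approx(0.0, abs=1e-9)
        assert sol.uptake("EX_chol") == pytest.approx(0.0, abs=1e-9)

    def test_missing_pathway_aborts(self, mini):
        with pytest.raises(PathwayError, match="2.3.1.178"):
            ectoine_production_sweep(_without(mini, "DAAT"))

    def test_fva_certifies_the_reported_fluxes(self, mini):
        sweep = ectoine_production_sweep(mini, glucose_rates=[3.0])
        assert sweep.rows[0]["max_variability_pct"] < 0.1


class TestAlanineScenario:
    def test_alanine_stimulates_growth_and_ectoine(self, mini):
        res = alanine_scenario(mini)
        assert res.supplemented_growth > res.baseline_growth
        assert res.supplemented_ectoine > res.baseline_ectoine
        assert res.growth_change_percent > 0 and res.ectoine_change_percent > 0

    def test_zero_alanine_reproduces_the_baseline(self, mini):
        res = alanine_scenario(mini, alanine_rate=0.0)
        assert res.supplemented_growth == pytest.approx(res.baseline_growth, abs=1e-9)
        assert res.growth_change_percent == pytest.approx(0.0, abs=1e-9)

    def test_missing_alanine_route_raises(self, mini):
        broken = _without(_without(mini, "EX_ala"), "T_ala")
        broken.metabolites = [m for m in broken.metabolites if m.id != "ala[e]"]
        with pytest.raises(MediumError, match="alanine"):
            alanine_scenario(broken)

    def test_percent_changes_use_reported_precision(self, mini):
        res = alanine_scenario(mini)
        b, t = round(res.baseline_growth, 4), round(res.supplemented_growth, 4)
        assert res.growth_change_percent == pytest.approx(100 * (t - b) / b)


def test_betaine_production_requires_a_choline_oxidation_route(mini):
    ko = knock_out(mini, ["CDH", "CMO"])
    sol = solve_fba(ko, extra_constraints=set_medium(ko, {"glucose": 3.0}))
    assert production_flux(ko, sol.fluxes, "bet[c]") == pytest.approx(0.0, abs=1e-9)
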