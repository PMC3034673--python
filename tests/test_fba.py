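"""FBA/FVA engine: analytic optima, oracle equivalence, media, invariants."""

import numpy as np
import pytest

from halofba.bruteforce import brute_force_fba_optimum
from halofba.errors import MediumError
from halofba.fba import flux_variability, resolve_exchange, set_medium, solve_fba
from halofba.model import MetabolicModel, Metabolite, Reaction, build_stoichiometric_matrix, knock_out
from halofba.synth import make_branched_toy, make_random_fba_toy, make_toy_chain


def steady_state_residual(model, solution):
    S = build_stoichiometric_matrix(model).S
    v = np.array([solution.fluxes[r.id] for r in model.reactions])
    return float(np.max(np.abs(S @ v), initial=0.0))


class TestSolveFba:
    def test_chain_optimum_is_the_uptake_bound(self, toy_chain3):
        sol = solve_fba(toy_chain3)
        assert sol.optimal and sol.objective_value == pytest.approx(5.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_vertex_enumeration_on_random_toys(self, seed):
        model, objective = make_random_fba_toy(seed)
        sol = solve_fba(model, objective_id=objective)
        assert sol.optimal
        ref = brute_force_fba_optimum(model, objective)
        assert sol.objective_value == pytest.approx(ref, abs=1e-6)

    def test_infeasible_is_reported_not_zero(self, toy_chain3):
        # force uptake of 3 while the transport step is knocked out
        dead = knock_out(toy_chain3, ["R1"])
        sol = solve_fba(dead, extra_constraints={"EX_A0": (-3.0, -3.0)})
        assert sol.status == "infeasible" and sol.objective_value is None

    def test_unbounded_is_reported_distinctly(self):
        model = MetabolicModel(
            metabolites=[Metabolite(id="a[e]", compartment="e")],
            reactions=[
                Reaction(id="SRC", stoichiometry={"a[e]": 1.0}, lower_bound=0.0, upper_bound=np.inf, kind="exchange"),
                Reaction(id="SNK", stoichiometry={"a[e]": -1.0}, lower_bound=0.0, upper_bound=np.inf, kind="exchange"),
            ],
        )
        sol = solve_fba(model, objective_id="SNK")
        assert sol.status == "unbounded" and sol.objective_value is None

    def test_steady_state_and_bounds_hold_at_the_optimum(self, mini):
        overrides = set_medium(mini, {"glucose": 3})
        sol = solve_fba(mini, extra_constraints=overrides)
        assert steady_state_residual(mini, sol) < 1e-8
        for rxn in mini.reactions:
            lo, hi = overrides.get(rxn.id, (rxn.lower_bound, rxn.upper_bound))
            assert lo - 1e-9 <= sol.fluxes[rxn.id] <= hi + 1e-9

    def test_relaxing_an_uptake_bound_never_decreases_the_optimum(self, mini):
        values = [
            solve_fba(mini, extra_constraints=set_medium(mini, {"glucose": r}, mode="max")).objective_value
            for r in (1.0, 2.0, 4.0, 8.0)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_single_limiting_substrate_scales_linearly(self, mini):
        g1 = solve_fba(mini, extra_constraints=set_medium(mini, {"glucose": 1})).objective_value
        g2 = solve_fba(mini, extra_constraints=set_medium(mini, {"glucose": 2})).objective_value
        assert g2 == pytest.approx(2 * g1, rel=1e-6)


class TestFva:
    def test_unique_optimum_chain_has_zero_spans(self, toy_chain3):
        res = flux_variability(toy_chain3)
        assert all(res.span(rid) == pytest.approx(0.0, abs=1e-6) for rid in res.v_min)

    def test_parallel_branches_span_their_capacity(self, branched):
        res = flux_variability(branched)
        assert res.objective_value == pytest.approx(5.0, abs=1e-9)
        for rid in ("BRANCH1", "BRANCH2", "JOIN1", "JOIN2"):
            assert res.span(rid) == pytest.approx(5.0, abs=1e-6)
        for rid in ("EX_A", "T_A", "BIOMASS"):
            assert res.span(rid) == pytest.approx(0.0, abs=1e-6)

    def test_open_sink_makes_the_split_unique_again(self):
        model = make_branched_toy(capacities=(5.0, 5.0), sink_bound=10.0)
        res = flux_variability(model)
        assert res.objective_value == pytest.approx(10.0, abs=1e-9)
        assert res.span("BRANCH1") == pytest.approx(0.0, abs=1e-6)

    def test_closing_one_branch_removes_the_degeneracy(self, branched):
        closed = knock_out(branched, ["BRANCH2"])
        res = flux_variability(closed)
        assert res.span("BRANCH1") == pytest.approx(0.0, abs=1e-6)

    def test_sandwich_and_objective_preservation(self, mini):
        overrides = set_medium(mini, {"glucose": 3})
        sol = solve_fba(mini, extra_constraints=overrides)
        res = flux_variability(mini, extra_constraints=overrides)
        for rid in res.v_min:
            assert res.v_min[rid] - 1e-6 <= sol.fluxes[rid] <= res.v_max[rid] + 1e-6
        # pinning any reaction at an FVA extreme still admits the optimum
        for rid in ("GLYC", "OXPHOS", "ECTS"):
            for extreme in (res.v_min[rid], res.v_max[rid]):
                pinned = dict(overrides)
                pinned[rid] = (extreme - 1e-6, extreme + 1e-6)
                again = solve_fba(mini, extra_constraints=pinned)
                assert again.optimal
                assert again.objective_value == pytest.approx(sol.objective_value, abs=1e-4)

    @pytest.mark.parametrize("fraction", [0.0, -0.5, 1.5])
    def test_fraction_outside_unit_interval_is_rejected(self, toy_chain3, fraction):
        with pytest.raises(ValueError):
            flux_variability(toy_chain3, fraction=fraction)

    def test_relaxed_fraction_widens_ranges(self, mini):
        overrides = set_medium(mini, {"glucose": 3})
        tight = flux_variability(mini, extra_constraints=overrides, reactions=["GLYC"], fraction=1.0)
        loose = flux_variability(mini, extra_constraints=overrides, reactions=["GLYC"], fraction=0.5)
        assert loose.span("GLYC") >= tight.span("GLYC") - 1e-9


class TestSetMedium:
    def test_zero_carbon_medium_gives_zero_growth(self, mini):
        sol = solve_fba(mini, extra_constraints=set_medium(mini, {}))
        assert sol.optimal and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_fixed_uptake_is_respected(self, mini):
        sol = solve_fba(mini, extra_constraints=set_medium(mini, {"glucose": 3}))
        assert sol.uptake("EX_glc") == pytest.approx(3.0, abs=1e-9)

    def test_unknown_substrate_names_the_substrate(self, mini):
        with pytest.raises(MediumError, match="adonitol"):
            set_medium(mini, {"adonitol": 1.0})

    def test_anaerobic_nitrate_medium_grows_slower_than_aerobic(self, mini):
        aerobic = solve_fba(mini, extra_constraints=set_medium(mini, {"glucose": 3}))
        anaerobic = solve_fba(
            mini, extra_constraints=set_medium(mini, {"glucose": 3, "oxygen": 0, "nitrate": 1}, aerobic=False)
        )
        assert anaerobic.optimal and 0 < anaerobic.objective_value < aerobic.objective_value
        assert anaerobic.uptake("EX_o2") == pytest.approx(0.0, abs=1e-9)
        assert anaerobic.uptake("EX_no3") == pytest.approx(1.0, abs=1e-9)

    def test_max_mode_caps_instead_of_fixing(self, mini):
        sol = solve_fba(mini, extra_constraints=set_medium(mini, {"glucose": 3}, mode="max"))
        assert sol.uptake("EX_glc") <= 3.0 + 1e-9

    def test_resolves_by_name_id_or_reaction(self, mini):
        assert resolve_exchange(mini, "glucose").id == "EX_glc"
        assert resolve_exchange(mini, "glc").id == "EX_glc"
        assert resolve_exchange(mini, "EX_glc").id == "EX_glc"
        assert resolve_exchange(mini, "unobtainium") is None


def test_cobrapy_cross_check_on_the_mini_halophile(mini):
    """Independent solver route: the same model built in cobrapy agrees."""
    import cobra

    cm = cobra.Model("mini")
    mets = {}
    for met in mini.metabolites:
        cmet = cobra.Metabolite(met.id, formula=met.formula, charge=met.charge, compartment=met.compartment)
        mets[met.id] = cmet
    overrides = set_medium(mini, {"glucose": 3})
    for rxn in mini.reactions:
        cr = cobra.Reaction(rxn.id)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        lo, hi = overrides.get(rxn.id, (rxn.lower_bound, rxn.upper_bound))
        cr.bounds = (lo, hi)
    cm.objective = "BIOMASS"
    ref = cm.optimize()
    ours = solve_fba(mini, extra_constraints=overrides)
    assert ours.objective_value == pytest.approx(ref.objective_value, abs=1e-6)
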