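"""Dead ends, mass/charge balance, adjacency, statistics, model comparison."""

import numpy as np
import pytest

from halofba.curation import (
    adjacency_matrices,
    audit_model,
    check_mass_charge_balance,
    compare_models,
    find_dead_ends,
    network_statistics,
)
from halofba.errors import FormulaError
from halofba.model import MetabolicModel, Metabolite, Reaction
from halofba.synth import GeneratorSpec, make_random_network, make_toy_chain


def brute_force_dead_ends(model):
    """Independent double loop over (metabolite, reaction) pairs."""
    out = []
    for met in model.metabolites:
        produced = consumed = False
        for rxn in model.reactions:
            coeff = rxn.stoichiometry.get(met.id)
            if coeff is None:
                continue
            if rxn.reversible or coeff > 0:
                produced = True
            if rxn.reversible or coeff < 0:
                consumed = True
        if not produced:
            out.append((met.id, "no-producer"))
        if not consumed:
            out.append((met.id, "no-consumer"))
    return out


class TestDeadEnds:
    def test_chain_with_exchanges_has_no_dead_ends(self, toy_chain3):
        assert find_dead_ends(toy_chain3) == []

    def test_missing_intermediate_step_is_localized(self):
        # a sugar can enter and its 6-phosphate can be consumed, but the
        # kinase linking them is absent: both halves report a gap
        mets = [
            Metabolite(id="tag[e]", compartment="e", name="tagatose"),
            Metabolite(id="tag[c]", name="tagatose"),
            Metabolite(id="tag6p[c]", name="tagatose 6-phosphate"),
            Metabolite(id="tbp[c]", name="tagatose 1,6-bisphosphate"),
        ]
        rxns = [
            Reaction(id="EX_tag", stoichiometry={"tag[e]": -1.0}, reversible=True, kind="exchange"),
            Reaction(id="T_tag", stoichiometry={"tag[e]": -1.0, "tag[c]": 1.0}, kind="transport"),
            # tagatose-6-phosphate kinase present, tagatose kinase missing
            Reaction(id="T6PK", stoichiometry={"tag6p[c]": -1.0, "tbp[c]": 1.0}),
            Reaction(id="SINK_tbp", stoichiometry={"tbp[c]": -1.0}),
        ]
        gaps = dict(find_dead_ends(MetabolicModel(metabolites=mets, reactions=rxns)))
        assert gaps["tag[c]"] == "no-consumer"
        assert gaps["tag6p[c]"] == "no-producer"

    @pytest.mark.parametrize("seed", range(6))
    def test_injected_orphans_are_recovered_exactly(self, seed):
        model, truth = make_random_network(GeneratorSpec(seed=seed, m=10, n=18, dead_end_fraction=0.4))
        assert sorted(find_dead_ends(model)) == sorted(truth.dead_ends)

    @pytest.mark.parametrize("seed", range(6))
    def test_agrees_with_brute_force_double_loop(self, seed):
        model, _ = make_random_network(
            GeneratorSpec(seed=seed + 100, m=12, n=24, dead_end_fraction=0.3, unbalanced_fraction=0.2)
        )
        assert sorted(find_dead_ends(model)) == sorted(brute_force_dead_ends(model))


def _met(mid, formula, charge):
    return Metabolite(id=mid, formula=formula, charge=charge)


GLUCOKINASE_REGISTRY = {
    "glc[c]": _met("glc[c]", "C6H12O6", 0),
    "atp[c]": _met("atp[c]", "C10H12N5O13P3", -4),
    "g6p[c]": _met("g6p[c]", "C6H11O9P", -2),
    "adp[c]": _met("adp[c]", "C10H12N5O10P2", -3),
    "h[c]": _met("h[c]", "H", 1),
}


class TestMassChargeBalance:
    def test_glucokinase_misses_exactly_one_proton(self):
        rxn = Reaction(id="GLK", stoichiometry={"glc[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1})
        report = check_mass_charge_balance(rxn, GLUCOKINASE_REGISTRY)
        assert report.status == "unbalanced"
        assert report.element_deficit == {"H": -1.0}
        assert report.charge_deficit == -1.0

    def test_adding_the_proton_balances_glucokinase(self):
        rxn = Reaction(
            id="GLK", stoichiometry={"glc[c]": -1, "atp[c]": -1, "g6p[c]": 1, "adp[c]": 1, "h[c]": 1}
        )
        report = check_mass_charge_balance(rxn, GLUCOKINASE_REGISTRY)
        assert report.balanced and report.element_deficit == {} and report.charge_deficit == 0.0

    def test_reversing_a_reaction_negates_the_deficit(self):
        rxn = Reaction(id="F", stoichiometry={"glc[c]": -1, "g6p[c]": 1})
        rev = Reaction(id="R", stoichiometry={"glc[c]": 1, "g6p[c]": -1})
        a = check_mass_charge_balance(rxn, GLUCOKINASE_REGISTRY)
        b = check_mass_charge_balance(rev, GLUCOKINASE_REGISTRY)
        assert a.element_deficit == {el: -v for el, v in b.element_deficit.items()}
        assert a.charge_deficit == -b.charge_deficit

    def test_missing_formula_yields_unknown_not_unbalanced(self):
        registry = dict(GLUCOKINASE_REGISTRY, **{"x[c]": _met("x[c]", None, None)})
        rxn = Reaction(id="U", stoichiometry={"glc[c]": -1, "x[c]": 1})
        report = check_mass_charge_balance(rxn, registry)
        assert report.status == "unknown" and report.unknown_metabolites == ["x[c]"]

    def test_unparseable_formula_names_the_metabolite(self):
        registry = {"bad[c]": _met("bad[c]", "C6H?", 0)}
        with pytest.raises(FormulaError, match="bad"):
            check_mass_charge_balance(Reaction(id="B", stoichiometry={"bad[c]": 1}), registry)

    @pytest.mark.parametrize("seed", range(5))
    def test_injected_water_imbalance_detected_with_exact_deficit(self, seed):
        model, truth = make_random_network(GeneratorSpec(seed=seed, m=10, n=20, unbalanced_fraction=0.3))
        report = audit_model(model)
        flagged = {b.reaction_id: b.element_deficit for b in report.unbalanced_reactions}
        assert flagged == truth.imbalances


class TestAdjacency:
    def test_single_reaction_links_exactly_one_pair(self):
        model = MetabolicModel(
            metabolites=[Metabolite(id="a[c]"), Metabolite(id="b[c]"), Metabolite(id="c[c]")],
            reactions=[Reaction(id="R", stoichiometry={"a[c]": -1.0, "b[c]": 1.0})],
        )
        met_adj, _ = adjacency_matrices(model)
        assert met_adj.sum() == 2 and met_adj[0, 1] == met_adj[1, 0] == 1

    def test_chain_reaction_adjacency_is_a_path_graph(self):
        model = make_toy_chain(length=4, uptake_bound=1.0)
        _, rxn_adj = adjacency_matrices(model)
        # EX-R1-R2-R3-R4-BIOMASS share metabolites only with their neighbors
        expected = np.zeros_like(rxn_adj)
        for i in range(len(model.reactions) - 1):
            expected[i, i + 1] = expected[i + 1, i] = 1
        np.testing.assert_array_equal(rxn_adj, expected)

    @pytest.mark.parametrize("seed", range(4))
    def test_symmetry_and_zero_diagonal(self, seed):
        model, _ = make_random_network(GeneratorSpec(seed=seed, m=9, n=16, dead_end_fraction=0.2))
        for mat in adjacency_matrices(model):
            np.testing.assert_array_equal(mat, mat.T)
            assert np.trace(mat) == 0


class TestNetworkStatistics:
    def test_mini_halophile_counts_are_sum_consistent(self, mini):
        stats = network_statistics(mini)
        assert stats.metabolites == len(mini.metabolites)
        assert stats.intracellular_metabolites + stats.extracellular_metabolites == stats.metabolites
        assert sum(stats.reactions_by_kind.values()) == stats.reactions == len(mini.reactions)
        assert stats.genes == len(mini.all_genes())
        assert abs(sum(stats.subsystem_distribution.values()) - 1.0) < 1e-9
        # every EC in the fixture maps to exactly one reaction
        assert stats.monofunctional_fraction == 1.0

    def test_shared_ec_number_makes_the_enzyme_multifunctional(self):
        mets = [Metabolite(id="a[c]"), Metabolite(id="b[c]"), Metabolite(id="c[c]")]
        rxns = [
            Reaction(id="R1", stoichiometry={"a[c]": -1.0, "b[c]": 1.0}, ec_numbers=["1.1.1.1"]),
            Reaction(id="R2", stoichiometry={"b[c]": -1.0, "c[c]": 1.0}, ec_numbers=["1.1.1.1"]),
        ]
        stats = network_statistics(MetabolicModel(metabolites=mets, reactions=rxns))
        assert stats.monofunctional_fraction == 0.0

    def test_statistics_are_permutation_invariant(self, mini):
        shuffled = mini.copy()
        rng = np.random.default_rng(3)
        shuffled.reactions = [shuffled.reactions[i] for i in rng.permutation(len(shuffled.reactions))]
        shuffled.metabolites = [shuffled.metabolites[i] for i in rng.permutation(len(shuffled.metabolites))]
        a, b = network_statistics(mini), network_statistics(shuffled)
        assert a.reactions_by_kind == b.reactions_by_kind
        assert a.subsystem_distribution == b.subsystem_distribution
        assert a.monofunctional_fraction == b.monofunctional_fraction


class TestCompareModels:
    def test_model_vs_itself_shares_everything(self, mini):
        res = compare_models(mini, mini)
        assert res.unique_a == [] and res.unique_b == []

    def test_renamed_copy_with_same_formulas_is_fully_shared(self, mini):
        renamed = mini.copy()
        mapping = {m.id: f"met{i}[{m.compartment}]" for i, m in enumerate(renamed.metabolites)}
        for met in renamed.metabolites:
            met.id = mapping[met.id]
        for rxn in renamed.reactions:
            rxn.stoichiometry = {mapping[k]: v for k, v in rxn.stoichiometry.items()}
            rxn.id = f"x_{rxn.id}"
        res = compare_models(mini, renamed)
        assert res.unique_a == [] and res.unique_b == []
        # symmetric in its arguments
        rev = compare_models(renamed, mini)
        assert rev.n_shared == res.n_shared

    def test_disjoint_toys_share_nothing(self):
        a, _ = make_random_network(GeneratorSpec(seed=1, m=6, n=8))
        b = make_toy_chain(2, 1.0)
        res = compare_models(a, b)
        assert res.shared_a == [] and res.shared_b == []


def test_mini_halophile_audit_is_clean(mini):
    report = audit_model(mini)
    assert report.clean
    assert report.unknown_composition_reactions == []
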