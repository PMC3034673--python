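import math

import pytest

from halofba.synth import make_branched_toy, make_mini_halophile, make_toy_chain


@pytest.fixture(scope="session")
def mini():
    return make_mini_halophile()


@pytest.fixture()
def toy_chain3():
    """Minimal 3-reaction chain: exchange (<=5), transport, biomass drain."""
    return make_toy_chain(length=1, uptake_bound=5.0)


@pytest.fixture()
def branched():
    """Two parallel capacity-5 branches into a capacity-5 sink: degenerate optimum."""
    return make_branched_toy(capacities=(5.0, 5.0), sink_bound=5.0)


def assert_models_equal(a, b, tol=1e-9):
    """Field-by-field equality of two models (floats within tolerance)."""
    assert [m.id for m in a.metabolites] == [m.id for m in b.metabolites]
    assert [r.id for r in a.reactions] == [r.id for r in b.reactions]
    assert a.objective_id == b.objective_id
    assert sorted(a.all_genes()) == sorted(b.all_genes())
    for ma, mb in zip(a.metabolites, b.metabolites):
        assert (ma.name, ma.compartment, ma.formula, ma.charge) == (mb.name, mb.compartment, mb.formula, mb.charge)
    for ra, rb in zip(a.reactions, b.reactions):
        assert ra.reversible == rb.reversible and ra.kind == rb.kind
        assert ra.ec_numbers == rb.ec_numbers
        assert ra.gene_association == rb.gene_association
        assert ra.subsystem == rb.subsystem
        assert math.isclose(ra.lower_bound, rb.lower_bound, abs_tol=tol)
        assert math.isclose(ra.upper_bound, rb.upper_bound, abs_tol=tol)
        assert set(ra.stoichiometry) == set(rb.stoichiometry)
        for met, coeff in ra.stoichiometry.items():
            assert math.isclose(coeff, rb.stoichiometry[met], abs_tol=tol), (ra.id, met)
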