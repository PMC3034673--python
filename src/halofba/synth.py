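"""Synthetic test networks: analytic toys, random QC networks, mini-halophile.

Three tiers of generated inputs let the whole stack run without any
download:

* analytic toys (:func:`make_toy_chain`, :func:`make_branched_toy`) with
  hand-computable LP optima and, for the branched toy, alternate optima by
  construction;
* random networks (:func:`make_random_network`) built from a mass-balanced
  polymerization core with seed-deterministic injected dead ends and
  elemental imbalances, ground truth recorded for curation oracles, and
  small random LPs (:func:`make_random_fba_toy`) for vertex-enumeration
  cross-checks;
* :func:`make_mini_halophile`, a curated ~50-reaction halophile cartoon
  with glucose/choline/alanine/nitrate/O2 uptakes, an abstracted
  glycolysis-TCA energy module, the four-step ectoine branch off aspartate
  (with both the glutamate- and alanine-dependent diaminobutyrate
  transaminases), the two-step choline-to-betaine pathway with both
  step-one enzymes, a catalase pair, and a biomass reaction that drains
  ectoine as the compatible solute.  Every enzymatic and transport reaction
  is elementally and charge balanced; coefficients are chosen for clean
  rational optima, not biological accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from halofba.errors import StructuralError
from halofba.io import parse_reaction_equation
from halofba.model import DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction


def _rxn(rid, equation, kind, name="", ec=(), gene="", subsystem="", lb=None, ub=None):
    stoich, reversible = parse_reaction_equation(equation)
    return Reaction(
        id=rid,
        name=name or rid,
        stoichiometry=stoich,
        reversible=reversible,
        lower_bound=lb,
        upper_bound=ub,
        ec_numbers=list(ec),
        gene_association=gene,
        subsystem=subsystem,
        kind=kind,
    )


# --------------------------------------------------------------------------
# analytic toys
# --------------------------------------------------------------------------
def make_toy_chain(length: int = 1, uptake_bound: float = 5.0) -> MetabolicModel:
    """Linear pathway EX -> A0 -> ... -> biomass with FBA optimum = uptake_bound.

    ``length`` is the number of conversion steps between the boundary
    species and the biomass drain; ``length=1`` is the minimal 3-reaction
    chain (exchange, transport, biomass drain).
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    mets = [Metabolite(id="A0[e]", name="A0", compartment="e", formula="C", charge=0)]
    mets += [
        Metabolite(id=f"A{i}[c]", name=f"A{i}", compartment="c", formula="C", charge=0)
        for i in range(1, length + 1)
    ]
    reactions = [
        _rxn("EX_A0", "A0[e] <=>", "exchange", lb=-uptake_bound, ub=DEFAULT_BOUND),
        _rxn("R1", "A0[e] -> A1[c]", "transport"),
    ]
    for i in range(2, length + 1):
        reactions.append(_rxn(f"R{i}", f"A{i-1}[c] -> A{i}[c]", "enzymatic"))
    reactions.append(_rxn("BIOMASS", f"A{length}[c] ->", "biomass", name="biomass drain"))
    model = MetabolicModel(id="toy_chain", metabolites=mets, reactions=reactions, objective_id="BIOMASS")
    model.validate()
    return model


def make_branched_toy(capacities=(5.0, 5.0), sink_bound: float | None = None) -> MetabolicModel:
    """Parallel branches of given capacities rejoining before a biomass drain.

    With ``sink_bound`` below total capacity the optimum equals the sink
    bound and the branch split is degenerate (alternate optima exist by
    construction); each branch's FVA range spans ``min(capacity, sink)``.
    """
    capacities = list(capacities)
    if len(capacities) < 2:
        raise ValueError("need >= 2 parallel branches")
    if sink_bound is None:
        sink_bound = float(sum(capacities))
    mets = [
        Metabolite(id="A[e]", name="A", compartment="e", formula="C", charge=0),
        Metabolite(id="A[c]", name="A", compartment="c", formula="C", charge=0),
        Metabolite(id="C[c]", name="C", compartment="c", formula="C", charge=0),
    ]
    mets += [
        Metabolite(id=f"B{i}[c]", name=f"B{i}", compartment="c", formula="C", charge=0)
        for i in range(1, len(capacities) + 1)
    ]
    reactions = [
        _rxn("EX_A", "A[e] <=>", "exchange", lb=-DEFAULT_BOUND),
        _rxn("T_A", "A[e] -> A[c]", "transport"),
    ]
    for i, cap in enumerate(capacities, start=1):
        reactions.append(_rxn(f"BRANCH{i}", f"A[c] -> B{i}[c]", "enzymatic", ub=float(cap)))
        reactions.append(_rxn(f"JOIN{i}", f"B{i}[c] -> C[c]", "enzymatic"))
    reactions.append(_rxn("BIOMASS", "C[c] ->", "biomass", ub=float(sink_bound)))
    model = MetabolicModel(id="branched_toy", metabolites=mets, reactions=reactions, objective_id="BIOMASS")
    model.validate()
    return model


# --------------------------------------------------------------------------
# random QC networks
# --------------------------------------------------------------------------
@dataclass
class GeneratorSpec:
    """Recipe for a seed-deterministic random network with known defects."""

    seed: int
    m: int = 12  # core metabolites (polymer sizes 1..m)
    n: int = 20  # target internal reaction count
    dead_end_fraction: float = 0.0
    unbalanced_fraction: float = 0.0

    def validate(self) -> None:
        if self.m < 3:
            raise StructuralError("m must be >= 3")
        if self.n < self.m - 1:
            raise StructuralError(f"n must be >= m-1 = {self.m - 1} (the core chain)")
        for name in ("dead_end_fraction", "unbalanced_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise StructuralError(f"{name} must be in [0, 1], got {v}")


@dataclass
class GroundTruth:
    """Defects injected by the generator."""

    dead_ends: list[tuple[str, str]] = field(default_factory=list)
    imbalances: dict[str, dict[str, float]] = field(default_factory=dict)


def make_random_network(spec: GeneratorSpec) -> tuple[MetabolicModel, GroundTruth]:
    """Random polymerization network, balanced except for recorded defects.

    Core metabolites ``M1..Mm`` carry formulas ``(CH2O)^i`` so that any
    reaction ``Mi + Mj -> M(i+j)`` is elementally balanced; coefficients are
    in {1, 2} to keep oracles exact.  Injected dead ends are extra species
    touching a single irreversible reaction; injected imbalances add one
    water molecule to a product side (deficit H:2, O:1).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    m = spec.m
    mets = [
        Metabolite(id=f"M{i}[c]", name=f"polymer-{i}", compartment="c", formula=f"C{i}H{2*i}O{i}", charge=0)
        for i in range(1, m + 1)
    ]
    for size in (1, m):
        mets.append(Metabolite(id=f"M{size}[e]", name=f"M{size} external", compartment="e",
                               formula=mets[size - 1].formula, charge=0))
    mets.append(Metabolite(id="h2o[c]", name="water", compartment="c", formula="H2O", charge=0))
    mets.append(Metabolite(id="h2o[e]", name="water", compartment="e", formula="H2O", charge=0))

    reactions = [
        _rxn("EX_M1", "M1[e] <=>", "exchange", lb=-DEFAULT_BOUND),
        _rxn(f"EX_M{m}", f"M{m}[e] <=>", "exchange", lb=-DEFAULT_BOUND),
        _rxn("EX_h2o", "h2o[e] <=>", "exchange", lb=-DEFAULT_BOUND),
        _rxn("T_M1", "M1[e] <=> M1[c]", "transport"),
        _rxn(f"T_M{m}", f"M{m}[e] <=> M{m}[c]", "transport"),
        _rxn("T_h2o", "h2o[e] <=> h2o[c]", "transport"),
    ]
    def condensation(i: int, j: int) -> str:
        if i == j:
            return f"2 M{i}[c] -> M{i+j}[c]"
        return f"M{i}[c] + M{j}[c] -> M{i+j}[c]"

    for i in range(1, m):
        reactions.append(_rxn(f"CHAIN{i}", condensation(i, 1) if i == 1 else f"M{i}[c] + M1[c] -> M{i+1}[c]",
                              "enzymatic"))
    n_extra = spec.n - (m - 1)
    for k in range(n_extra):
        if rng.random() < 0.25:
            i = int(rng.integers(1, m // 2 + 1))
            eq = condensation(i, i)
        else:
            i = int(rng.integers(1, m - 1))
            j = int(rng.integers(1, m - i))
            eq = condensation(i, j)
        reactions.append(_rxn(f"EXTRA{k+1}", eq, "enzymatic"))

    truth = GroundTruth()
    n_dead = int(round(spec.dead_end_fraction * m))
    for d in range(n_dead):
        i = int(rng.integers(1, m + 1))
        did = f"D{d+1}[c]"
        mets.append(Metabolite(id=did, name=f"orphan-{d+1}", compartment="c",
                               formula=f"C{i}H{2*i}O{i}", charge=0))
        if rng.random() < 0.5:
            reactions.append(_rxn(f"DEAD{d+1}", f"M{i}[c] -> {did}", "enzymatic"))
            truth.dead_ends.append((did, "no-consumer"))
        else:
            reactions.append(_rxn(f"DEAD{d+1}", f"{did} -> M{i}[c]", "enzymatic"))
            truth.dead_ends.append((did, "no-producer"))

    eligible = [r for r in reactions if r.id.startswith(("CHAIN", "EXTRA"))]
    n_bad = int(round(spec.unbalanced_fraction * len(eligible)))
    if n_bad > len(eligible):
        raise StructuralError("unbalanced_fraction exceeds eligible reactions")
    for r in rng.choice(len(eligible), size=n_bad, replace=False):
        rxn = eligible[int(r)]
        rxn.stoichiometry["h2o[c]"] = rxn.stoichiometry.get("h2o[c]", 0.0) + 1.0
        truth.imbalances[rxn.id] = {"H": 2.0, "O": 1.0}

    model = MetabolicModel(id=f"random-{spec.seed}", metabolites=mets, reactions=reactions)
    model.validate()
    return model, truth


def make_random_fba_toy(seed: int, max_reactions: int = 8) -> tuple[MetabolicModel, str]:
    """Small random LP (<= ``max_reactions`` reactions, finite bounds, 0 feasible)
    for cross-checking the simplex against exhaustive vertex enumeration."""
    rng = np.random.default_rng(seed)
    n_mets = int(rng.integers(2, 5))
    n_rxns = int(rng.integers(3, max_reactions + 1))
    mets = [Metabolite(id=f"X{i}[c]", name=f"X{i}", compartment="c") for i in range(n_mets)]
    reactions = []
    for j in range(n_rxns):
        k = int(rng.integers(1, min(3, n_mets) + 1))
        chosen = rng.choice(n_mets, size=k, replace=False)
        stoich = {}
        for idx in chosen:
            coeff = float(rng.choice([-2, -1, 1, 2]))
            stoich[f"X{int(idx)}[c]"] = coeff
        hi = float(rng.integers(1, 11))
        lo = float(rng.choice([0.0, -hi]))
        reactions.append(
            Reaction(
                id=f"R{j}",
                stoichiometry=stoich,
                reversible=lo < 0,
                lower_bound=lo,
                upper_bound=hi,
            )
        )
    objective_id = f"R{int(rng.integers(0, n_rxns))}"
    model = MetabolicModel(id=f"lp-toy-{seed}", metabolites=mets, reactions=reactions)
    return model, objective_id


# --------------------------------------------------------------------------
# curated mini-halophile fixture
# --------------------------------------------------------------------------
_MINI_METABOLITES = [
    # id, name, compartment, formula, charge
    ("glc[e]", "glucose", "e", "C6H12O6", 0),
    ("chol[e]", "choline", "e", "C5H14NO", 1),
    ("ala[e]", "alanine", "e", "C3H7NO2", 0),
    ("no3[e]", "nitrate", "e", "NO3", -1),
    ("no2[e]", "nitrite", "e", "NO2", -1),
    ("o2[e]", "oxygen", "e", "O2", 0),
    ("co2[e]", "carbon dioxide", "e", "CO2", 0),
    ("nh4[e]", "ammonium", "e", "H4N", 1),
    ("h2o[e]", "water", "e", "H2O", 0),
    ("h[e]", "proton", "e", "H", 1),
    ("pi[e]", "phosphate", "e", "HO4P", -2),
    ("bet[e]", "betaine", "e", "C5H11NO2", 0),
    ("ect[e]", "ectoine", "e", "C6H10N2O2", 0),
    ("lac[e]", "lactate", "e", "C3H5O3", -1),
    ("na[e]", "sodium", "e", "Na", 1),
    ("cl[e]", "chloride", "e", "Cl", -1),
    ("nacl[e]", "nacl", "e", "ClNa", 0),
    ("glc[c]", "glucose", "c", "C6H12O6", 0),
    ("pyr[c]", "pyruvate", "c", "C3H3O3", -1),
    ("accoa[c]", "acetyl-CoA", "c", "C23H34N7O17P3S", -4),
    ("coa[c]", "coenzyme A", "c", "C21H32N7O16P3S", -4),
    ("oaa[c]", "oxaloacetate", "c", "C4H2O5", -2),
    ("akg[c]", "2-oxoglutarate", "c", "C5H4O5", -2),
    ("glu[c]", "glutamate", "c", "C5H8NO4", -1),
    ("asp[c]", "aspartate", "c", "C4H6NO4", -1),
    ("asp4p[c]", "4-phospho-aspartate", "c", "C4H6NO7P", -2),
    ("asa[c]", "aspartate 4-semialdehyde", "c", "C4H7NO3", 0),
    ("dab[c]", "L-2,4-diaminobutyrate", "c", "C4H11N2O2", 1),
    ("nada[c]", "N-gamma-acetyl-diaminobutyrate", "c", "C6H12N2O3", 0),
    ("ect[c]", "ectoine", "c", "C6H10N2O2", 0),
    ("ala[c]", "alanine", "c", "C3H7NO2", 0),
    ("chol[c]", "choline", "c", "C5H14NO", 1),
    ("betald[c]", "betaine aldehyde", "c", "C5H12NO", 1),
    ("bet[c]", "betaine", "c", "C5H11NO2", 0),
    ("atp[c]", "ATP", "c", "C10H12N5O13P3", -4),
    ("adp[c]", "ADP", "c", "C10H12N5O10P2", -3),
    ("pi[c]", "phosphate", "c", "HO4P", -2),
    ("h[c]", "proton", "c", "H", 1),
    ("h2o[c]", "water", "c", "H2O", 0),
    ("nad[c]", "NAD+", "c", "C21H26N7O14P2", -1),
    ("nadh[c]", "NADH", "c", "C21H27N7O14P2", -2),
    ("o2[c]", "oxygen", "c", "O2", 0),
    ("co2[c]", "carbon dioxide", "c", "CO2", 0),
    ("nh4[c]", "ammonium", "c", "H4N", 1),
    ("no3[c]", "nitrate", "c", "NO3", -1),
    ("no2[c]", "nitrite", "c", "NO2", -1),
    ("h2o2[c]", "hydrogen peroxide", "c", "H2O2", 0),
    ("lac[c]", "lactate", "c", "C3H5O3", -1),
    ("na[c]", "sodium", "c", "Na", 1),
    ("cl[c]", "chloride", "c", "Cl", -1),
]

# default exchange lower bounds: organic substrates closed unless opened by a
# medium; free inorganic species and water open; glucose modestly open
_MINI_EXCHANGES = [
    ("EX_glc", "glc[e]", -10.0),
    ("EX_chol", "chol[e]", 0.0),
    ("EX_ala", "ala[e]", 0.0),
    ("EX_no3", "no3[e]", 0.0),
    ("EX_no2", "no2[e]", 0.0),
    ("EX_o2", "o2[e]", -DEFAULT_BOUND),
    ("EX_co2", "co2[e]", -DEFAULT_BOUND),
    ("EX_nh4", "nh4[e]", -DEFAULT_BOUND),
    ("EX_h2o", "h2o[e]", -DEFAULT_BOUND),
    ("EX_h", "h[e]", -DEFAULT_BOUND),
    ("EX_pi", "pi[e]", -DEFAULT_BOUND),
    ("EX_bet", "bet[e]", 0.0),
    ("EX_ect", "ect[e]", 0.0),
    ("EX_lac", "lac[e]", 0.0),
    ("EX_na", "na[e]", -DEFAULT_BOUND),
    ("EX_cl", "cl[e]", -DEFAULT_BOUND),
    ("EX_nacl", "nacl[e]", 0.0),
]

_MINI_TRANSPORTS = [
    ("T_glc", "glc[e] -> glc[c]"),
    ("T_chol", "chol[e] -> chol[c]"),
    ("T_ala", "ala[e] -> ala[c]"),
    ("T_no3", "no3[e] -> no3[c]"),
    ("T_no2", "no2[c] -> no2[e]"),
    ("T_o2", "o2[e] <=> o2[c]"),
    ("T_co2", "co2[c] <=> co2[e]"),
    ("T_nh4", "nh4[e] <=> nh4[c]"),  # bidirectional: ammonia is a secreted by-product
    ("T_h2o", "h2o[c] <=> h2o[e]"),
    ("T_h", "h[c] <=> h[e]"),
    ("T_pi", "pi[e] -> pi[c]"),
    ("T_bet", "bet[c] <=> bet[e]"),
    ("T_ect", "ect[c] -> ect[e]"),
    ("T_lac", "lac[c] -> lac[e]"),
    ("T_na", "na[c] <=> na[e]"),
    ("T_cl", "cl[c] <=> cl[e]"),
    ("T_nacl", "nacl[e] -> na[c] + cl[c]"),
]

# (id, equation, name, EC numbers, gene association, subsystem)
_MINI_ENZYMES = [
    ("GLYC", "glc[c] + 2 adp[c] + 2 pi[c] + 2 nad[c] -> 2 pyr[c] + 2 atp[c] + 2 nadh[c] + 2 h2o[c] + 2 h[c]",
     "glycolysis (lumped)", ["2.7.1.2"], "Csal0935", "carbohydrate"),
    ("PDH", "pyr[c] + coa[c] + nad[c] -> accoa[c] + co2[c] + nadh[c]",
     "pyruvate dehydrogenase", ["1.2.4.1"], "Csal1007", "energy"),
    ("CS_AKG", "accoa[c] + oaa[c] + h2o[c] + nad[c] -> akg[c] + co2[c] + coa[c] + nadh[c] + h[c]",
     "citrate synthase to 2-oxoglutarate (lumped)", ["2.3.3.1"], "Csal0182", "energy"),
    ("TCA_OAA", "akg[c] + 3 nad[c] + adp[c] + pi[c] + h2o[c] -> oaa[c] + co2[c] + 3 nadh[c] + atp[c] + 2 h[c]",
     "2-oxoglutarate to oxaloacetate (lumped)", ["1.2.4.2"], "Csal0201", "energy"),
    ("PYC", "pyr[c] + co2[c] + atp[c] + h2o[c] -> oaa[c] + adp[c] + pi[c] + 2 h[c]",
     "pyruvate carboxylase", ["6.4.1.1"], "Csal0404", "carbohydrate"),
    ("AST", "oaa[c] + glu[c] <=> asp[c] + akg[c]",
     "aspartate transaminase", ["2.6.1.1"], "Csal0640", "amino acid"),
    ("GDH", "akg[c] + nh4[c] + nadh[c] + h[c] <=> glu[c] + h2o[c] + nad[c]",
     "glutamate dehydrogenase", ["1.4.1.4"], "Csal1129", "amino acid"),
    ("ALATA", "pyr[c] + glu[c] <=> ala[c] + akg[c]",
     "alanine transaminase", ["2.6.1.2"], "Csal0971", "amino acid"),
    ("ASK", "asp[c] + atp[c] -> asp4p[c] + adp[c]",
     "aspartate kinase", ["2.7.2.4"], "Csal0626", "amino acid"),
    ("ASD", "asp4p[c] + nadh[c] + h[c] -> asa[c] + pi[c] + nad[c]",
     "aspartate-semialdehyde dehydrogenase", ["1.2.1.11"], "Csal2450", "amino acid"),
    ("DAT_GLU", "asa[c] + glu[c] -> dab[c] + akg[c]",
     "diaminobutyrate-2-oxoglutarate transaminase", ["2.6.1.76"], "Csal1877", "osmolyte"),
    ("DAT_ALA", "asa[c] + ala[c] -> dab[c] + pyr[c]",
     "diaminobutyrate-pyruvate transaminase", ["2.6.1.46"], "Csal1877", "osmolyte"),
    ("DAAT", "dab[c] + accoa[c] -> nada[c] + coa[c] + h[c]",
     "diaminobutyrate acetyltransferase", ["2.3.1.178"], "Csal1876", "osmolyte"),
    ("ECTS", "nada[c] -> ect[c] + h2o[c]",
     "ectoine synthase", ["4.2.1.108"], "Csal1878", "osmolyte"),
    ("CDH", "chol[c] + nad[c] -> betald[c] + nadh[c] + h[c]",
     "choline dehydrogenase", ["1.1.99.1"], "Csal1514", "osmolyte"),
    ("CMO", "chol[c] + o2[c] + nadh[c] + h[c] -> betald[c] + 2 h2o[c] + nad[c]",
     "choline monooxygenase", ["1.14.15.7"], "Csal2455", "osmolyte"),
    ("BADH", "betald[c] + nad[c] + h2o[c] -> bet[c] + nadh[c] + 2 h[c]",
     "betaine aldehyde dehydrogenase", ["1.2.1.8"], "Csal1515", "osmolyte"),
    ("OXPHOS", "2 nadh[c] + o2[c] + 4 adp[c] + 4 pi[c] + 6 h[c] -> 2 nad[c] + 4 atp[c] + 6 h2o[c]",
     "oxidative phosphorylation (lumped, P/O = 2)", ["1.9.3.1"], "Csal0325 and Csal0326", "energy"),
    ("NAR", "nadh[c] + no3[c] + adp[c] + pi[c] + 2 h[c] -> nad[c] + no2[c] + atp[c] + 2 h2o[c]",
     "nitrate reductase (respiratory)", ["1.7.99.4"], "Csal0216", "energy"),
    ("LDH", "pyr[c] + nadh[c] + h[c] -> lac[c] + nad[c]",
     "lactate dehydrogenase", ["1.1.1.27"], "Csal0812", "energy"),
    ("NOX", "nadh[c] + h[c] + o2[c] -> nad[c] + h2o2[c]",
     "NADH oxidase (peroxide-forming)", ["1.6.3.1"], "Csal0550", "energy"),
    ("CAT", "2 h2o2[c] -> 2 h2o[c] + o2[c]",
     "catalase", ["1.11.1.6"], "Csal0087", "energy"),
    ("ATPM", "atp[c] + h2o[c] -> adp[c] + pi[c] + h[c]",
     "ATP maintenance", [], "", "energy"),
]

#: biomass drain: growth precursors, ATP cost, and ectoine as the compatible
#: solute (large coefficient: osmolyte demand dominates a halophile's drain).
#: The ATP coefficient keeps growth energy-limited across the case-study
#: uptake ranges so osmolyte-pathway redox credit translates into growth.
_MINI_BIOMASS = (
    "0.5 glu[c] + 0.3 asp[c] + 0.3 ala[c] + 0.5 pyr[c] + 0.2 accoa[c] + 7.5 ect[c]"
    " + 40 atp[c] + 40 h2o[c] + 0.05 na[c] + 0.05 cl[c]"
    " -> 40 adp[c] + 40 pi[c] + 40 h[c] + 0.2 coa[c]"
)

#: substrates the fixture declares for its own phenotype table
MINI_HALOPHILE_INVIVO = [
    ("glucose", "+"),
    ("alanine", "+"),
    ("adonitol", "-"),   # no transport route in the fixture, as in vivo
    ("cellobiose", "-"),
]


def make_mini_halophile() -> MetabolicModel:
    """Deterministic curated halophile cartoon (see module docstring)."""
    mets = [
        Metabolite(id=mid, name=name, compartment=comp, formula=formula, charge=charge)
        for mid, name, comp, formula, charge in _MINI_METABOLITES
    ]
    reactions = []
    for rid, species, lb in _MINI_EXCHANGES:
        reactions.append(_rxn(rid, f"{species} <=>", "exchange", name=f"{species} exchange",
                              lb=lb, ub=DEFAULT_BOUND))
    for rid, eq in _MINI_TRANSPORTS:
        reactions.append(_rxn(rid, eq, "transport", name=rid, subsystem="transport"))
    for rid, eq, name, ec, gene, subsystem in _MINI_ENZYMES:
        reactions.append(_rxn(rid, eq, "enzymatic", name=name, ec=ec, gene=gene, subsystem=subsystem))
    reactions.append(_rxn("BIOMASS", _MINI_BIOMASS, "biomass", name="biomass (growth + osmolyte demand)"))
    model = MetabolicModel(
        id="mini_halophile",
        metabolites=mets,
        reactions=reactions,
        objective_id="BIOMASS",
    )
    model.genes = sorted(model.all_genes())
    model.validate()
    return model
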