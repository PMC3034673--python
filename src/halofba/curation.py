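"""Reconstruction quality control.

Covers the gap-analysis toolkit used while refining a draft reconstruction:
dead-end metabolite detection, per-reaction elemental/charge balance,
metabolite and reaction adjacency matrices, network summary statistics
(counts by compartment/kind, subsystem distribution, EC-class
reactions-per-gene ratios, monofunctional-enzyme fraction) and a canonical
cross-model reaction comparison.
"""

from __future__ import annotations

import json
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

from halofba.errors import FormulaError
from halofba.formulas import parse_formula
from halofba.model import MetabolicModel, Metabolite, Reaction, build_stoichiometric_matrix

#: reaction kinds subject to mass/charge balance (boundary and lumped
#: pseudo-reactions are exempt by construction)
BALANCED_KINDS = ("enzymatic", "transport")

BALANCE_TOL = 1e-6


# --------------------------------------------------------------------------
# dead ends
# --------------------------------------------------------------------------
def find_dead_ends(model: MetabolicModel) -> list[tuple[str, str]]:
    """Metabolites with no producing or no consuming reaction.

    A reversible reaction counts as both a producer and a consumer of every
    participant; exchange and biomass reactions count like any other.  A
    metabolite missing both roles is reported twice (once per mode).
    """
    producers: Counter = Counter()
    consumers: Counter = Counter()
    for rxn in model.reactions:
        for met_id, coeff in rxn.stoichiometry.items():
            if rxn.reversible:
                producers[met_id] += 1
                consumers[met_id] += 1
            elif coeff > 0:
                producers[met_id] += 1
            else:
                consumers[met_id] += 1
    out: list[tuple[str, str]] = []
    for met in model.metabolites:
        if producers[met.id] == 0:
            out.append((met.id, "no-producer"))
        if consumers[met.id] == 0:
            out.append((met.id, "no-consumer"))
    return out


# --------------------------------------------------------------------------
# mass / charge balance
# --------------------------------------------------------------------------
@dataclass
class BalanceReport:
    """Outcome of checking one reaction: products minus substrates per element."""

    reaction_id: str
    status: str  # balanced | unbalanced | unknown
    element_deficit: dict[str, float] = field(default_factory=dict)
    charge_deficit: float | None = None
    unknown_metabolites: list[str] = field(default_factory=list)

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


def check_mass_charge_balance(reaction: Reaction, metabolite_registry) -> BalanceReport:
    """Per-element and charge deficit of a reaction (Sum products - Sum substrates).

    ``metabolite_registry`` is a model or a mapping of metabolite id ->
    :class:`Metabolite`.  A participant without a formula makes the verdict
    ``unknown`` rather than unbalanced; an unparseable formula raises
    :class:`FormulaError` naming the metabolite.
    """
    if isinstance(metabolite_registry, MetabolicModel):
        registry = {m.id: m for m in metabolite_registry.metabolites}
    else:
        registry = dict(metabolite_registry)
    deficit: defaultdict = defaultdict(float)
    charge = 0.0
    charge_known = True
    unknown: list[str] = []
    for met_id, coeff in reaction.stoichiometry.items():
        met = registry[met_id]
        if met.formula is None or not str(met.formula).strip():
            unknown.append(met_id)
            continue
        try:
            composition = parse_formula(met.formula)
        except FormulaError as exc:
            raise FormulaError(f"metabolite {met_id!r}: {exc}") from None
        for element, count in composition.items():
            deficit[element] += coeff * count
        if met.charge is None:
            charge_known = False
        else:
            charge += coeff * met.charge
    element_deficit = {el: v for el, v in deficit.items() if abs(v) > BALANCE_TOL}
    charge_deficit = None
    if not unknown and charge_known:
        charge_deficit = charge if abs(charge) > BALANCE_TOL else 0.0
    if unknown:
        return BalanceReport(reaction.id, "unknown", element_deficit, None, unknown)
    status = "balanced" if not element_deficit and not (charge_deficit or 0.0) else "unbalanced"
    return BalanceReport(reaction.id, status, element_deficit, charge_deficit)


# --------------------------------------------------------------------------
# topology
# --------------------------------------------------------------------------
def adjacency_matrices(model: MetabolicModel) -> tuple[np.ndarray, np.ndarray]:
    """(metabolite m x m, reaction n x n) binary adjacency matrices.

    Metabolites are adjacent iff they co-occur in some reaction; reactions
    are adjacent iff they share a metabolite.  Both are symmetric with a
    zero diagonal.
    """
    S = build_stoichiometric_matrix(model).S
    B = sparse.csr_matrix((np.ones_like(S.data), S.indices, S.indptr), shape=S.shape)
    met_adj = (B @ B.T).toarray() > 0
    rxn_adj = (B.T @ B).toarray() > 0
    np.fill_diagonal(met_adj, False)
    np.fill_diagonal(rxn_adj, False)
    return met_adj.astype(np.int8), rxn_adj.astype(np.int8)


def metabolite_graph(model: MetabolicModel) -> nx.Graph:
    met_adj, _ = adjacency_matrices(model)
    ids = [m.id for m in model.metabolites]
    g = nx.from_numpy_array(met_adj)
    return nx.relabel_nodes(g, dict(enumerate(ids)))


# --------------------------------------------------------------------------
# network statistics
# --------------------------------------------------------------------------
@dataclass
class NetworkStats:
    genes: int
    metabolites: int
    intracellular_metabolites: int
    extracellular_metabolites: int
    reactions: int
    reactions_by_kind: dict[str, int]
    reactions_with_genes: int
    reactions_with_genes_by_kind: dict[str, int]
    subsystem_distribution: dict[str, float]
    ec_class_ratio: dict[str, float]
    monofunctional_fraction: float | None
    connected_components: int


def network_statistics(model: MetabolicModel) -> NetworkStats:
    """Summary counts and ratios of the network."""
    by_kind = Counter(r.kind for r in model.reactions)
    with_genes = [r for r in model.reactions if r.gene_association.strip()]
    subsystems = Counter(r.subsystem for r in model.reactions if r.subsystem.strip())
    total_labeled = sum(subsystems.values())
    subsystem_distribution = (
        {s: c / total_labeled for s, c in sorted(subsystems.items())} if total_labeled else {}
    )

    ec_reactions: defaultdict = defaultdict(set)
    class_reactions: defaultdict = defaultdict(set)
    class_genes: defaultdict = defaultdict(set)
    for r in model.reactions:
        for ec in r.ec_numbers:
            ec_reactions[ec].add(r.id)
            top = ec.split(".")[0]
            class_reactions[top].add(r.id)
            class_genes[top] |= r.genes
    ec_class_ratio = {
        top: (len(class_reactions[top]) / len(class_genes[top]) if class_genes[top] else float("nan"))
        for top in sorted(class_reactions)
    }
    monofunctional = None
    if ec_reactions:
        monofunctional = sum(1 for rxns in ec_reactions.values() if len(rxns) == 1) / len(ec_reactions)

    return NetworkStats(
        genes=len(model.all_genes()),
        metabolites=len(model.metabolites),
        intracellular_metabolites=sum(1 for m in model.metabolites if m.compartment == "c"),
        extracellular_metabolites=sum(1 for m in model.metabolites if m.compartment == "e"),
        reactions=len(model.reactions),
        reactions_by_kind=dict(by_kind),
        reactions_with_genes=len(with_genes),
        reactions_with_genes_by_kind=dict(Counter(r.kind for r in with_genes)),
        subsystem_distribution=subsystem_distribution,
        ec_class_ratio=ec_class_ratio,
        monofunctional_fraction=monofunctional,
        connected_components=(
            nx.number_connected_components(metabolite_graph(model)) if model.metabolites else 0
        ),
    )


# --------------------------------------------------------------------------
# cross-model comparison
# --------------------------------------------------------------------------
def _species_key(met: Metabolite) -> str:
    if met.formula:
        return f"formula:{met.formula}"
    base = met.id
    for suffix in (f"[{met.compartment}]", f"_{met.compartment}"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
    return f"id:{base.lower()}"


def reaction_signature(rxn: Reaction, model: MetabolicModel) -> tuple:
    """Canonical, compartment-normalized signature for cross-model matching.

    Species are identified by elemental formula when available (ids are not
    comparable across publications), compartments are stripped, and a
    reversible reaction is oriented to the lexicographically smaller of its
    two directions.
    """
    merged: defaultdict = defaultdict(float)
    for met_id, coeff in rxn.stoichiometry.items():
        merged[_species_key(model.metabolite(met_id))] += coeff
    pairs = tuple(sorted((k, round(v, 6)) for k, v in merged.items() if abs(v) > 1e-9))
    if rxn.reversible:
        flipped = tuple(sorted((k, round(-v, 6)) for k, v in merged.items() if abs(v) > 1e-9))
        pairs = min(pairs, flipped)
    return pairs


@dataclass
class ModelComparison:
    shared_a: list[str]
    shared_b: list[str]
    unique_a: list[str]
    unique_b: list[str]

    @property
    def n_shared(self) -> int:
        """Number of distinct shared reaction signatures."""
        return len({s for s in self._shared_sigs})

    _shared_sigs: set = field(default_factory=set, repr=False)


def compare_models(model_a: MetabolicModel, model_b: MetabolicModel, kinds=("enzymatic",)) -> ModelComparison:
    """Shared and unique reactions between two models by canonical signature.

    Only metabolic (enzymatic) reactions are compared by default: transport
    and exchange pseudo-reactions of the same species collapse to empty
    signatures under compartment normalization.  A reaction whose signature
    is empty (an interconversion of species with identical formulas) is
    treated as unmatchable and listed as unique.
    """

    def signatures(model):
        sigs: defaultdict = defaultdict(list)
        empties: list[str] = []
        for r in model.reactions:
            if r.kind in kinds:
                sig = reaction_signature(r, model)
                (empties if not sig else sigs[sig]).append(r.id)
        return sigs, empties

    (sa, ea), (sb, eb) = signatures(model_a), signatures(model_b)
    shared = set(sa) & set(sb)
    cmpres = ModelComparison(
        shared_a=sorted(rid for sig in shared for rid in sa[sig]),
        shared_b=sorted(rid for sig in shared for rid in sb[sig]),
        unique_a=sorted([rid for sig in set(sa) - shared for rid in sa[sig]] + ea),
        unique_b=sorted([rid for sig in set(sb) - shared for rid in sb[sig]] + eb),
    )
    cmpres._shared_sigs = shared
    return cmpres


# --------------------------------------------------------------------------
# audit
# --------------------------------------------------------------------------
@dataclass
class AuditReport:
    model_id: str
    dead_end_metabolites: list[tuple[str, str]]
    unbalanced_reactions: list[BalanceReport]
    unknown_composition_reactions: list[str]
    stats: NetworkStats

    @property
    def clean(self) -> bool:
        return not self.dead_end_metabolites and not self.unbalanced_reactions

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "dead_end_metabolites": [{"metabolite": m, "mode": mode} for m, mode in self.dead_end_metabolites],
            "unbalanced_reactions": [
                {
                    "reaction": b.reaction_id,
                    "element_deficit": b.element_deficit,
                    "charge_deficit": b.charge_deficit,
                }
                for b in self.unbalanced_reactions
            ],
            "unknown_composition_reactions": self.unknown_composition_reactions,
            "stats": {
                **{k: v for k, v in self.stats.__dict__.items()},
            },
        }

    def write(self, json_path: str | Path, tsv_path: str | Path | None = None) -> None:
        Path(json_path).write_text(json.dumps(self.to_dict(), indent=1, default=str))
        if tsv_path is not None:
            rows = [
                {"type": "dead_end", "id": met, "detail": mode}
                for met, mode in self.dead_end_metabolites
            ] + [
                {
                    "type": "unbalanced",
                    "id": b.reaction_id,
                    "detail": json.dumps({"elements": b.element_deficit, "charge": b.charge_deficit}),
                }
                for b in self.unbalanced_reactions
            ]
            pd.DataFrame(rows, columns=["type", "id", "detail"]).to_csv(tsv_path, sep="\t", index=False)


def audit_model(model: MetabolicModel) -> AuditReport:
    """Full QC pass: dead ends, balance of enzymatic/transport reactions, stats."""
    unbalanced: list[BalanceReport] = []
    unknown: list[str] = []
    registry = {m.id: m for m in model.metabolites}
    for rxn in model.reactions:
        if rxn.kind not in BALANCED_KINDS:
            continue
        report = check_mass_charge_balance(rxn, registry)
        if report.status == "unbalanced":
            unbalanced.append(report)
        elif report.status == "unknown":
            unknown.append(rxn.id)
    return AuditReport(
        model_id=model.id,
        dead_end_metabolites=find_dead_ends(model),
        unbalanced_reactions=unbalanced,
        unknown_composition_reactions=unknown,
        stats=network_statistics(model),
    )
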