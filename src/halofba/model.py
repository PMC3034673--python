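"""In-memory representation of a genome-scale metabolic model.

A :class:`MetabolicModel` holds metabolites (intracellular ``c`` or
extracellular ``e``), reactions with stoichiometry, reversibility, flux
bounds in mmol/gDW/h, EC numbers and gene associations, and the id of the
biomass objective reaction.  :func:`build_stoichiometric_matrix` produces the
m x n stoichiometric matrix S whose entry S_ij is the coefficient of
metabolite i in reaction j; steady-state analysis solves S.v = 0.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

from halofba.errors import StructuralError, UndefinedRatioError, UnknownReactionError
from halofba.gpr import gpr_genes, parse_gpr

#: tolerance for stoichiometric-coefficient equality checks
COEFF_TOL = 1e-9

COMPARTMENTS = ("c", "e")
REACTION_KINDS = ("enzymatic", "transport", "exchange", "biomass")

#: default flux bounds (mmol/gDW/h) when a file omits them
DEFAULT_BOUND = 1000.0


@dataclass
class Metabolite:
    """A chemical species in one compartment.

    ``formula`` is an elemental composition in Hill notation (e.g.
    ``C6H12O6``) or ``None`` when unknown; ``charge`` is the net charge at
    physiological pH or ``None``.
    """

    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None
    annotations: dict = field(default_factory=dict)


@dataclass
class Reaction:
    """A stoichiometric conversion with flux bounds.

    ``stoichiometry`` maps metabolite id to a nonzero coefficient, negative
    for consumed species and positive for produced ones.  ``lower_bound`` /
    ``upper_bound`` are the alpha/beta flux limits in mmol/gDW/h.
    """

    id: str
    name: str = ""
    stoichiometry: dict[str, float] = field(default_factory=dict)
    reversible: bool = False
    lower_bound: float | None = None
    upper_bound: float | None = None
    ec_numbers: list[str] = field(default_factory=list)
    gene_association: str = ""
    subsystem: str = ""
    kind: str = "enzymatic"
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.lower_bound is None:
            self.lower_bound = -DEFAULT_BOUND if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = DEFAULT_BOUND

    @property
    def genes(self) -> set[str]:
        return gpr_genes(self.gene_association)

    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class MetabolicModel:
    """A set of metabolites, reactions and genes with a biomass objective."""

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    objective_id: str | None = None

    # ---- lookups -------------------------------------------------------
    @property
    def metabolite_index(self) -> dict[str, int]:
        return {m.id: i for i, m in enumerate(self.metabolites)}

    @property
    def reaction_index(self) -> dict[str, int]:
        return {r.id: i for i, r in enumerate(self.reactions)}

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self.metabolites[self.metabolite_index[met_id]]
        except KeyError:
            raise UnknownReactionError(f"unknown metabolite {met_id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self.reactions[self.reaction_index[rxn_id]]
        except KeyError:
            raise UnknownReactionError(f"unknown reaction {rxn_id!r}") from None

    def reactions_by_ec(self, ec: str) -> list[Reaction]:
        return [r for r in self.reactions if ec in r.ec_numbers]

    def exchanges(self) -> list[Reaction]:
        return [r for r in self.reactions if r.kind == "exchange"]

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # ---- validation ----------------------------------------------------
    def validate(self) -> None:
        """Check every structural invariant; raise StructuralError on the first group found."""
        problems: list[str] = []
        met_ids = [m.id for m in self.metabolites]
        met_set = set(met_ids)
        if len(met_set) != len(met_ids):
            dupes = {m for m in met_ids if met_ids.count(m) > 1}
            problems.append(f"duplicate metabolite ids: {sorted(dupes)}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = {r for r in rxn_ids if rxn_ids.count(r) > 1}
            problems.append(f"duplicate reaction ids: {sorted(dupes)}")
        for m in self.metabolites:
            if m.compartment not in COMPARTMENTS:
                problems.append(f"metabolite {m.id}: compartment {m.compartment!r} not in {COMPARTMENTS}")
        declared_genes = set(self.genes)
        for r in self.reactions:
            if r.kind not in REACTION_KINDS:
                problems.append(f"reaction {r.id}: kind {r.kind!r} not in {REACTION_KINDS}")
            if not r.stoichiometry:
                problems.append(f"reaction {r.id}: empty stoichiometry")
            for met_id, coeff in r.stoichiometry.items():
                if met_id not in met_set:
                    problems.append(f"reaction {r.id}: unresolved metabolite reference {met_id!r}")
                if abs(coeff) <= COEFF_TOL:
                    problems.append(f"reaction {r.id}: zero coefficient on {met_id}")
            if r.lower_bound > r.upper_bound:
                problems.append(f"reaction {r.id}: lower bound {r.lower_bound} > upper bound {r.upper_bound}")
            if not r.reversible and r.lower_bound < 0:
                problems.append(f"reaction {r.id}: irreversible with negative lower bound {r.lower_bound}")
            if r.kind == "exchange":
                for met_id in r.stoichiometry:
                    if met_id in met_set and self.metabolite(met_id).compartment != "e":
                        problems.append(f"exchange {r.id}: touches non-extracellular metabolite {met_id}")
            if declared_genes:
                missing = r.genes - declared_genes
                if missing:
                    problems.append(f"reaction {r.id}: undeclared genes {sorted(missing)}")
            parse_gpr(r.gene_association)  # raises GPRParseError if malformed
        if self.objective_id is not None:
            if self.objective_id not in set(rxn_ids):
                problems.append(f"objective {self.objective_id!r} does not resolve")
            elif self.reaction(self.objective_id).kind != "biomass":
                problems.append(f"objective {self.objective_id!r} is not a biomass reaction")
        if problems:
            raise StructuralError("; ".join(problems))

    def all_genes(self) -> set[str]:
        """Genes declared plus genes referenced from gene associations."""
        out = set(self.genes)
        for r in self.reactions:
            out |= r.genes
        return out


@dataclass
class StoichiometricMatrix:
    """The m x n stoichiometric matrix with id/index maps."""

    S: sparse.csr_matrix
    row_index: dict[str, int]
    col_index: dict[str, int]

    @property
    def m(self) -> int:
        return self.S.shape[0]

    @property
    def n(self) -> int:
        return self.S.shape[1]

    def coefficient(self, met_id: str, rxn_id: str) -> float:
        return float(self.S[self.row_index[met_id], self.col_index[rxn_id]])

    def to_dense(self) -> np.ndarray:
        return self.S.toarray()

    def column_stoichiometry(self, rxn_id: str) -> dict[str, float]:
        """Recover the stoichiometry map of one reaction from the matrix."""
        j = self.col_index[rxn_id]
        col = self.S.getcol(j).tocoo()
        rows = {i: met for met, i in self.row_index.items()}
        return {rows[i]: float(v) for i, v in zip(col.row, col.data)}


def build_stoichiometric_matrix(model: MetabolicModel) -> StoichiometricMatrix:
    """Assemble S (metabolites x reactions) from the model's stoichiometries."""
    row_index = model.metabolite_index
    col_index = model.reaction_index
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coeff in rxn.stoichiometry.items():
            if met_id not in row_index:
                raise StructuralError(f"reaction {rxn.id}: unresolved metabolite reference {met_id!r}")
            rows.append(row_index[met_id])
            cols.append(j)
            data.append(float(coeff))
    S = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )
    return StoichiometricMatrix(S=S, row_index=dict(row_index), col_index=dict(col_index))


def gene_reaction_coverage(model: MetabolicModel) -> float:
    """Fraction of enzymatic reactions carrying a non-empty gene association."""
    enzymatic = [r for r in model.reactions if r.kind == "enzymatic"]
    if not enzymatic:
        raise UndefinedRatioError("model has no enzymatic reactions")
    associated = sum(1 for r in enzymatic if r.gene_association.strip())
    return associated / len(enzymatic)


def knock_out(model: MetabolicModel, reaction_ids: Iterable[str]) -> MetabolicModel:
    """Return a copy of the model with the named reactions forced to zero flux."""
    ids = list(reaction_ids)
    index = model.reaction_index
    unknown = [r for r in ids if r not in index]
    if unknown:
        raise UnknownReactionError(f"unknown reaction ids: {unknown}")
    out = model.copy()
    for rid in ids:
        rxn = out.reactions[index[rid]]
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return out


def apply_bounds(model: MetabolicModel, overrides: Mapping[str, tuple[float, float]]) -> MetabolicModel:
    """Return a copy with (lower, upper) bound overrides applied per reaction id."""
    index = model.reaction_index
    unknown = [r for r in overrides if r not in index]
    if unknown:
        raise UnknownReactionError(f"unknown reaction ids: {unknown}")
    out = model.copy()
    for rid, (lo, hi) in overrides.items():
        if lo > hi:
            raise StructuralError(f"override for {rid}: lower {lo} > upper {hi}")
        rxn = out.reactions[index[rid]]
        rxn.lower_bound = float(lo)
        rxn.upper_bound = float(hi)
    return out
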