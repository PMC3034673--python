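"""Osmoadaptation case studies: choline-betaine sweep, ectoine production,
alanine supplementation, pathway-presence audit.

Glycine betaine is made from choline in two steps (choline dehydrogenase EC
1.1.99.1 or choline monooxygenase EC 1.14.15.7, then betaine aldehyde
dehydrogenase EC 1.2.1.8).  Ectoine branches off the aspartate family:
aspartate kinase (EC 2.7.2.4) -> aspartate-semialdehyde dehydrogenase (EC
1.2.1.11) -> diaminobutyrate transaminase (glutamate-dependent EC 2.6.1.76
or alanine-dependent EC 2.6.1.46) -> diaminobutyrate acetyltransferase (EC
2.3.1.178) -> ectoine synthase (EC 4.2.1.108).

"Production flux" of an osmolyte is its net synthesis rate by enzymatic
reactions at the reported optimum; at steady state this equals excretion
plus incorporation into biomass, and it reduces to the excretion flux in a
model whose biomass does not drain the osmolyte.  Sweeps attach an FVA
variability percentage to certify that headline fluxes are not
alternate-optima artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from halofba.errors import MediumError, PathwayError
from halofba.fba import flux_variability, resolve_exchange, set_medium, solve_fba
from halofba.model import MetabolicModel, knock_out
from halofba.phenotype import _species_base

ECTOINE_PATHWAY_ECS = ("2.7.2.4", "1.2.1.11", "2.6.1.76", "2.6.1.46", "2.3.1.178", "4.2.1.108")
BETAINE_PATHWAY_ECS = ("1.1.99.1", "1.14.15.7", "1.2.1.8")
#: the two step-one choline-oxidizing enzymes (knocked out in ectoine runs)
CHOLINE_OXIDATION_ECS = ("1.1.99.1", "1.14.15.7")

#: EC groups where any one member suffices (isoenzymes for the same step)
_EITHER_OR_STEPS = (frozenset({"2.6.1.76", "2.6.1.46"}), frozenset({"1.1.99.1", "1.14.15.7"}))


@dataclass
class PathwayReport:
    """Presence of a pathway's EC numbers with their mapped reaction ids."""

    found: dict[str, list[str]]
    missing: list[str]

    @property
    def complete(self) -> bool:
        """True when every step is covered (isoenzyme steps need one member)."""
        missing = set(self.missing)
        for group in _EITHER_OR_STEPS:
            group_missing = group & missing
            if group_missing and group_missing != group:
                missing -= group_missing  # the sibling enzyme covers the step
        return not missing


def verify_pathway(model: MetabolicModel, ec_list: Sequence[str]) -> PathwayReport:
    """Map each EC number to its reactions; list the ones absent from the model."""
    found: dict[str, list[str]] = {}
    missing: list[str] = []
    for ec in ec_list:
        rxns = [r.id for r in model.reactions_by_ec(ec)]
        if rxns:
            found[ec] = rxns
        else:
            missing.append(ec)
    return PathwayReport(found=found, missing=missing)


def production_flux(model: MetabolicModel, fluxes: dict[str, float], species: str) -> float:
    """Net synthesis rate of a species by enzymatic reactions (mmol/gDW/h)."""
    base = _species_base(species)
    total = 0.0
    for rxn in model.reactions:
        if rxn.kind != "enzymatic":
            continue
        for met_id, coeff in rxn.stoichiometry.items():
            if _species_base(met_id) == base:
                total += coeff * fluxes.get(rxn.id, 0.0)
    return total


@dataclass
class SweepResult:
    """One controlled-uptake sweep: biomass, product flux, yield per value."""

    variable: str
    product: str
    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def column(self, key: str) -> list:
        return [row[key] for row in self.rows]


def _product_reactions(model: MetabolicModel, species: str) -> list[str]:
    base = _species_base(species)
    return [
        r.id
        for r in model.reactions
        if r.kind == "enzymatic" and any(_species_base(m) == base for m in r.stoichiometry)
    ]


def _sweep(model, medium_for, values, variable, product_species, with_fva):
    rows = []
    fva_targets = _product_reactions(model, product_species) + [model.objective_id]
    for value in values:
        overrides = medium_for(value)
        sol = solve_fba(model, extra_constraints=overrides).raise_for_status()
        row = {
            variable: float(value),
            "biomass": sol.objective_value,
            "product_flux": production_flux(model, sol.fluxes, product_species),
        }
        if with_fva:
            fva = flux_variability(model, extra_constraints=overrides, reactions=fva_targets)
            row["max_variability_pct"] = max(fva.variability_percent.values(), default=0.0)
        rows.append(row)
    return rows


def choline_betaine_sweep(
    model: MetabolicModel,
    glucose_rate: float = 3.0,
    choline_rates: Sequence[float] = (0.0, 1.0, 1.2, 1.4, 1.6, 1.8, 2.0),
    with_fva: bool = True,
    glucose: str = "glucose",
    choline: str = "choline",
    betaine: str = "betaine",
) -> SweepResult:
    """Biomass and betaine production across fixed exogenous choline uptakes.

    Glucose uptake is fixed at ``glucose_rate``; each sweep point fixes
    choline uptake and maximizes biomass.
    """
    report = verify_pathway(model, BETAINE_PATHWAY_ECS)
    if not report.complete:
        raise PathwayError(f"betaine pathway incomplete, missing EC {report.missing}")
    bet_rxn = resolve_exchange(model, betaine)
    bet_species = next(iter(bet_rxn.stoichiometry)) if bet_rxn is not None else betaine

    def medium_for(rate):
        uptakes = {glucose: glucose_rate}
        if rate > 0:
            uptakes[choline] = rate
        return set_medium(model, uptakes)

    rows = _sweep(model, medium_for, choline_rates, "choline_uptake", bet_species, with_fva)
    return SweepResult(variable="choline_uptake", product="betaine", rows=rows)


def ectoine_production_sweep(
    model: MetabolicModel,
    glucose_rates: Sequence[float] = tuple(range(3, 11)),
    objective: str = "biomass",
    with_fva: bool = True,
    glucose: str = "glucose",
    ectoine: str = "ectoine",
) -> SweepResult:
    """Ectoine production, biomass and molar yield across glucose uptakes.

    Emulates the osmoprotectant-free condition: choline and betaine uptakes
    are closed by the minimal medium and the choline-oxidation reactions are
    knocked out.  ``objective="ectoine"`` maximizes the ectoine exchange
    directly (theoretical production capacity) instead of biomass.
    """
    report = verify_pathway(model, ECTOINE_PATHWAY_ECS)
    if not report.complete:
        raise PathwayError(f"ectoine pathway incomplete, missing EC {report.missing}")
    ko_ids = [r.id for ec in CHOLINE_OXIDATION_ECS for r in model.reactions_by_ec(ec)]
    closed = knock_out(model, ko_ids) if ko_ids else model.copy()
    ect_exchange = resolve_exchange(closed, ectoine)
    ect_species = next(iter(ect_exchange.stoichiometry)) if ect_exchange is not None else ectoine

    rows = []
    fva_targets = _product_reactions(closed, ect_species) + [closed.objective_id]
    for rate in glucose_rates:
        overrides = set_medium(closed, {glucose: rate} if rate > 0 else {})
        if objective == "biomass":
            sol = solve_fba(closed, extra_constraints=overrides).raise_for_status()
            product = production_flux(closed, sol.fluxes, ect_species)
            biomass = sol.objective_value
        elif objective == "ectoine":
            if ect_exchange is None:
                raise PathwayError(f"no exchange found for {ectoine!r}")
            sol = solve_fba(closed, objective_id=ect_exchange.id, extra_constraints=overrides).raise_for_status()
            product = sol.objective_value  # excretion flux
            biomass = sol.fluxes.get(closed.objective_id, 0.0)
        else:
            raise ValueError(f"objective must be 'biomass' or 'ectoine', got {objective!r}")
        row = {
            "glucose_uptake": float(rate),
            "biomass": biomass,
            "product_flux": product,
            "yield": product / rate if rate > 0 else None,
        }
        if with_fva and objective == "biomass":
            fva = flux_variability(closed, extra_constraints=overrides, reactions=fva_targets)
            row["max_variability_pct"] = max(fva.variability_percent.values(), default=0.0)
        rows.append(row)
    return SweepResult(variable="glucose_uptake", product="ectoine", rows=rows)


@dataclass
class AlanineScenario:
    """Growth/ectoine with and without alanine supplementation."""

    baseline_growth: float
    baseline_ectoine: float
    supplemented_growth: float
    supplemented_ectoine: float
    growth_change_percent: float
    ectoine_change_percent: float


def _pct(before: float, after: float) -> float:
    # percent changes on 4-decimal rounded fluxes, matching reported precision
    b, a = round(before, 4), round(after, 4)
    if b == 0:
        raise MediumError("baseline flux rounds to zero; percent change undefined")
    return 100.0 * (a - b) / b


def alanine_scenario(
    model: MetabolicModel,
    glucose_rate: float = 1.0,
    nacl_rate: float = 1.1,
    alanine_rate: float = 1.2,
    glucose: str = "glucose",
    nacl: str = "nacl",
    alanine: str = "alanine",
    ectoine: str = "ectoine",
) -> AlanineScenario:
    """Effect of alanine in the medium on growth and ectoine production.

    Baseline fixes glucose and NaCl uptakes; the treatment adds a fixed
    alanine uptake.  A missing alanine route raises :class:`MediumError`.
    """
    if resolve_exchange(model, alanine) is None:
        raise MediumError(f"substrate {alanine!r} has no uptake route in the model")
    ect_exchange = resolve_exchange(model, ectoine)
    ect_species = next(iter(ect_exchange.stoichiometry)) if ect_exchange is not None else ectoine

    base_uptakes = {glucose: glucose_rate, nacl: nacl_rate}
    base = solve_fba(model, extra_constraints=set_medium(model, base_uptakes)).raise_for_status()
    treat_uptakes = dict(base_uptakes)
    if alanine_rate > 0:
        treat_uptakes[alanine] = alanine_rate
    treat = solve_fba(model, extra_constraints=set_medium(model, treat_uptakes)).raise_for_status()

    b_ect = production_flux(model, base.fluxes, ect_species)
    t_ect = production_flux(model, treat.fluxes, ect_species)
    return AlanineScenario(
        baseline_growth=base.objective_value,
        baseline_ectoine=b_ect,
        supplemented_growth=treat.objective_value,
        supplemented_ectoine=t_ect,
        growth_change_percent=_pct(base.objective_value, treat.objective_value),
        ectoine_change_percent=_pct(b_ect, t_ect),
    )
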