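"""Substrate-utilization phenotype screens and enzyme-activity tests.

A substrate screen grows the model on a minimal medium with one substrate
as the sole carbon source (for amino acids, also the sole nitrogen source:
ammonium is closed) and calls the in-silico verdict "+" when the biomass
optimum exceeds a growth threshold.  An activity test asks whether a named
reaction can carry flux at all under a medium.  ``growth_vs_uptake`` traces
the growth rate against the uptake rate of a single limiting substrate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

from halofba.errors import MediumError
from halofba.fba import resolve_exchange, set_medium, solve_fba
from halofba.formulas import parse_formula
from halofba.model import MetabolicModel

#: biomass flux above which in-silico growth is called "+" (h^-1)
GROWTH_THRESHOLD = 1e-6
#: |flux| above which a reaction is listed as active (mmol/gDW/h)
FLUX_THRESHOLD = 1e-9


@dataclass
class PhenotypeRecord:
    """One row of a substrate screen (the shape of a published phenotype table)."""

    name: str
    in_silico: str  # "+" or "-"
    growth_rate: float
    in_vivo: str | None = None
    transport_reactions: list[str] = field(default_factory=list)
    utilization_reactions: list[str] = field(default_factory=list)
    reason: str = ""

    @property
    def concordant(self) -> bool | None:
        return None if self.in_vivo is None else self.in_vivo == self.in_silico


def _species_base(met_id: str) -> str:
    for suffix in ("[e]", "[c]"):
        if met_id.endswith(suffix):
            return met_id[: -len(suffix)]
    return met_id


def _active_reactions(model: MetabolicModel, fluxes: Mapping[str, float], base: str, kinds) -> list[str]:
    """Reactions of the given kinds carrying flux that touch the substrate species."""
    out = []
    for rxn in model.reactions:
        if rxn.kind not in kinds or abs(fluxes.get(rxn.id, 0.0)) <= FLUX_THRESHOLD:
            continue
        if any(_species_base(m) == base for m in rxn.stoichiometry):
            out.append(rxn.id)
    return out


def _is_nitrogenous(model: MetabolicModel, exchange_rxn) -> bool:
    met = model.metabolite(next(iter(exchange_rxn.stoichiometry)))
    if met.formula is None:
        return False
    try:
        return parse_formula(met.formula).get("N", 0) > 0
    except Exception:
        return False


def substrate_screen(
    model: MetabolicModel,
    substrates: Sequence[str] | Sequence[tuple[str, str]],
    uptake_rate: float = 1.0,
    aerobic: bool = True,
    sole_nitrogen_for_nitrogenous: bool = True,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> list[PhenotypeRecord]:
    """One :class:`PhenotypeRecord` per substrate on a sole-carbon medium.

    ``substrates`` is a list of names, or of ``(name, in_vivo)`` pairs when
    a reference verdict is available.  A substrate without an uptake route
    yields "-" rather than an error; only an invalid model aborts the screen.
    """
    model.validate()
    records: list[PhenotypeRecord] = []
    for item in substrates:
        name, in_vivo = (item, None) if isinstance(item, str) else (item[0], item[1])
        exchange = resolve_exchange(model, name)
        if exchange is None:
            records.append(
                PhenotypeRecord(name=name, in_silico="-", growth_rate=0.0, in_vivo=in_vivo,
                                reason="no transport/exchange route")
            )
            continue
        overrides = set_medium(model, {name: uptake_rate}, aerobic=aerobic)
        if sole_nitrogen_for_nitrogenous and _is_nitrogenous(model, exchange):
            ammonium = resolve_exchange(model, "ammonium") or resolve_exchange(model, "nh4")
            if ammonium is not None:
                overrides[ammonium.id] = (0.0, max(ammonium.upper_bound, 0.0))
        sol = solve_fba(model, extra_constraints=overrides)
        if not sol.optimal:
            records.append(
                PhenotypeRecord(name=name, in_silico="-", growth_rate=0.0, in_vivo=in_vivo,
                                reason=f"FBA {sol.status}")
            )
            continue
        growth = sol.objective_value
        verdict = "+" if growth > growth_threshold else "-"
        base = _species_base(next(iter(exchange.stoichiometry)))
        records.append(
            PhenotypeRecord(
                name=name,
                in_silico=verdict,
                growth_rate=growth,
                in_vivo=in_vivo,
                transport_reactions=_active_reactions(model, sol.fluxes, base, ("transport",)),
                utilization_reactions=_active_reactions(model, sol.fluxes, base, ("enzymatic",)),
                reason="" if verdict == "+" else "no growth",
            )
        )
    return records


def concordance(records: Iterable[PhenotypeRecord]) -> float:
    """Fraction of records whose in-silico verdict matches the in-vivo one."""
    scored = [r for r in records if r.in_vivo is not None]
    if not scored:
        raise MediumError("no records carry an in-vivo verdict")
    return sum(1 for r in scored if r.concordant) / len(scored)


def activity_test(
    model: MetabolicModel,
    target_reaction_id: str,
    medium: Mapping[str, tuple[float, float]] | None = None,
    flux_threshold: float = FLUX_THRESHOLD,
) -> tuple[float, bool]:
    """Maximum attainable |flux| through a reaction under a medium.

    Returns ``(max_abs_flux, verdict)`` with verdict "+" iff the flux
    exceeds the threshold.  ``medium`` is a bound-override map as produced
    by :func:`halofba.fba.set_medium`.
    """
    rxn = model.reaction(target_reaction_id)  # raises on unknown id
    best = 0.0
    for maximize in (True, False) if rxn.lower_bound < 0 else (True,):
        sol = solve_fba(model, objective_id=target_reaction_id, extra_constraints=medium, maximize=maximize)
        if sol.optimal:
            best = max(best, abs(sol.objective_value))
    return best, best > flux_threshold


def growth_vs_uptake(
    model: MetabolicModel,
    substrate: str,
    uptake_rates: Sequence[float],
    aerobic: bool = True,
) -> list[tuple[float, float]]:
    """(uptake rate, FBA growth) pairs for a single limiting substrate."""
    out = []
    for rate in uptake_rates:
        if rate < 0:
            raise MediumError(f"negative uptake rate {rate}")
        overrides = set_medium(model, {substrate: rate}, aerobic=aerobic)
        sol = solve_fba(model, extra_constraints=overrides).raise_for_status()
        out.append((float(rate), sol.objective_value))
    return out


# --------------------------------------------------------------------------
# packaged in-vivo reference (transcription of the published phenotype table)
# --------------------------------------------------------------------------
def load_invivo_reference() -> pd.DataFrame:
    """The packaged in-vivo substrate/activity verdict table.

    Columns: ``entry, type (substrate|activity), in_vivo, transport_reactions,
    utilization_reactions`` — used for offline concordance screens against a
    loaded genome-scale model.
    """
    with resources.files("halofba.data").joinpath("table2_invivo.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str, keep_default_na=False)
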