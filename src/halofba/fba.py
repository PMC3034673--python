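"""Flux balance analysis and flux variability analysis.

FBA solves ``max c.v  s.t.  S.v = 0,  alpha <= v <= beta`` with the biomass
reaction as the default objective; the optimum of the biomass flux is the
specific growth rate (h^-1).  FVA re-solves 2n LPs with the objective pinned
at (a fraction of) its optimum to measure each reaction's admissible flux
range, i.e. the spread of alternate optima.

All LPs go through scipy's HiGHS dual simplex, single-threaded and
deterministic, with feasibility/optimality tolerances of 1e-9.

Sign convention: exchange reactions are stored as ``x[e] <=>`` so a negative
exchange flux is uptake; every user-facing uptake rate (``set_medium``,
sweeps, reports) is a positive number in mmol/gDW/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.optimize import linprog

from halofba.errors import InfeasibleError, MediumError, UnboundedError
from halofba.formulas import parse_formula
from halofba.model import MetabolicModel, Reaction, build_stoichiometric_matrix

SOLVER_METHOD = "highs-ds"
SOLVER_OPTIONS = {
    "primal_feasibility_tolerance": 1e-9,
    "dual_feasibility_tolerance": 1e-9,
}
#: denominator floor for FVA variability percentages
FVA_EPSILON = 1e-6

_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


@dataclass
class FluxSolution:
    """Outcome of one FBA run."""

    status: str
    objective_id: str | None
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def __getitem__(self, rxn_id: str) -> float:
        return self.fluxes[rxn_id]

    def uptake(self, rxn_id: str) -> float:
        """Exchange flux reported on the positive-uptake convention."""
        return -self.fluxes[rxn_id]

    def raise_for_status(self) -> "FluxSolution":
        if self.status == "infeasible":
            raise InfeasibleError("FBA constraints are infeasible")
        if self.status == "unbounded":
            raise UnboundedError("FBA objective is unbounded")
        return self


@dataclass
class FVAResult:
    """Per-reaction flux ranges at a fixed objective value."""

    objective_id: str
    objective_value: float
    fraction: float
    v_fba: dict[str, float]
    v_min: dict[str, float]
    v_max: dict[str, float]

    @property
    def variability_percent(self) -> dict[str, float]:
        return {
            rid: 100.0 * (self.v_max[rid] - self.v_min[rid]) / max(abs(self.v_fba[rid]), FVA_EPSILON)
            for rid in self.v_min
        }

    def span(self, rxn_id: str) -> float:
        return self.v_max[rxn_id] - self.v_min[rxn_id]

    def to_dataframe(self) -> pd.DataFrame:
        var = self.variability_percent
        return pd.DataFrame(
            {
                "reaction_id": list(self.v_min),
                "flux": [self.v_fba[r] for r in self.v_min],
                "vmin": [self.v_min[r] for r in self.v_min],
                "vmax": [self.v_max[r] for r in self.v_min],
                "variability_pct": [var[r] for r in self.v_min],
            }
        )


def _lp_arrays(model: MetabolicModel, extra_constraints: Mapping[str, tuple[float, float]] | None):
    matrix = build_stoichiometric_matrix(model)
    bounds = [[r.lower_bound, r.upper_bound] for r in model.reactions]
    if extra_constraints:
        index = model.reaction_index
        for rid, (lo, hi) in extra_constraints.items():
            if rid not in index:
                raise MediumError(f"constraint on unknown reaction {rid!r}")
            bounds[index[rid]] = [lo, hi]
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    return matrix, lo, hi


def _run_lp(S, lo, hi, c):
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lo, hi]),
        method=SOLVER_METHOD,
        options=dict(SOLVER_OPTIONS),
    )
    return res


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    extra_constraints: Mapping[str, tuple[float, float]] | None = None,
    maximize: bool = True,
) -> FluxSolution:
    """Maximize (or minimize) the objective reaction flux at steady state.

    Infeasibility and unboundedness are reported distinctly on
    ``FluxSolution.status``, never as a zero optimum.
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise MediumError("no objective reaction given and the model declares none")
    j = model.reaction_index.get(objective_id)
    if j is None:
        raise MediumError(f"objective reaction {objective_id!r} not in model")
    matrix, lo, hi = _lp_arrays(model, extra_constraints)
    c = np.zeros(matrix.n)
    c[j] = -1.0 if maximize else 1.0
    res = _run_lp(matrix.S, lo, hi, c)
    status = _STATUS.get(res.status, f"solver-status-{res.status}")
    if status != "optimal":
        return FluxSolution(status=status, objective_id=objective_id, objective_value=None)
    fluxes = {r.id: float(v) for r, v in zip(model.reactions, res.x)}
    return FluxSolution(
        status="optimal",
        objective_id=objective_id,
        objective_value=float(fluxes[objective_id]),
        fluxes=fluxes,
    )


def flux_variability(
    model: MetabolicModel,
    objective_id: str | None = None,
    fraction: float = 1.0,
    reactions: Iterable[str] | None = None,
    extra_constraints: Mapping[str, tuple[float, float]] | None = None,
) -> FVAResult:
    """Min/max each reaction's flux with the objective fixed at
    ``fraction`` x its FBA optimum."""
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    objective_id = objective_id or model.objective_id
    sol = solve_fba(model, objective_id, extra_constraints).raise_for_status()
    matrix, lo, hi = _lp_arrays(model, extra_constraints)
    j = model.reaction_index[objective_id]
    target = fraction * sol.objective_value
    # pin the objective; the slack absorbs solver round-off and must stay
    # comfortably above the 1e-9 feasibility tolerance or presolve rejects
    # the near-degenerate interval
    slack = 1e-7 * max(1.0, abs(target))
    lo[j] = max(lo[j], target - slack)
    hi[j] = min(hi[j], sol.objective_value + slack)

    wanted = list(reactions) if reactions is not None else [r.id for r in model.reactions]
    index = model.reaction_index
    v_min, v_max = {}, {}
    for rid in wanted:
        k = index[rid]
        c = np.zeros(matrix.n)
        c[k] = 1.0
        lo_res = _run_lp(matrix.S, lo, hi, c)
        c[k] = -1.0
        hi_res = _run_lp(matrix.S, lo, hi, c)
        if lo_res.status != 0 or hi_res.status != 0:
            raise InfeasibleError(f"FVA subproblem for {rid} returned status {lo_res.status}/{hi_res.status}")
        v_min[rid] = float(lo_res.x[k])
        v_max[rid] = float(hi_res.x[k])
    return FVAResult(
        objective_id=objective_id,
        objective_value=sol.objective_value,
        fraction=fraction,
        v_fba={rid: sol.fluxes[rid] for rid in wanted},
        v_min=v_min,
        v_max=v_max,
    )


# --------------------------------------------------------------------------
# media
# --------------------------------------------------------------------------
#: formulas treated as freely exchangeable despite containing carbon
_INORGANIC_CARBON = {"CO2", "CHO3", "CO3"}


def _exchange_metabolite(model: MetabolicModel, rxn: Reaction):
    mets = list(rxn.stoichiometry)
    return model.metabolite(mets[0]) if len(mets) == 1 else None


def _is_organic(met) -> bool:
    if met.formula is None:
        return True  # unknown composition: conservatively treat as a carbon source
    if met.formula in _INORGANIC_CARBON:
        return False
    try:
        return parse_formula(met.formula).get("C", 0) > 0
    except Exception:
        return True


def resolve_exchange(model: MetabolicModel, substrate: str) -> Reaction | None:
    """Find the exchange reaction for a substrate named by metabolite id or name."""
    needle = substrate.strip().lower()
    for rxn in model.exchanges():
        met = _exchange_metabolite(model, rxn)
        if met is None:
            continue
        candidates = {met.id.lower(), met.id.lower().removesuffix("[e]"), met.name.lower(), rxn.id.lower()}
        if needle in candidates:
            return rxn
    return None


def set_medium(
    model: MetabolicModel,
    uptake_map: Mapping[str, float],
    aerobic: bool = True,
    mode: str = "fixed",
) -> dict[str, tuple[float, float]]:
    """Bound overrides implementing a defined medium.

    Each named substrate's uptake is fixed at its rate (``mode="fixed"``:
    alpha = beta = rate) or capped at it (``mode="max"``).  Every other
    organic-carbon uptake is closed; carbon-free species (water, phosphate,
    ammonium, sulfate, Na+, Cl-, protons...) and inorganic carbon stay open,
    as does O2 when ``aerobic``.  Rates are positive mmol/gDW/h; internally
    an uptake is a negative exchange flux.
    """
    if mode not in ("fixed", "max"):
        raise ValueError(f"mode must be 'fixed' or 'max', got {mode!r}")
    overrides: dict[str, tuple[float, float]] = {}
    named: dict[str, float] = {}
    for substrate, rate in uptake_map.items():
        if rate < 0:
            raise MediumError(f"uptake rate for {substrate!r} must be non-negative, got {rate}")
        rxn = resolve_exchange(model, substrate)
        if rxn is None:
            raise MediumError(f"substrate {substrate!r} has no exchange/uptake route in the model")
        named[rxn.id] = float(rate)
    for rxn in model.exchanges():
        met = _exchange_metabolite(model, rxn)
        if rxn.id in named:
            rate = named[rxn.id]
            if mode == "fixed":
                overrides[rxn.id] = (-rate, -rate if rate > 0 else max(rxn.upper_bound, 0.0))
            else:
                overrides[rxn.id] = (-rate, max(rxn.upper_bound, 0.0))
            continue
        if met is not None and met.formula is not None and met.formula == "O2":
            overrides[rxn.id] = (rxn.lower_bound if aerobic else 0.0, rxn.upper_bound)
            continue
        if met is None or _is_organic(met):
            overrides[rxn.id] = (0.0, max(rxn.upper_bound, 0.0))  # secretion only
        # carbon-free species: leave the model's own bounds in place
    return overrides
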