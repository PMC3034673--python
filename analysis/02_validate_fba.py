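#!/usr/bin/env python
"""Validate the LP engine and simulate growth under defined media.

Cross-checks the simplex against exhaustive vertex enumeration on random
toys, verifies steady state, then runs the fixture's aerobic / nitrate-
respiring media and the growth-vs-glucose-uptake curve.

Writes results/fba_validation.json and results/growth_vs_uptake.tsv.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from halofba.bruteforce import brute_force_fba_optimum
from halofba.fba import set_medium, solve_fba
from halofba.model import build_stoichiometric_matrix
from halofba.phenotype import growth_vs_uptake
from halofba.synth import make_mini_halophile, make_random_fba_toy

RESULTS = Path(__file__).resolve().parent.parent / "results"
N_TOYS = 200


def main():
    worst = 0.0
    for seed in range(N_TOYS):
        model, objective = make_random_fba_toy(seed)
        sol = solve_fba(model, objective_id=objective)
        ref = brute_force_fba_optimum(model, objective)
        worst = max(worst, abs(sol.objective_value - ref))
    print(f"simplex vs vertex enumeration on {N_TOYS} random toys: max |diff| = {worst:.3g}")

    mini = make_mini_halophile()
    aerobic = solve_fba(mini, extra_constraints=set_medium(mini, {"glucose": 3}))
    anaerobic = solve_fba(
        mini, extra_constraints=set_medium(mini, {"glucose": 3, "oxygen": 0, "nitrate": 1}, aerobic=False)
    )
    S = build_stoichiometric_matrix(mini).S
    v = np.array([aerobic.fluxes[r.id] for r in mini.reactions])
    residual = float(np.max(np.abs(S @ v)))
    print(f"fixture growth, glucose 3 mmol/gDW/h: aerobic {aerobic.objective_value:.4f} h^-1, "
          f"anaerobic (nitrate 1) {anaerobic.objective_value:.4f} h^-1")
    print(f"steady-state residual at the aerobic optimum: {residual:.3g}")

    curve = growth_vs_uptake(mini, "glucose", [0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 10.0])
    pd.DataFrame(curve, columns=["glucose_uptake", "growth_rate"]).to_csv(
        RESULTS / "growth_vs_uptake.tsv", sep="\t", index=False
    )
    (RESULTS / "fba_validation.json").write_text(json.dumps({
        "vertex_oracle_max_abs_diff": worst,
        "n_random_toys": N_TOYS,
        "aerobic_growth_glc3": round(aerobic.objective_value, 4),
        "anaerobic_growth_glc3_no3_1": round(anaerobic.objective_value, 4),
        "steady_state_residual": residual,
    }, indent=1))
    print(f"growth curve ({len(curve)} points) -> results/growth_vs_uptake.tsv")


if __name__ == "__main__":
    main()
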