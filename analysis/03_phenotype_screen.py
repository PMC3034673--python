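#!/usr/bin/env python
"""Substrate-utilization screen and enzyme-activity tests on the fixture.

Each substrate is offered as the sole carbon (and, for nitrogenous
substrates, nitrogen) source; the in-silico verdict is compared with the
fixture's declared in-vivo column.  Writes results/phenotype.tsv.
"""

from pathlib import Path

import pandas as pd

from halofba.fba import set_medium
from halofba.model import knock_out
from halofba.phenotype import activity_test, concordance, substrate_screen
from halofba.synth import MINI_HALOPHILE_INVIVO, make_mini_halophile

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    mini = make_mini_halophile()
    records = substrate_screen(mini, MINI_HALOPHILE_INVIVO, uptake_rate=3.0)
    df = pd.DataFrame(
        {
            "substrate": [r.name for r in records],
            "in_vivo": [r.in_vivo for r in records],
            "in_silico": [r.in_silico for r in records],
            "growth_rate": [round(r.growth_rate, 4) for r in records],
            "transport_reactions": [";".join(r.transport_reactions) for r in records],
            "utilization_reactions": [";".join(r.utilization_reactions) for r in records],
        }
    )
    df.to_csv(RESULTS / "phenotype.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    print(f"substrate concordance: {concordance(records):.2%}")

    glc_medium = set_medium(mini, {"glucose": 3})
    cat_flux, cat_ok = activity_test(mini, "CAT", glc_medium)
    nar_flux, nar_ok = activity_test(
        mini, "NAR", set_medium(mini, {"glucose": 3, "nitrate": 1}, aerobic=False)
    )
    no_nox = knock_out(mini, ["NOX"])
    ko_flux, ko_ok = activity_test(no_nox, "CAT", set_medium(no_nox, {"glucose": 3}))
    print(f"catalase activity on glucose: {'+' if cat_ok else '-'} (max flux {cat_flux:.3g})")
    print(f"catalase without the peroxide source: {'+' if ko_ok else '-'} (max flux {ko_flux:.3g})")
    print(f"nitrate reduction on nitrate medium: {'+' if nar_ok else '-'} (max flux {nar_flux:.3g})")


if __name__ == "__main__":
    main()
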