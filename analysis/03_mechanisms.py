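#!/usr/bin/env python
"""Why dynamic Fe allocation helps: the O2-budget decomposition.

Compares the optimized dynamic and fixed runs at the two standard Fe levels
(40 and 1250 pM, sinusoidal light) and decomposes the daily intracellular O2
budget into LPET production, respiratory-protection (RP) consumption and
physical exchange.  Two mechanisms are quantified:

  1. releasing photosystem Fe during the N2-fixation window lowers O2
     production, so less carbohydrate must be burned by RP (carbon saved);
  2. starting the day with little nitrogenase means less Fe is trapped in
     O2-inactivated nitrogenase while morning photosynthesis runs hot.

Writes results/table2_style.tsv, results/mechanisms.tsv and
results/fe_trapped_<level>.tsv.
"""

from pathlib import Path

import pandas as pd

from trichofe import CaseConfig, Forcing, ParameterSet, default_initial_fractions
from trichofe.experiments import decompose_mechanisms, optimize_and_run

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = ParameterSet()
forcing = Forcing(mode="sinusoidal")

table_rows, mech_rows = [], []
for Fe in (40.0, 1250.0):
    fPS, fNF = default_initial_fractions(Fe, params.f_maint)
    runs = {}
    for mode in ("dynamic", "fixed"):
        case = CaseConfig(mode=mode, fFe0PS=fPS, fFe0NF=fNF)
        runs[mode], _ = optimize_and_run(params, forcing, case, Fe,
                                         n_starts=8, seed=1234)
        s = runs[mode]
        table_rows.append({
            "Fe_prime_pM": Fe, "mode": mode, "G": s.G, "grossCF": s.grossCF,
            "NF_daily": s.NF_daily, "CN_ratio": s.CN_ratio,
            "RP_fraction_pct": s.RP_fraction, "CUE_pct": s.CUE,
        })
    mech = decompose_mechanisms(runs["dynamic"], runs["fixed"])
    mech_rows.append({
        "Fe_prime_pM": Fe,
        "dO2_production_pct": mech.dO2_production_pct,
        "dRP_pct": mech.dRP_pct,
        "max_Fe_trapped_diff": mech.Fe_trapped_inactive["diff"].min(),
    })
    # 6-min resolution is plenty for the trapped-Fe contrast
    mech.Fe_trapped_inactive.iloc[::36].to_csv(OUT / f"fe_trapped_{Fe:g}pM.tsv",
                                               sep="\t", index=False)

table = pd.DataFrame(table_rows)
table.to_csv(OUT / "table2_style.tsv", sep="\t", index=False)
mechs = pd.DataFrame(mech_rows)
mechs.to_csv(OUT / "mechanisms.tsv", sep="\t", index=False)

print("Daily-integrated rates (optimized cases):")
print(table.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nO2-budget changes, dynamic relative to fixed (negative = reduction):")
print(mechs.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print("\nExpected pattern: dynamic allocation grows faster on less gross "
      "carbon (higher CUE), with lower O2 production and a smaller RP burn; "
      "the trapped-Fe series (negative diff) shows dynamic allocation keeps "
      "less Fe locked in inactivated nitrogenase.")
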