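#!/usr/bin/env python
"""Follow-up experiments: how much more could flexible allocation buy?

Three variants per Fe level, each against the standard optimized dynamic and
fixed cases:

  (i)   dynamic allocation that also optimizes the dawn photosystem and
        nitrogenase Fe fractions (instead of using the culture-observed ones);
  (ii)  instant decomposition of O2-inactivated nitrogenase (its Fe returns
        to the buffer immediately);
  (iii) variant (ii) started with photosystems holding all allocatable
        (90% of metabolic) Fe.

Writes results/followup.tsv.
"""

from pathlib import Path

from trichofe import Forcing, ParameterSet
from trichofe.experiments import run_followup_experiments

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = ParameterSet()
forcing = Forcing(mode="sinusoidal")

df = run_followup_experiments(params, forcing, n_starts=8, seed=1234)
df.to_csv(OUT / "followup.tsv", sep="\t", index=False)
print(df.to_string(index=False, float_format=lambda v: f"{v:.4g}"))

low = df[df.Fe_prime_pM == df.Fe_prime_pM.min()].set_index("variant")
print("\nReading the table: gain_vs_dynamic_pct measures how much growth the "
      "standard dynamic case leaves on the table by starting from the "
      "observed dawn allocation (opt_initial_pools) or by having to write "
      "off O2-inactivated nitrogenase for the rest of the day "
      "(instant_decomposition).  At the low-Fe level the dawn-allocation "
      f"flexibility is worth {low.loc['opt_initial_pools', 'gain_vs_dynamic_pct']:+.1f}% "
      f"and recycling inactivated nitrogenase {low.loc['instant_decomposition', 'gain_vs_dynamic_pct']:+.1f}%; "
      "under high Fe both margins shrink to a few percent because the pools "
      "are no longer iron-limited.")
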