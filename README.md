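# trichofe

*Trichodesmium* is the dominant nitrogen-fixing cyanobacterium of the
oligotrophic surface ocean, and iron limits it doubly: its nitrogenase is
one of the most Fe-expensive enzymes in biology, and the O₂ produced by its
own photosynthesis irreversibly inactivates that enzyme during the very
hours both processes must run.  `trichofe` is an eco-physiological model of
a *Trichodesmium* trichome over one 12-hour light period in which
intracellular iron is a dynamic resource: it can be re-allocated during the
day among photosystems, a buffer pool, and active nitrogenase — or held
fixed — so the value of diurnal Fe re-allocation can be quantified as the
growth difference between the two strategies across an ambient-iron
gradient.

## The model in brief

Eight states are integrated with fixed-step RK4 (dt = 10 s): carbohydrate
CH₂O, carbon skeletons CS, fixed nitrogen N, intracellular O₂, and four Fe
pools (photosystems, active and O₂-inactivated nitrogenase, buffer).  The
core laws, in the field's standard notation:

* photosynthetic electron transport
  `V_PET = vPETmax · FePS/(FePS+kFePS) · (1−e^(−αI·I)) · e^(−β·V_RP)`;
* an instantaneous ATP/NADPH budget that splits electrons between the
  linear (ATP + NADPH + O₂) and alternative (ATP-only) pathways so both
  currencies are exactly co-exhausted, yielding the N₂-fixation ceiling
  V_NFmax and the carbon-fixation rate V_CF;
* realized N₂ fixation
  `V_NF = V_NFmax · FeNF/(FeNF+kFeNF) · (1 − O₂/(O₂+kO2NF))`;
* respiratory protection `V_RP = vRPmax · Φ · kO2RP/(O₂+kO2RP)` — carbon
  burned solely to hold intracellular O₂ down, its ATP wasted as heat —
  driven by the demand signal
  `Φ = (1−e^(−αI·I)) · CS/(CS+kCS) · (N_max−N)/N_max`;
* Fe translocation: light-stimulated photosystem synthesis from the buffer,
  RP-inhibited decomposition back into it, Φ-driven nitrogenase synthesis,
  and O₂-driven irreversible inactivation
  `TNFmaxNA · FeNF/(FeNF+kFeNF) · O₂/(O₂+kO2NF)` (inactivated nitrogenase
  keeps its Fe until night);
* growth from the dusk pools,
  `G = ln(1 + min(N/q_N, CS, CH₂O/(1+c_bio)))` per day.

Each case optimizes its regulatory constants to maximize G (multistart
Nelder–Mead: fixed-Fe case — RP capacity and the dawn PS/NF fractions;
dynamic-Fe case — RP capacity and the three translocation maxima, with dawn
fractions from culture observations).  See `docs/methods.md` for the full
account, calibration story, and known limitations.

## Worked example

```python
from trichofe import ParameterSet, Forcing, CaseConfig, run_case, default_initial_fractions

params = ParameterSet()                       # shipped calibrated defaults
forcing = Forcing(mode="constant", I_const=90.0)
fPS, fNF = default_initial_fractions(40.0)    # observed dawn Fe fractions
case = CaseConfig(mode="dynamic", fFe0PS=fPS, fFe0NF=fNF)
s = run_case(params, forcing, case, Fe_prime=40.0)
print(f"G = {s.G:.3f} /d, gross CF = {s.grossCF:.2f}, "
      f"N2 fixation = {s.NF_daily:.4f} mol N (mol C)^-1 d^-1")
```

prints (at the shipped defaults, before growth-optimizing the free
parameters)

```
G = 0.154 /d, gross CF = 3.22, N2 fixation = 0.0264 mol N (mol C)^-1 d^-1
```

i.e. an Fe-depleted (40 pM), constant-light day fixes ~3.2 mol C and
~0.026 mol N per mol cell C.  With the case's free parameters optimized
(`trichofe.experiments.optimize_and_run`) the same condition reaches
G ≈ 0.28 d⁻¹, matching the Fe-depleted culture growth rate; the Fe-replete
condition (1250 pM) reaches G ≈ 0.45 d⁻¹.  `s.time_series` holds the full
diurnal record (states, fluxes, cumulative integrals) as a DataFrame.

The analysis proper lives in `analysis/`:

| script | what it does |
| --- | --- |
| `01_calibrate_constant_light.py` | constant-light calibration check: growth targets, Fe-trajectory R², and a two-parameter refit from perturbed values |
| `02_fe_gradient.py` | ten-level Fe′ gradient (20–1800 pM), both allocation modes re-optimized per level |
| `03_mechanisms.py` | dynamic-vs-fixed O₂-budget decomposition and the trapped-Fe series at 40 / 1250 pM |
| `04_followups.py` | allocation-flexibility experiments (optimized dawn pools; instant nitrogenase decomposition; 90 %-photosystem start) |

Each writes delimited-text tables under `results/`.  A `trichofe` console
command exposes the same steps (`simulate`, `calibrate`, `synth`,
`gradient`, `compare`, `followup`) for shell use.

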