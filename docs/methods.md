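# Methods

## The model in one paragraph

`trichofe` simulates one 12-hour light period of a *Trichodesmium* trichome.
Eight state variables are integrated: carbohydrate (CH₂O) and carbon-skeleton
(CS) pools, the fixed-nitrogen store N, intracellular O₂, and four iron pools
— photosystems (FePS), active nitrogenase (FeNF_act), O₂-inactivated
nitrogenase (FeNF_inact) and a buffer (FeBF) — all normalised to cellular
carbon.  Photosynthetic electron transport (PET) supplies ATP and NADPH;
carbon fixation, N₂ fixation and maintenance consume them; respiratory
protection (RP) burns carbohydrate purely to draw down intracellular O₂ so
nitrogenase can work; and during the day iron is translocated between
photosystems, the buffer and nitrogenase ("dynamic-Fe" case) or held fixed
("fixed-Fe" case, in which only O₂ inactivation of nitrogenase still moves
iron).  The pools accumulated by dusk are converted into one night's biomass
increment and a daily growth rate.  Case-specific regulatory constants are
optimized to maximize that growth rate, reflecting the premise that the
organism tunes its regulation to grow as fast as its environment allows.

## Process laws

All symbols are model parameters (`trichofe.params.ParameterSet`) with units
in the dataclass docstring.

* **Light.** Constant (`I_const`, culture conditions) or half-sine
  `I(t) = I_max·sin(πt/T)` over the photoperiod `T` = 43 200 s.
* **Iron partition.** The total quota is the sum of two saturating uptake
  systems — multiphasic uptake kinetics:
  `Q = Q0_max·Fe′/(Fe′+K0_Fe) + Q_max·Fe′²/(Fe′²+K_Fe²)`, a high-affinity
  transporter (K0 = 2 pM) essentially saturated at the Fe-depleted end of
  the gradient plus a cooperative low-affinity system (K = 600 pM) carrying
  the rise toward Fe-replete conditions.  A single Michaelis-Menten quota
  curve cannot hold the quota nearly flat between 20 and 40 pM (which the
  fixed-allocation strategy needs to remain viable at the gradient's low
  end) while still tripling it by 1250 pM and plateauing beyond; the
  two-system form does, and both systems' constants are calibration
  parameters.  A storage ("luxury uptake") fraction
  `f_sto = f_sto_max·Fe′/(Fe′+K_sto)` is diverted to storage; 10% of the
  remaining metabolic iron runs maintenance and 90% is allocatable among
  photosystems, nitrogenase and buffer.
* **PET.** `V_PET = vPETmax · FePS/(FePS+kFePS) · (1−e^(−αI·I)) · e^(−β·V_RP)`:
  Michaelis in photosystem iron, saturating in light, exponentially inhibited
  by respiratory protection.
* **Energy split.** PET electrons divide between the linear pathway (LPET:
  ATP + NADPH + O₂) and the alternative pathway (AET: ATP only).  At every
  instant the LPET fraction x is chosen so the co-limited flux is maximal;
  at an interior optimum this means ATP and NADPH are *exactly*
  co-exhausted.  The split is solved twice: first with all post-maintenance
  supply directed to N₂ fixation, which defines the energetic ceiling
  `V_NFmax`; then, with the realized iron- and O₂-limited `V_NF`
  (`V_NF = V_NFmax · FeNF/(FeNF+kFeNF) · (1 − O₂/(O₂+kO2NF))`), carbon
  fixation absorbs the remainder, defining `V_CF` and the final x.  If PET
  cannot cover the maintenance ATP drain, ordinary respiration (RESP) closes
  the deficit and no fixation runs.
* **Carbon skeletons.** `V_CS = vCSmax · CH₂O/(CH₂O+kCH2O) · kCSi/(CS+kCSi)`,
  consuming carbohydrate one-to-one; the product-inhibition term keeps the
  skeleton pool from accumulating far beyond what biosynthesis can use.
* **Respiratory protection.** The demand signal
  `Φ = (1−e^(−αI·I)) · CS/(CS+kCS) · (N_max−N)/N_max` rises with light and
  skeleton availability and falls as the nitrogen store fills;
  `V_RP = vRPmax · Φ · kO2RP/(O₂+kO2RP)`.  Within the integrator the
  realized RP additionally rolls off with its substrates
  (`O₂/(O₂+0.02)` and `CH₂O/(CH₂O+0.01)`); see *Numerics*.
* **O₂.** `dO₂/dt = ρ_C·(x·V_PET/4 − V_RP − V_RESP) + κ_O2·(O₂amb − O₂)`,
  with `ρ_C` an effective carbon density converting per-carbon rates into
  concentrations in the trichome's (colony-scale) water volume and `κ_O2` a
  lumped first-order exchange constant.  The window behaviour depends on the
  production-to-exchange ratio, which calibration sets; the two constants
  are not interpreted individually.
* **Iron translocation (dynamic case).** Photosystem synthesis from the
  buffer `TPSmaxBF·(1−e^(−αI·I))·(1−FePS/(FePS+kFePS_syn))`; decomposition
  back into the buffer `TBFmaxPS·FePS/(FePS+kFePS_dec)·e^(−β·V_RP)`;
  nitrogenase synthesis `TNFmaxBF·Φ·FeBF/(FeBF+kFeBF_syn)`; O₂ inactivation
  `TNFmaxNA·FeNF/(FeNF+kFeNF)·O₂/(O₂+kO2NF)`.  Inactivated nitrogenase
  keeps its iron for the rest of the day (nighttime decomposition is outside
  the simulated window) unless the instant-decomposition experiment routes
  the flux straight back to the buffer.  In the fixed-Fe case synthesis and
  decomposition are frozen and only inactivation moves iron.
* **Growth.** With dusk state (CH₂O_T, CS_T, N_T), the biomass increment is
  `ΔB = min(N_T/q_N, CS_T, CH₂O_T/(1+c_bio))` — nitrogen at the biomass
  quota `q_N` = 1/6.3 mol N (mol C)⁻¹, carbon skeletons, or carbohydrate
  net of the biosynthesis energy cost `c_bio` = 0.4 C respired per C
  assembled — and `G = ln(1+ΔB)` d⁻¹ (the culture-dilution definition).
  The published daily-rate tables are internally consistent with exactly
  this rule binding on nitrogen (G = ln(1 + 6.3·NF_daily) reproduces every
  row), which motivated adopting it.

## Optimized versus calibrated constants

Two distinct fitting notions are used, mirroring the study design:

* **Growth-maximized (per case and Fe level):** fixed-Fe case — `vRPmax`
  and the dawn fractions `fFe0PS`, `fFe0NF`; dynamic-Fe case — `vRPmax`,
  `TPSmaxBF`, `TBFmaxPS`, `TNFmaxBF` (dawn fractions come from culture
  observations: nitrogenase holds 15% of metabolic Fe at 40 pM and 41% at
  1250 pM, interpolated along Fe′ by a saturating curve between the observed
  conditions and held at the observed low-Fe value below 40 pM, with the
  buffer starting at 10%).  Optimization is multistart Nelder–Mead from
  Latin-hypercube starts (default 32; the shipped experiments use 8), with a
  fixed seed.  The growth landscape is multimodal — a low-O₂ window forms
  only beyond a threshold RP capacity, and the dynamic case has a second
  optimum family that strips photosystems hard and rebuilds nitrogenase —
  so the local searches are additionally seeded with coarse geometric
  sweeps along `vRPmax` from the defaults and from that
  decompose-and-rebuild archetype, and the incumbent optimum gets a final
  polish restart.  These deterministic informed starts make the optimizer's
  outcome reproducible across seeds instead of depending on which basin the
  quasi-random draw happens to reach; the reported comparisons are
  therefore between fully, and equally, optimized strategies.
* **Calibrated once (shipped defaults):** everything the growth optimizer
  does not touch — the uptake curve (`Q0_max`, `K0_Fe`, `Q_max`, `K_Fe`,
  `f_sto_max`, `K_sto`), `vPETmax`, the half-saturations, `N_max`,
  `TNFmaxNA`, the O₂ exchange pair and `I_max` — was fitted against the
  study's benchmark values: constant-light growth
  0.26/0.46 d⁻¹ at 40/1250 pM, the sinusoidal-light daily-rate table, and
  the decline of the dynamic-allocation growth benefit from ~20% at the
  Fe-depleted end of the gradient to a few percent at the replete end.
  Not every published number could be met simultaneously; see
  *Known limitations*.  Energy stoichiometries are standard
  bioenergetics and were not fitted: 4 e⁻ per O₂, 0.5 NADPH and 1 ATP per
  LPET electron, 1.5 ATP per AET electron, 4.5 ATP + 2 NADPH per C fixed
  (including a CO₂-concentrating surcharge), 8 ATP + 2 NADPH per N fixed,
  4.5 ATP per C respired.

## Numerics

* Fixed-step classical RK4, dt = 10 s (4320 steps per day).  Daily integrals
  accumulate with the same stage weights as the state update, so discrete
  budget identities (O₂ budget, reported integrals) close to machine
  precision; step-halving changes the daily growth rate by < 10⁻³ d⁻¹.
* Non-negativity is enforced by flux limiting inside the right-hand side: a
  flux consuming a pool is scaled so the pool cannot be driven below zero
  within one step, and consumers of a shared pool are scaled together.
  Respiratory protection additionally carries smooth substrate saturations
  in O₂ (half-saturation 0.02 mol m⁻³) and carbohydrate (0.01 mol C
  (mol C)⁻¹); without them the hard per-step caps switch discontinuously
  when RP capacity exceeds supply, and the solution chatters at dt = 10 s.
  The two constants are numerical regularisations, not calibration targets.
* The energy split is solved in closed form (the limitation curves are
  linear in x); tests verify it against a dense-grid scan oracle.
* Iron-pool tendencies are built from pairwise transfers, so allocatable
  iron is conserved to round-off over the day (< 10⁻⁹ relative).

## Synthetic observations

`trichofe.synthetic` generates the calibration pseudo-data: monotone
saturating-exponential templates for the diurnal photosystem and (total)
nitrogenase Fe quotas at both culture conditions, anchored at the observed
dawn fractions and bounded by the allocatable quota, plus the growth targets
0.26 ± 0.02 and 0.46 ± 0.01 d⁻¹.  Observation noise is multiplicative
lognormal (default CV 0.15, mean-preserving) at 5 evenly spaced times per
day, a typical culture sampling density.  These are declared stand-ins for
the unavailable raw culture data: they emulate the *pattern* (monotone
trends, dawn allocation, magnitudes within the quota) but not protein-level
measurement structure, replicate correlation, or day-to-day variability — so
passing calibration tests shows the machinery recovers parameters from data
of this shape, not that the model is validated against real measurements.
Nitrogenase observations are compared against active + inactivated model
pools, since protein assays do not distinguish the two.

## Design choices where the design was open

* **O₂ control of RP** follows the stated behaviour literally (RP decreases
  as O₂ rises, shape constant `kO2RP`).  This makes RP self-reinforcing once
  O₂ falls; stability comes from the substrate saturations and from Φ
  shutting RP down as the N store fills.
* **Ordinary respiration** exists only as a maintenance-deficit closure; it
  never runs while PET covers maintenance.
* **Initial state:** CH₂O = CS = 0.01, N = 0, O₂ equilibrated with the
  medium; dawn iron fractions as above, inactivated nitrogenase empty
  (nighttime resynthesis).
* **Gradient levels:** ten log-spaced levels over 20–1800 pM, re-optimizing
  both cases per level, each level's search warm-started from its
  neighbour's optimum (the landscape varies smoothly along the gradient);
  `I_max` (unconstrained by the culture data, which are constant-light) was
  calibrated alongside the other shipped constants rather than set to a
  nominal midday irradiance — with the calibrated light slope, a nominal
  800-peak sine would deliver more integrated light drive than the cultures
  the model is fitted to.
* **Φ uses instantaneous CS and N** (no smoothing).

## Problem sizes

The shipped experiments use dt = 10 s, 8 multistart points per optimization
and ten gradient levels; these sizes make the full analysis reproducible on
a laptop-class single core in well under an hour while leaving the reported
percentages stable to re-seeding within about one percentage point.

## Known limitations

* **Coupled benefit and O₂-production signals.** In this model the
  optimized dynamic case earns most of its advantage by stripping
  photosystem Fe and rebuilding nitrogenase inside the low-O₂ window.  The
  same Fe movement that produces the ~20–25% low-Fe growth benefit and the
  ~+15% gain from freeing the dawn allocation necessarily lowers the
  dynamic case's daily O₂ production by ~20–25% relative to the fixed case
  (and its respiratory-protection burn by ~40%).  Calibrations that damp
  the O₂-production difference to a few percent (an Fe-saturated PET, i.e.
  small `kFePS`) also collapse the growth benefit and the dawn-allocation
  gain to a few percent: with the main-text process laws these quantities
  cannot be tuned independently.  The shipped calibration favours the
  growth-benefit pattern and the culture growth rates, and reports the
  O₂-budget decomposition as the model actually computes it.
* The O₂ pool is zero-dimensional; colony microenvironments, spatial
  segregation along the trichome and boundary-layer structure are not
  represented (ρ_C and κ_O2 lump them).
* Nighttime metabolism is not resolved: biosynthesis is a single end-of-day
  conversion, and nitrogenase decomposition/resynthesis kinetics at night
  are outside the model.
* Iron in the respiratory electron chain is not a separate pool.
* Spectral light, photoinhibition and temperature dependence are out of
  scope; the light response is a single saturating curve.
* The growth law's min-rule treats the three dusk pools as substitutable
  only at the margin; co-limitation shapes between the caps are not
  modelled.
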