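alloc.TBFmaxPS: 0.0005
alloc.TNFmaxBF: 0.0005
alloc.TNFmaxNA: 0.00045
alloc.TPSmaxBF: 0.0005
alloc.kFeBF_syn: 2.0
alloc.kFePS_dec: 4.75
alloc.kFePS_syn: 4.75
case.decompose_inactivated: false
case.fFe0NF: 0.15
case.fFe0PS: 0.65
case.mode: dynamic
case.optimize_initial_pools: false
cs.kCH2O: 0.1
cs.kCSi: 0.35
cs.vCSmax: 3.5e-05
energy.atp_maintenance: 2.0e-06
energy.atp_per_C_CF: 4.5
energy.atp_per_C_RESP: 4.5
energy.atp_per_N_NF: 8.0
energy.atp_per_e_AET: 1.5
energy.atp_per_e_LPET: 1.0
energy.e_per_O2: 4.0
energy.nadph_per_C_CF: 2.0
energy.nadph_per_N_NF: 2.0
energy.nadph_per_e_LPET: 0.5
environment.Fe_prime_pM: 40.0
environment.O2_ambient: 0.21
exchange.kappa_O2: 0.005
exchange.rho_C: 60.0
forcing.I_const: 90.0
forcing.I_max: 275.0
forcing.day_length_s: 43200.0
forcing.mode: sinusoidal
growth.c_bio: 0.4
growth.q_N: 0.15873015873015872
nfix.N_max: 0.115
nfix.kCS: 0.2
nfix.kFeNF: 5.0
nfix.kO2NF: 0.02
photo.alpha_I: 0.02
photo.beta: 3000.0
photo.kFePS: 4.75
photo.vPETmax: 0.000735
rp.kO2RP: 0.5
rp.vRPmax: 0.0002
uptake.K0_Fe: 2.0
uptake.K_Fe: 600.0
uptake.K_sto: 600.0
uptake.Q0_max: 16.9
uptake.Q_max: 41.5
uptake.f_maint: 0.1
uptake.f_sto_max: 0.45
uptake.hill_Fe: 2.0
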