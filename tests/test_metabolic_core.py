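"""Flux laws and the ATP/NADPH budget closure.

The budget closure is checked against an independent brute-force oracle: a
dense scan over the LPET electron fraction x that maximizes the co-limited
(min of ATP-limited and NADPH-limited) flux.  At the crossing point of the
two limitation curves both currencies are exactly exhausted, which is the
defining property of the closure.
"""

import numpy as np
import pytest

from trichofe import ParameterSet
from trichofe.metabolic_core import (
    close_energy_budget,
    cs_production_rate,
    energy_residuals,
    nf_rate,
    nf_requirement,
    pet_rate,
    rp_rate,
)

BIG = 1e9  # drives saturating terms to their asymptote


# --------------------------------------------------------------------------
# independent brute-force oracle for the energy split
# --------------------------------------------------------------------------

def _maximin(x, a, b):
    """max over the grid of min(a, b), refined by intersecting the two lines
    around the grid argmax (both limitation curves are linear in x)."""
    cap = np.minimum(a, b)
    i = int(np.argmax(cap))
    best = float(cap[i])
    lo, hi = max(i - 1, 0), min(i + 1, len(x) - 1)
    da = (a[hi] - a[lo]) / (x[hi] - x[lo])
    db = (b[hi] - b[lo]) / (x[hi] - x[lo])
    if da != db:
        xc = x[lo] + (b[lo] - a[lo]) / (da - db)
        if x[lo] <= xc <= x[hi]:
            best = max(best, float(a[lo] + da * (xc - x[lo])))
    return best


def brute_force_budget(p: ParameterSet, V_PET, FeNF, O2, n_grid=1_000_001):
    """Scan x on a dense grid; maximize min(ATP-limited, NADPH-limited)."""
    x = np.linspace(0.0, 1.0, n_grid)
    atp = V_PET * (x * p.atp_per_e_LPET + (1 - x) * p.atp_per_e_AET)
    nadph = V_PET * x * p.nadph_per_e_LPET
    m = p.atp_maintenance

    if np.max(atp) <= m:  # maintenance deficit: no photic metabolism
        return 0.0, 0.0, 0.0

    V_NFmax = max(_maximin(x, (atp - m) / p.atp_per_N_NF,
                           nadph / p.nadph_per_N_NF), 0.0)

    fFe = FeNF / (FeNF + p.kFeNF) if FeNF > 0 else 0.0
    fO2 = 1.0 - O2 / (O2 + p.kO2NF) if O2 > 0 else 1.0
    V_NF = V_NFmax * fFe * fO2

    V_CF = max(_maximin(x, (atp - m - V_NF * p.atp_per_N_NF) / p.atp_per_C_CF,
                        (nadph - V_NF * p.nadph_per_N_NF) / p.nadph_per_C_CF), 0.0)
    return V_NFmax, V_NF, V_CF


# --------------------------------------------------------------------------
# pointwise flux laws: half-saturation and limiting-case identities
# --------------------------------------------------------------------------

class TestPetRate:
    def test_dark_gives_zero(self, params):
        assert pet_rate(params, FePS=10.0, I=0.0, V_RP=0.0) == 0.0

    def test_half_saturation_in_photosystem_fe(self, params):
        v = pet_rate(params, FePS=params.kFePS, I=BIG, V_RP=0.0)
        assert v == pytest.approx(params.vPETmax / 2, rel=1e-9)

    def test_rp_inhibition_halves_at_ln2(self, params):
        vrp = np.log(2.0) / params.beta
        v = pet_rate(params, FePS=BIG, I=BIG, V_RP=vrp)
        assert v == pytest.approx(params.vPETmax / 2, rel=1e-6)

    def test_monotone_in_light_fe_and_rp(self, params, rng):
        for _ in range(50):
            fe, I, vrp = rng.uniform(0, 20), rng.uniform(0, 500), rng.uniform(0, 1e-3)
            base = pet_rate(params, fe, I, vrp)
            assert pet_rate(params, fe + 1, I, vrp) >= base
            assert pet_rate(params, fe, I + 10, vrp) >= base
            assert pet_rate(params, fe, I, vrp + 1e-4) <= base

    def test_negative_input_rejected(self, params):
        with pytest.raises(ValueError):
            pet_rate(params, FePS=-1.0, I=10.0, V_RP=0.0)


class TestNfRequirement:
    def test_full_n_store_gives_zero(self, params):
        assert nf_requirement(params, I=BIG, CS=BIG, N=params.N_max) == pytest.approx(0.0)

    def test_dark_gives_zero(self, params):
        assert nf_requirement(params, I=0.0, CS=1.0, N=0.0) == 0.0

    def test_half_saturation_in_cs(self, params):
        phi = nf_requirement(params, I=BIG, CS=params.kCS, N=0.0)
        assert phi == pytest.approx(0.5, rel=1e-9)

    def test_overfull_store_rejected(self, params):
        with pytest.raises(ValueError):
            nf_requirement(params, I=1.0, CS=1.0, N=params.N_max * 1.01)


class TestRpRate:
    def test_no_requirement_gives_zero(self, params):
        assert rp_rate(params, Phi=0.0, O2=0.1) == 0.0

    def test_high_o2_shuts_off(self, params):
        assert rp_rate(params, Phi=1.0, O2=BIG) == pytest.approx(0.0, abs=1e-12)

    def test_half_saturation_in_o2_control(self, params):
        v = rp_rate(params, Phi=1.0, O2=params.kO2RP)
        assert v == pytest.approx(params.vRPmax / 2, rel=1e-9)


class TestNfRate:
    def test_asymptote_no_o2(self, params):
        v = nf_rate(params, V_NFmax=1e-5, FeNF=BIG, O2=0.0)
        assert v == pytest.approx(1e-5, rel=1e-6)

    def test_double_half_saturation_quarters(self, params):
        v = nf_rate(params, V_NFmax=1e-5, FeNF=params.kFeNF, O2=params.kO2NF)
        assert v == pytest.approx(1e-5 / 4, rel=1e-9)

    def test_zero_ceiling_gives_zero(self, params):
        assert nf_rate(params, V_NFmax=0.0, FeNF=5.0, O2=0.01) == 0.0

    def test_monotone_in_fe_and_o2(self, params, rng):
        for _ in range(50):
            fe, o2 = rng.uniform(0, 30), rng.uniform(0, 1.0)
            base = nf_rate(params, 1e-5, fe, o2)
            assert nf_rate(params, 1e-5, fe + 0.5, o2) >= base
            assert nf_rate(params, 1e-5, fe, o2 + 0.05) <= base


class TestCsProduction:
    def test_no_carbohydrate_gives_zero(self, params):
        assert cs_production_rate(params, CH2O=0.0, CS=0.1) == 0.0

    def test_asymptote(self, params):
        v = cs_production_rate(params, CH2O=BIG, CS=0.0)
        assert v == pytest.approx(params.vCSmax, rel=1e-6)

    def test_double_half_saturation_quarters(self, params):
        v = cs_production_rate(params, CH2O=params.kCH2O, CS=params.kCSi)
        assert v == pytest.approx(params.vCSmax / 4, rel=1e-9)


# --------------------------------------------------------------------------
# budget closure
# --------------------------------------------------------------------------

class TestEnergyBudget:
    def test_dark_maintenance_met_by_respiration(self, params):
        x, nfmax, nf, cf, resp = close_energy_budget(params, V_PET=0.0)
        assert nf == 0.0 and cf == 0.0
        assert resp == pytest.approx(params.atp_maintenance / params.atp_per_C_RESP,
                                     rel=1e-12)

    def test_no_n_demand_sends_all_to_carbon_fixation(self, params):
        """With nitrogenase Fe = 0 the realized NF is 0 and carbon fixation
        exhausts both currencies exactly."""
        x, nfmax, nf, cf, resp = close_energy_budget(params, V_PET=1e-3, FeNF=0.0,
                                                     O2=0.0)
        assert nf == 0.0
        _, _, cf_oracle = brute_force_budget(params, 1e-3, 0.0, 0.0)
        assert cf == pytest.approx(cf_oracle, rel=1e-6)
        atp, nadph = energy_residuals(params, 1e-3, x, nf, cf, resp)
        assert abs(atp) < 1e-10 * 1e-3
        assert abs(nadph) < 1e-10 * 1e-3

    def test_generic_case_closes_both_currencies(self, params):
        x, nfmax, nf, cf, resp = close_energy_budget(params, V_PET=1e-3, FeNF=3.0,
                                                     O2=0.05)
        atp, nadph = energy_residuals(params, 1e-3, x, nf, cf, resp)
        scale = 1e-3 * params.atp_per_e_AET
        assert abs(atp) < 1e-10 * scale
        assert abs(nadph) < 1e-10 * scale

    def test_matches_brute_force_on_random_draws(self, params, rng):
        """100 random parameter/state draws agree with the x-grid oracle."""
        for _ in range(100):
            p = params.replace(
                atp_per_e_LPET=rng.uniform(0.6, 1.4),
                atp_per_e_AET=rng.uniform(0.8, 2.0),
                nadph_per_e_LPET=rng.uniform(0.3, 0.7),
                atp_per_C_CF=rng.uniform(3.0, 6.0),
                atp_per_N_NF=rng.uniform(6.0, 12.0),
                atp_maintenance=rng.uniform(0.0, 5e-6),
            )
            V_PET = rng.uniform(1e-5, 2e-3)
            FeNF = rng.uniform(0.0, 20.0)
            O2 = rng.uniform(0.0, 1.0)
            x, nfmax, nf, cf, resp = close_energy_budget(p, V_PET, FeNF, O2)
            nfmax_o, nf_o, cf_o = brute_force_budget(p, V_PET, FeNF, O2,
                                                     n_grid=10_001)
            assert nfmax == pytest.approx(nfmax_o, rel=1e-6, abs=1e-15)
            assert nf == pytest.approx(nf_o, rel=1e-6, abs=1e-15)
            assert cf == pytest.approx(cf_o, rel=1e-6, abs=1e-15)

    def test_realized_nf_never_exceeds_ceiling(self, params, rng):
        for _ in range(50):
            V_PET = rng.uniform(0, 1e-3)
            _, nfmax, nf, _, _ = close_energy_budget(
                params, V_PET, FeNF=rng.uniform(0, 10), O2=rng.uniform(0, 0.5))
            assert nf <= nfmax + 1e-18

    def test_zero_demand_stoichiometry_rejected(self, params):
        bad = params.replace(nadph_per_N_NF=0.0)
        with pytest.raises(ValueError):
            close_energy_budget(bad, V_PET=1e-3)
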