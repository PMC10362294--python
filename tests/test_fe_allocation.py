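"""Fe translocation laws and pool-tendency bookkeeping."""

import numpy as np
import pytest

from trichofe import CaseConfig
from trichofe.fe_allocation import (
    FePools,
    fe_pool_tendencies,
    initial_pools,
    nf_inactivation_rate,
    nf_synthesis_rate,
    ps_decomposition_rate,
    ps_synthesis_rate,
)

BIG = 1e9


class TestTranslocationLaws:
    def test_ps_synthesis_dark_zero(self, params):
        assert ps_synthesis_rate(params, I=0.0, FePS=1.0) == 0.0

    def test_ps_synthesis_empty_pool_asymptote(self, params):
        v = ps_synthesis_rate(params, I=BIG, FePS=0.0)
        assert v == pytest.approx(params.TPSmaxBF, rel=1e-6)

    def test_ps_synthesis_half_saturation(self, params):
        v = ps_synthesis_rate(params, I=BIG, FePS=params.kFePS_syn)
        assert v == pytest.approx(params.TPSmaxBF / 2, rel=1e-6)

    def test_ps_decomposition_empty_pool_zero(self, params):
        assert ps_decomposition_rate(params, FePS=0.0, V_RP=0.0) == 0.0

    def test_ps_decomposition_half_saturation(self, params):
        v = ps_decomposition_rate(params, FePS=params.kFePS_dec, V_RP=0.0)
        assert v == pytest.approx(params.TBFmaxPS / 2, rel=1e-9)

    def test_ps_decomposition_rp_inhibition(self, params):
        vrp = np.log(2.0) / params.beta
        v = ps_decomposition_rate(params, FePS=BIG, V_RP=vrp)
        assert v == pytest.approx(params.TBFmaxPS / 2, rel=1e-6)

    def test_nf_synthesis_zero_cases(self, params):
        assert nf_synthesis_rate(params, Phi=0.0, FeBF=5.0) == 0.0
        assert nf_synthesis_rate(params, Phi=1.0, FeBF=0.0) == 0.0

    def test_nf_synthesis_half_saturation(self, params):
        v = nf_synthesis_rate(params, Phi=1.0, FeBF=params.kFeBF_syn)
        assert v == pytest.approx(params.TNFmaxBF / 2, rel=1e-9)

    def test_inactivation_no_o2_zero(self, params):
        assert nf_inactivation_rate(params, FeNF_act=5.0, O2=0.0) == 0.0

    def test_inactivation_double_half_saturation(self, params):
        v = nf_inactivation_rate(params, FeNF_act=params.kFeNF, O2=params.kO2NF)
        assert v == pytest.approx(params.TNFmaxNA / 4, rel=1e-9)

    def test_inactivation_asymptote(self, params):
        v = nf_inactivation_rate(params, FeNF_act=BIG, O2=BIG)
        assert v == pytest.approx(params.TNFmaxNA, rel=1e-6)


class TestPoolTendencies:
    def _pools(self):
        return FePools(FePS=4.0, FeNF_act=2.0, FeNF_inact=0.5, FeBF=1.5)

    @pytest.mark.parametrize("mode", ["dynamic", "fixed"])
    @pytest.mark.parametrize("decomp", [False, True])
    def test_tendencies_conserve_allocatable_fe(self, params, mode, decomp, rng):
        case = CaseConfig(mode=mode, fFe0PS=0.5, fFe0NF=0.2,
                          decompose_inactivated=decomp)
        for _ in range(20):
            pools = FePools(*rng.uniform(0.1, 10.0, size=4))
            d = fe_pool_tendencies(pools, params, case, I=rng.uniform(0, 500),
                                   Phi=rng.uniform(0, 1), O2=rng.uniform(0, 1),
                                   V_RP=rng.uniform(0, 2e-4))
            assert sum(d.values()) == pytest.approx(0.0, abs=1e-18)

    def test_fixed_mode_only_inactivation_moves_iron(self, params):
        case = CaseConfig(mode="fixed", fFe0PS=0.5, fFe0NF=0.2)
        d = fe_pool_tendencies(self._pools(), params, case, I=200.0, Phi=0.8,
                               O2=0.3, V_RP=0.0)
        assert d["FePS"] == 0.0
        assert d["FeBF"] == 0.0
        assert d["FeNF_inact"] > 0.0
        assert d["FeNF_act"] == pytest.approx(-d["FeNF_inact"], rel=1e-12)

    def test_instant_decomposition_routes_to_buffer(self, params):
        case = CaseConfig(mode="dynamic", fFe0PS=0.5, fFe0NF=0.2,
                          decompose_inactivated=True)
        d = fe_pool_tendencies(self._pools(), params, case, I=200.0, Phi=0.8,
                               O2=0.3, V_RP=0.0)
        inact = nf_inactivation_rate(params, 2.0, 0.3)
        assert d["FeNF_inact"] == 0.0
        base = fe_pool_tendencies(self._pools(), params,
                                  CaseConfig(mode="dynamic", fFe0PS=0.5, fFe0NF=0.2),
                                  I=200.0, Phi=0.8, O2=0.3, V_RP=0.0)
        assert d["FeBF"] == pytest.approx(base["FeBF"] + inact, rel=1e-12)


class TestInitialPools:
    def test_buffer_takes_remainder_and_inactive_starts_empty(self):
        case = CaseConfig(mode="dynamic", fFe0PS=0.6, fFe0NF=0.2)
        pools = initial_pools(9.0, case, f_maint=0.10)
        metabolic = 9.0 / 0.9
        assert pools.FePS == pytest.approx(0.6 * metabolic)
        assert pools.FeNF_act == pytest.approx(0.2 * metabolic)
        assert pools.FeNF_inact == 0.0
        assert pools.total == pytest.approx(9.0, rel=1e-12)

    def test_overcommitted_fractions_rejected(self):
        case = CaseConfig(mode="dynamic", fFe0PS=0.8, fFe0NF=0.2)
        with pytest.raises(ValueError):
            initial_pools(9.0, case, f_maint=0.10)
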