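"""Day integration: conservation, budget closure, convergence, growth law."""

import numpy as np
import pytest

from trichofe import (
    CaseConfig,
    CellState,
    Forcing,
    ParameterSet,
    end_of_day_growth,
    integrate_day,
    run_case,
)
from trichofe.fe_allocation import FePools
from trichofe.simulator import biomass_increment


def _fe_total(ts):
    return ts["FePS"] + ts["FeNF_act"] + ts["FeNF_inact"] + ts["FeBF"]


class TestIntegration:
    def test_dark_day_fixes_nothing(self, params, case_dynamic):
        f = Forcing(mode="constant", I_const=0.0)
        s = run_case(params, f, case_dynamic, 40.0, dt=60.0)
        assert s.grossCF == 0.0
        assert s.NF_daily == 0.0

    @pytest.mark.parametrize("mode,Fe", [("dynamic", 40.0), ("fixed", 40.0),
                                         ("dynamic", 1250.0), ("fixed", 1250.0)])
    def test_allocatable_fe_conserved(self, params, forcing_sin, mode, Fe):
        case = CaseConfig(mode=mode, fFe0PS=0.55, fFe0NF=0.2)
        s = run_case(params, forcing_sin, case, Fe)
        tot = _fe_total(s.time_series)
        assert np.max(np.abs(tot - tot.iloc[0])) / tot.iloc[0] < 1e-9

    def test_inactivated_nitrogenase_monotone(self, params, forcing_sin):
        case = CaseConfig(mode="dynamic", fFe0PS=0.55, fFe0NF=0.2)
        s = run_case(params, forcing_sin, case, 1250.0)
        inact = s.time_series["FeNF_inact"].to_numpy()
        assert np.all(np.diff(inact) >= -1e-15)

    def test_oxygen_never_negative(self, params, forcing_sin, case_dynamic):
        s = run_case(params, forcing_sin, case_dynamic, 40.0)
        assert s.time_series["O2"].min() >= 0.0

    def test_o2_relaxes_exponentially_without_biology(self, forcing_const):
        """With all biological fluxes disabled, O2(t) follows the first-order
        closed form toward the ambient concentration."""
        p = ParameterSet(vPETmax=0.0, vRPmax=0.0, vCSmax=0.0,
                         atp_maintenance=0.0, TPSmaxBF=0.0, TBFmaxPS=0.0,
                         TNFmaxBF=0.0, TNFmaxNA=0.0)
        case = CaseConfig(mode="dynamic", fFe0PS=0.5, fFe0NF=0.2)
        O2_0 = 0.03
        state0 = CellState(CH2O=0.01, CS=0.01, N=0.0, O2=O2_0,
                           pools=FePools(4.0, 1.0, 0.0, 1.0))
        s = integrate_day(state0, p, forcing_const, case, dt=10.0)
        ts = s.time_series
        expected = forcing_const.O2_ambient + (O2_0 - forcing_const.O2_ambient) \
            * np.exp(-p.kappa_O2 * ts["t"])
        assert np.max(np.abs(ts["O2"] - expected) / forcing_const.O2_ambient) < 1e-3

    @pytest.mark.parametrize("mode", ["dynamic", "fixed"])
    def test_daily_o2_budget_closes(self, params, forcing_sin, mode):
        """Integrated net biological term plus integrated exchange equals the
        net change of intracellular O2."""
        case = CaseConfig(mode=mode, fFe0PS=0.55, fFe0NF=0.2)
        s = run_case(params, forcing_sin, case, 40.0)
        ts = s.time_series
        lhs = s.O2_bio_daily + s.O2_exch_daily
        rhs = ts["O2"].iloc[-1] - ts["O2"].iloc[0]
        assert lhs == pytest.approx(rhs, rel=1e-6, abs=1e-12)

    def test_step_halving_growth_converges(self, params, forcing_sin, case_dynamic):
        G10 = run_case(params, forcing_sin, case_dynamic, 40.0, dt=10.0).G
        G1 = run_case(params, forcing_sin, case_dynamic, 40.0, dt=1.0).G
        assert abs(G10 - G1) < 1e-3

    def test_dt_must_divide_day(self, params, forcing_sin, case_dynamic):
        with pytest.raises(ValueError):
            run_case(params, forcing_sin, case_dynamic, 40.0, dt=7.0)

    def test_mode_equivalence_without_o2_and_translocation(self, forcing_const):
        """With O2 absent (no ambient O2, no LPET O2 via zero electron flow to
        inactivation) and zero translocation constants, the dynamic and fixed
        trajectories coincide."""
        p = ParameterSet(TPSmaxBF=0.0, TBFmaxPS=0.0, TNFmaxBF=0.0)
        f = Forcing(mode="constant", I_const=90.0, O2_ambient=0.0)
        # disable O2 production so intracellular O2 stays identically zero
        p = p.replace(nadph_per_e_LPET=0.5, vRPmax=0.0)
        p2 = p.replace(e_per_O2=1e30)
        out = {}
        for mode in ("dynamic", "fixed"):
            case = CaseConfig(mode=mode, fFe0PS=0.55, fFe0NF=0.2)
            out[mode] = run_case(p2, f, case, 40.0, dt=60.0).time_series
        for col in ("CH2O", "CS", "N", "FePS", "FeNF_act", "FeNF_inact", "FeBF"):
            np.testing.assert_allclose(out["dynamic"][col], out["fixed"][col],
                                       rtol=1e-12, atol=1e-15)


class TestGrowthLaw:
    def _state(self, CH2O, CS, N):
        return CellState(CH2O=CH2O, CS=CS, N=N, O2=0.2,
                         pools=FePools(1.0, 1.0, 0.0, 1.0))

    def test_no_nitrogen_no_growth(self, params):
        assert end_of_day_growth(self._state(1.0, 1.0, 0.0), params) == 0.0

    def test_nitrogen_limited_increment(self, params):
        st = self._state(10.0, 10.0, 0.05)
        assert biomass_increment(st, params) == pytest.approx(0.05 / params.q_N)

    def test_carbohydrate_cap_includes_biosynthesis_cost(self, params):
        st = self._state(0.07, 10.0, 10.0 * params.q_N)
        assert biomass_increment(st, params) == pytest.approx(0.07 / (1 + params.c_bio))

    def test_small_increment_scales_linearly(self, params):
        """For small pools, doubling the terminal pools doubles G to first
        order (G = ln(1+dB))."""
        st1 = self._state(0.01, 0.01, 0.01 * params.q_N)
        st2 = self._state(0.02, 0.02, 0.02 * params.q_N)
        G1 = end_of_day_growth(st1, params)
        G2 = end_of_day_growth(st2, params)
        assert G2 == pytest.approx(2 * G1, rel=5e-3)
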