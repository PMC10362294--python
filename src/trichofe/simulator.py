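"""Integrate the coupled trichome state over the 12-h light period.

The state couples carbon pools (carbohydrate CH2O and carbon skeleton CS),
the fixed-nitrogen store, intracellular O2 and the four allocatable Fe pools.
A fixed-step classical RK4 scheme (default dt = 10 s) advances the state;
consuming fluxes are limited inside each step so no pool is driven negative.
Biosynthesis is not resolved in time: the pools accumulated by dusk are
converted into one night's biomass increment and hence a daily growth rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernel as K
from .environment import partition_iron
from .fe_allocation import FePools, initial_pools
from .params import CaseConfig, Forcing, ParameterSet

__all__ = ["CellState", "DailySummary", "integrate_day", "end_of_day_growth",
           "biomass_increment", "run_case", "initial_state"]

STATE_COLUMNS = ("CH2O", "CS", "N", "O2", "FePS", "FeNF_act", "FeNF_inact", "FeBF")


@dataclass
class CellState:
    """Instantaneous pools: carbon in mol C (mol C)^-1, N in mol N (mol C)^-1,
    O2 in mol m^-3, Fe in umol Fe (mol C)^-1."""

    CH2O: float
    CS: float
    N: float
    O2: float
    pools: FePools

    def to_array(self) -> np.ndarray:
        return np.array([
            self.CH2O, self.CS, self.N, self.O2,
            self.pools.FePS, self.pools.FeNF_act,
            self.pools.FeNF_inact, self.pools.FeBF,
        ])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CellState":
        return cls(
            CH2O=float(y[0]), CS=float(y[1]), N=float(y[2]), O2=float(y[3]),
            pools=FePools(FePS=float(y[4]), FeNF_act=float(y[5]),
                          FeNF_inact=float(y[6]), FeBF=float(y[7])),
        )


@dataclass
class DailySummary:
    """End-of-day integrated rates and derived metrics for one run."""

    G: float                 # growth rate, d^-1
    grossCF: float           # gross C fixation, mol C (mol C)^-1 d^-1
    NF_daily: float          # N2 fixation, mol N (mol C)^-1 d^-1
    CN_ratio: float          # grossCF / NF_daily (nan if NF_daily == 0)
    RP_fraction: float       # % of gross fixed C consumed by RP
    CUE: float               # % of gross fixed C assimilated to biomass
    RP_daily: float          # mol C (mol C)^-1 d^-1
    RESP_daily: float
    O2_prod_daily: float     # daily LPET O2 production, mol O2 m^-3
    O2_bio_daily: float      # daily net biological O2 term, mol O2 m^-3
    O2_exch_daily: float     # daily physical exchange, mol O2 m^-3
    delta_B: float           # biomass increment, mol C (mol C)^-1
    state_end: CellState = field(repr=False)
    time_series: pd.DataFrame = field(repr=False)


def initial_state(
    params: ParameterSet,
    forcing: Forcing,
    case: CaseConfig,
    Fe_prime: float,
    CH2O0: float = 0.01,
    CS0: float = 0.01,
) -> CellState:
    """Dawn state: small carbon reserves after nighttime drawdown, no fixed
    N, O2 equilibrated with the medium, Fe pools from the ambient partition
    and the case's initial fractions."""
    part = partition_iron(Fe_prime, params)
    pools = initial_pools(part.Fe_metabolic_allocatable, case, params.f_maint)
    return CellState(CH2O=CH2O0, CS=CS0, N=0.0, O2=forcing.O2_ambient, pools=pools)


def biomass_increment(state: CellState, params: ParameterSet) -> float:
    """Biomass C assembled overnight from the dusk pools.

    The increment is capped by fixed N (at the biomass quota q_N), by carbon
    skeletons, and by carbohydrate net of the biosynthesis energy cost
    (c_bio carbohydrate C respired per biomass C assembled).
    """
    if params.q_N <= 0:
        raise ValueError("q_N must be positive")
    caps = (
        max(state.N, 0.0) / params.q_N,
        max(state.CS, 0.0),
        max(state.CH2O, 0.0) / (1.0 + params.c_bio),
    )
    return float(min(caps))


def end_of_day_growth(state: CellState, params: ParameterSet) -> float:
    """Daily growth rate G = ln(1 + dB) per day, the culture-dilution
    definition for one division cycle."""
    return float(np.log1p(biomass_increment(state, params)))


def integrate_day(
    state0: CellState,
    params: ParameterSet,
    forcing: Forcing,
    case: CaseConfig,
    dt: float = 10.0,
) -> DailySummary:
    """Run the light period and summarize.

    ``dt`` must divide the day length.  Raises if the integration produces a
    non-finite state, naming the step and variable.
    """
    n = round(forcing.day_length / dt)
    if abs(n * dt - forcing.day_length) > 1e-9 * forcing.day_length:
        raise ValueError(f"dt={dt} does not divide day_length={forcing.day_length}")

    params.validate()
    P = params.to_array()
    light_mode = K.LIGHT_CONSTANT if forcing.mode == "constant" else K.LIGHT_SINUSOIDAL
    I_param = forcing.I_const if forcing.mode == "constant" else forcing.I_max

    Y, F, Ints = K.run_day_kernel(
        P, light_mode, I_param, forcing.day_length, forcing.O2_ambient,
        case.mode == "fixed", case.decompose_inactivated,
        state0.to_array(), dt,
    )

    if not np.all(np.isfinite(Y)):
        i, j = np.argwhere(~np.isfinite(Y))[0]
        raise ArithmeticError(
            f"non-finite state at step {i} (t={i * dt:.0f} s), "
            f"variable {STATE_COLUMNS[j]}"
        )

    t = np.arange(n + 1) * dt
    I_vals = np.array([K.light_kernel(light_mode, I_param, forcing.day_length, ti)
                       for ti in t])
    ts = pd.DataFrame({"t": t, "I": I_vals})
    for j, name in enumerate(STATE_COLUMNS):
        ts[name] = Y[:, j]
    for j, name in enumerate(K.FLUX_NAMES):
        ts[name] = F[:, j]
    for j, name in enumerate(K.INTEGRAL_NAMES):
        ts["cum_" + name] = Ints[:, j]

    ints = Ints[-1]
    grossCF = float(ints[0])
    NF_daily = float(ints[1])
    RP_daily = float(ints[2])
    RESP_daily = float(ints[3])

    state_end = CellState.from_array(Y[-1])
    dB = biomass_increment(state_end, params)
    G = float(np.log1p(dB))

    return DailySummary(
        G=G,
        grossCF=grossCF,
        NF_daily=NF_daily,
        CN_ratio=grossCF / NF_daily if NF_daily > 0 else float("nan"),
        RP_fraction=100.0 * RP_daily / grossCF if grossCF > 0 else 0.0,
        CUE=100.0 * dB / grossCF if grossCF > 0 else 0.0,
        RP_daily=RP_daily,
        RESP_daily=RESP_daily,
        O2_prod_daily=float(ints[5]),
        O2_bio_daily=float(ints[6]),
        O2_exch_daily=float(ints[7]),
        delta_B=dB,
        state_end=state_end,
        time_series=ts,
    )


def run_case(
    params: ParameterSet,
    forcing: Forcing,
    case: CaseConfig,
    Fe_prime: float,
    dt: float = 10.0,
) -> DailySummary:
    """Convenience wrapper: build the dawn state for ``Fe_prime`` and run."""
    return integrate_day(initial_state(params, forcing, case, Fe_prime),
                         params, forcing, case, dt=dt)
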