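"""Instantaneous metabolic fluxes of the trichome.

Photosynthetic electron transport (PET) feeds two pathways: linear transport
(LPET) yields ATP, NADPH and O2, while the alternative pathway (AET) yields
ATP only.  At every instant the LPET fraction ``x_LPET`` is chosen so the
two energy currencies are exactly co-exhausted — first to find the
N2-fixation ceiling ``V_NFmax`` (all post-maintenance supply to nitrogen),
then, with the realized Fe- and O2-limited ``V_NF``, to let carbon fixation
absorb the remainder.  Respiratory protection (RP) burns carbohydrate purely
to draw down intracellular O2; its ATP is wasted as heat.  Ordinary
respiration runs only to close a maintenance ATP deficit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .params import ParameterSet

__all__ = [
    "FluxVector",
    "pet_rate",
    "nf_requirement",
    "rp_rate",
    "close_energy_budget",
    "nf_rate",
    "cs_production_rate",
    "o2_tendency",
    "energy_residuals",
]

# large dt disables the in-step non-negativity limiter for the pointwise API
_NO_LIMIT_DT = 1e30


@dataclass(frozen=True)
class FluxVector:
    """One instant's fluxes (per mol cellular C; O2_exchange per m^3)."""

    V_PET: float
    x_LPET: float
    V_CF: float
    V_NF: float
    V_NFmax: float
    V_RP: float
    V_RESP: float
    V_CS: float
    O2_net_bio: float
    O2_exchange: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.x_LPET <= 1.0:
            raise ValueError("x_LPET must lie in [0, 1]")


def _check_nonneg(**vals: float) -> None:
    for name, v in vals.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")


def pet_rate(params: ParameterSet, FePS: float, I: float, V_RP: float) -> float:
    """Total PET rate [mol e- (mol C)^-1 s^-1].

    Michaelis-Menten in photosystem Fe, saturating in light, exponentially
    inhibited by respiratory protection.
    """
    _check_nonneg(FePS=FePS, I=I, V_RP=V_RP)
    return float(K.pet_rate_kernel(params.to_array(), FePS, I, V_RP))


def nf_requirement(params: ParameterSet, I: float, CS: float, N: float) -> float:
    """N2-fixation requirement Phi in [0, 1].

    Rises with light and carbon-skeleton availability, vanishes as the fixed-N
    store fills.
    """
    _check_nonneg(I=I, CS=CS, N=N)
    if N > params.N_max:
        raise ValueError(f"N={N} exceeds N_max={params.N_max}")
    return float(K.nf_requirement_kernel(params.to_array(), I, CS, N))


def rp_rate(params: ParameterSet, Phi: float, O2: float) -> float:
    """Respiratory-protection rate [mol C (mol C)^-1 s^-1].

    Proportional to the N2-fixation requirement and shut off as intracellular
    O2 rises.  (Within the integrator the rate is additionally flux-limited
    by the available carbohydrate and O2.)
    """
    _check_nonneg(O2=O2)
    if not 0.0 <= Phi <= 1.0:
        raise ValueError("Phi must lie in [0, 1]")
    return float(K.rp_rate_kernel(params.to_array(), Phi, O2))


def nf_rate(params: ParameterSet, V_NFmax: float, FeNF: float, O2: float) -> float:
    """Realized N2 fixation: the energetic ceiling, Michaelis-limited by
    nitrogenase Fe and inhibited by intracellular O2."""
    _check_nonneg(V_NFmax=V_NFmax, FeNF=FeNF, O2=O2)
    return float(K.nf_rate_kernel(params.to_array(), V_NFmax, FeNF, O2))


def cs_production_rate(params: ParameterSet, CH2O: float, CS: float) -> float:
    """Carbon-skeleton production from carbohydrate, down-regulated by its
    own accumulation; consumes CH2O one-to-one in carbon."""
    _check_nonneg(CH2O=CH2O, CS=CS)
    return float(K.cs_production_kernel(params.to_array(), CH2O, CS))


def close_energy_budget(
    params: ParameterSet,
    V_PET: float,
    FeNF: float = 0.0,
    O2: float = 0.0,
    N_headroom_rate: float = np.inf,
) -> tuple[float, float, float, float, float]:
    """Solve the instantaneous ATP/NADPH budget.

    Returns ``(x_LPET, V_NFmax, V_NF, V_CF, V_RESP)``.  In the interior
    regime (x not pinned at 0 or 1) both currencies balance exactly;
    :func:`energy_residuals` verifies this.
    """
    _check_nonneg(V_PET=V_PET, FeNF=FeNF, O2=O2)
    if params.atp_per_N_NF <= 0 or params.nadph_per_N_NF <= 0 \
            or params.atp_per_C_CF <= 0 or params.nadph_per_C_CF <= 0:
        raise ValueError("ATP/NADPH demand stoichiometries must be positive")
    out = K.close_budget_kernel(params.to_array(), V_PET, FeNF, O2, N_headroom_rate)
    return tuple(float(v) for v in out)


def energy_residuals(
    params: ParameterSet,
    V_PET: float,
    x_LPET: float,
    V_NF: float,
    V_CF: float,
    V_RESP: float,
) -> tuple[float, float]:
    """(ATP, NADPH) production minus consumption for a given flux set.

    RP ATP is wasted as heat and excluded by construction; ordinary
    respiration contributes usable ATP.
    """
    p = params
    atp = (
        V_PET * (x_LPET * p.atp_per_e_LPET + (1 - x_LPET) * p.atp_per_e_AET)
        + V_RESP * p.atp_per_C_RESP
        - p.atp_maintenance
        - V_NF * p.atp_per_N_NF
        - V_CF * p.atp_per_C_CF
    )
    nadph = (
        V_PET * x_LPET * p.nadph_per_e_LPET
        - V_NF * p.nadph_per_N_NF
        - V_CF * p.nadph_per_C_CF
    )
    return float(atp), float(nadph)


def o2_tendency(
    fluxes: FluxVector,
    O2: float,
    params: ParameterSet,
    O2_ambient: float,
) -> float:
    """Net intracellular O2 tendency [mol O2 m^-3 s^-1].

    Sum of the biological term (LPET production minus RP and ordinary
    respiration, converted by the carbon density) and first-order physical
    exchange with the ambient medium; positive exchange is O2 flux into the
    cell.  The individual terms are retrievable from the flux vector
    (``O2_net_bio``, ``O2_exchange``).
    """
    _check_nonneg(O2=O2, O2_ambient=O2_ambient)
    bio = fluxes.x_LPET * fluxes.V_PET / params.e_per_O2 - fluxes.V_RP - fluxes.V_RESP
    return float(params.rho_C * bio + params.kappa_O2 * (O2_ambient - O2))
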