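"""Diurnal translocation of allocatable metabolic Fe.

Four pools exchange iron during the light period: photosystems are
synthesized from the buffer under light and decomposed back into it (the
decomposition suppressed while respiratory protection runs); active
nitrogenase is synthesized from the buffer in proportion to the N2-fixation
requirement and is irreversibly inactivated by intracellular O2.  Inactivated
nitrogenase holds its Fe for the rest of the day (no daytime decomposition)
unless the instant-decomposition experiment flag routes that flux straight
back to the buffer.  In the fixed-Fe variant all translocation is frozen and
only the inactivation flux moves Fe.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _kernel as K
from .params import CaseConfig, ParameterSet

__all__ = [
    "FePools",
    "ps_synthesis_rate",
    "ps_decomposition_rate",
    "nf_synthesis_rate",
    "nf_inactivation_rate",
    "fe_pool_tendencies",
    "initial_pools",
]


@dataclass
class FePools:
    """Allocatable metabolic Fe [umol Fe (mol C)^-1] by compartment."""

    FePS: float
    FeNF_act: float
    FeNF_inact: float
    FeBF: float

    @property
    def total(self) -> float:
        return self.FePS + self.FeNF_act + self.FeNF_inact + self.FeBF


def _check_nonneg(**vals: float) -> None:
    for name, v in vals.items():
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")


def ps_synthesis_rate(params: ParameterSet, I: float, FePS: float) -> float:
    """Photosystem synthesis from the buffer, stimulated by light and
    saturating as FePS accumulates.  (The integrator additionally scales
    this flux to zero as the buffer empties.)"""
    _check_nonneg(I=I, FePS=FePS)
    return float(K.ps_synthesis_kernel(params.to_array(), I, FePS))


def ps_decomposition_rate(params: ParameterSet, FePS: float, V_RP: float) -> float:
    """Photosystem decomposition into the buffer, Michaelis in FePS and
    exponentially inhibited by respiratory protection."""
    _check_nonneg(FePS=FePS, V_RP=V_RP)
    return float(K.ps_decomposition_kernel(params.to_array(), FePS, V_RP))


def nf_synthesis_rate(params: ParameterSet, Phi: float, FeBF: float) -> float:
    """Nitrogenase synthesis from the buffer, proportional to the
    N2-fixation requirement Phi."""
    _check_nonneg(FeBF=FeBF)
    if not 0.0 <= Phi <= 1.0:
        raise ValueError("Phi must lie in [0, 1]")
    return float(K.nf_synthesis_kernel(params.to_array(), Phi, FeBF))


def nf_inactivation_rate(params: ParameterSet, FeNF_act: float, O2: float) -> float:
    """Irreversible O2 inactivation of active nitrogenase.  Runs in both the
    dynamic-Fe and fixed-Fe variants."""
    _check_nonneg(FeNF_act=FeNF_act, O2=O2)
    return float(K.nf_inactivation_kernel(params.to_array(), FeNF_act, O2))


def fe_pool_tendencies(
    pools: FePools,
    params: ParameterSet,
    case: CaseConfig,
    I: float,
    Phi: float,
    O2: float,
    V_RP: float = 0.0,
) -> dict[str, float]:
    """d/dt of the four Fe pools [umol Fe (mol C)^-1 s^-1].

    The tendencies are built from pairwise transfers, so they sum to zero
    exactly (allocatable Fe is conserved over the day).
    """
    _check_nonneg(FePS=pools.FePS, FeNF_act=pools.FeNF_act,
                  FeNF_inact=pools.FeNF_inact, FeBF=pools.FeBF)
    if case.mode == "fixed":
        syn_ps = dec_ps = syn_nf = 0.0
    else:
        syn_ps = ps_synthesis_rate(params, I, pools.FePS)
        syn_nf = nf_synthesis_rate(params, Phi, pools.FeBF)
        dec_ps = ps_decomposition_rate(params, pools.FePS, V_RP)
    inact = nf_inactivation_rate(params, pools.FeNF_act, O2)

    d = {
        "FePS": syn_ps - dec_ps,
        "FeNF_act": syn_nf - inact,
        "FeNF_inact": 0.0 if case.decompose_inactivated else inact,
        "FeBF": dec_ps - syn_ps - syn_nf
        + (inact if case.decompose_inactivated else 0.0),
    }
    return d


def initial_pools(
    allocatable: float, case: CaseConfig, f_maint: float = 0.10
) -> FePools:
    """Dawn Fe pools from the allocatable quota and the case's initial
    fractions (fractions are of *metabolic* Fe, of which ``1 - f_maint``
    is allocatable).  The buffer takes the remainder; inactivated
    nitrogenase starts empty after nighttime resynthesis.
    """
    if allocatable < 0:
        raise ValueError("allocatable Fe must be >= 0")
    frac_alloc = 1.0 - f_maint
    if case.fFe0PS + case.fFe0NF > frac_alloc + 1e-9:
        raise ValueError(
            f"initial PS+NF fractions ({case.fFe0PS + case.fFe0NF:.3f}) exceed "
            f"the allocatable share of metabolic Fe ({frac_alloc:.2f})"
        )
    metabolic = allocatable / frac_alloc if frac_alloc > 0 else 0.0
    FePS = case.fFe0PS * metabolic
    FeNF = case.fFe0NF * metabolic
    FeBF = allocatable - FePS - FeNF
    if FeBF < 0:
        FeBF = 0.0
    return FePools(FePS=FePS, FeNF_act=FeNF, FeNF_inact=0.0, FeBF=FeBF)
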