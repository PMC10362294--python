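"""Light forcing and partition of ambient inorganic Fe into cellular pools.

The total cellular Fe quota saturates with ambient dissolved inorganic iron
(Fe', pM).  A growing share of that quota is diverted to storage as Fe'
rises (luxury uptake); of the remaining *metabolic* Fe, a fixed 10% runs
maintenance and the other 90% is allocatable among photosystems,
nitrogenase and the buffer pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernel as K
from .params import Forcing, ParameterSet

__all__ = ["FePartition", "light_at", "partition_iron"]


@dataclass(frozen=True)
class FePartition:
    """Ambient Fe' (pM) and the resulting cellular Fe quotas (umol Fe / mol C)."""

    Fe_prime: float
    Fe_total: float
    Fe_storage: float
    Fe_maintenance: float
    Fe_metabolic_allocatable: float

    @property
    def Fe_metabolic(self) -> float:
        """Metabolic Fe = maintenance + allocatable."""
        return self.Fe_maintenance + self.Fe_metabolic_allocatable


def light_at(forcing: Forcing, t: float) -> float:
    """Photon flux (umol m^-2 s^-1) at time ``t`` (s) into the light period.

    Constant mode returns ``I_const``; sinusoidal mode returns
    ``I_max * sin(pi * t / day_length)``, zero at dawn and dusk.
    """
    if not 0.0 <= t <= forcing.day_length:
        raise ValueError(f"t={t} outside the light period [0, {forcing.day_length}]")
    mode = K.LIGHT_CONSTANT if forcing.mode == "constant" else K.LIGHT_SINUSOIDAL
    I_param = forcing.I_const if forcing.mode == "constant" else forcing.I_max
    return float(K.light_kernel(mode, I_param, forcing.day_length, t))


def partition_iron(Fe_prime: float, params: ParameterSet) -> FePartition:
    """Partition ambient Fe' (pM) into total, storage, maintenance and
    allocatable metabolic quotas.

    The total quota is the sum of two saturating uptake systems — a
    high-affinity transporter (``Q0_max``, ``K0_Fe``) that is nearly
    saturated at the low end of the gradient, and a cooperative
    low-affinity system (``Q_max``, ``K_Fe``, Hill coefficient ``hill_Fe``)
    carrying the rise toward Fe-replete conditions.  The storage fraction
    itself saturates as ``f_sto_max * Fe'/(Fe' + K_sto)``, so storage is
    disproportionately large under high Fe (luxury uptake).
    """
    if Fe_prime < 0:
        raise ValueError(f"Fe_prime must be >= 0, got {Fe_prime}")
    h = params.hill_Fe
    low_aff = params.Q_max * Fe_prime ** h / (Fe_prime ** h + params.K_Fe ** h) \
        if Fe_prime > 0 else 0.0
    Fe_total = params.Q0_max * K.mm(Fe_prime, params.K0_Fe) + low_aff
    f_sto = params.f_sto_max * K.mm(Fe_prime, params.K_sto)
    Fe_storage = Fe_total * f_sto
    Fe_metabolic = Fe_total - Fe_storage
    Fe_maintenance = params.f_maint * Fe_metabolic
    return FePartition(
        Fe_prime=float(Fe_prime),
        Fe_total=float(Fe_total),
        Fe_storage=float(Fe_storage),
        Fe_maintenance=float(Fe_maintenance),
        Fe_metabolic_allocatable=float(Fe_metabolic - Fe_maintenance),
    )
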