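"""Hypoxia- and adenosine-modulated per-step event probabilities.

Local hypoxia is ``1/(U + c)`` with ``U`` the oxygen concentration at the
site where the event happens.  Hypoxia and adenosine raise the tumor
division and Treg polarization probabilities and depress effector
cytotoxicity; all three results are clamped into [0, 1].

The Treg and cytotoxicity modulations use absolute hypoxia and adenosine
levels.  The tumor-division modulation subtracts the reference levels
``params.hypoxia_ref`` / ``params.adenosine_ref`` first: its base rate is
calibrated at the in-vivo baseline where the standing adenosine steady
state (~188) is already present, so division responds to the *excess*
adenosine (the default ``hypoxia_ref`` is 0).  Setting both references to
0 gives the raw absolute-level form for all three rates.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _kernels as kn
from .core_types import ParameterSet

__all__ = ["ModulatedRates", "treg_rate", "tumor_rate", "cytotoxicity_rate",
           "modulated_rates"]


@dataclass(frozen=True)
class ModulatedRates:
    p_treg_bar: float
    p_tumor_bar: float
    mu_bar: float


def treg_rate(U_local: float, Ad: float, params: ParameterSet) -> float:
    """Treg polarization probability P̄_Treg = P_Treg + r_Hr/(U+c) + r_Ar·Ad."""
    return float(kn.treg_rate_kernel(U_local, Ad, params.kernel_array()))


def tumor_rate(U_local: float, Ad: float, params: ParameterSet) -> float:
    """Tumor division probability
    P̄_tumor = P_tumor + r_Ht·(1/(U+c) − hypoxia_ref) + r_At·(Ad − adenosine_ref)."""
    return float(kn.tumor_rate_kernel(U_local, Ad, params.kernel_array()))


def cytotoxicity_rate(U_local: float, Ad: float, params: ParameterSet) -> float:
    """Effector kill probability µ̄ = µ − r_He/(U+c) − r_Ae·Ad (floored at 0)."""
    return float(kn.cytotoxicity_rate_kernel(U_local, Ad, params.kernel_array()))


def modulated_rates(U_local: float, Ad: float, params: ParameterSet) -> ModulatedRates:
    pk = params.kernel_array()
    return ModulatedRates(
        p_treg_bar=float(kn.treg_rate_kernel(U_local, Ad, pk)),
        p_tumor_bar=float(kn.tumor_rate_kernel(U_local, Ad, pk)),
        mu_bar=float(kn.cytotoxicity_rate_kernel(U_local, Ad, pk)),
    )
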