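"""Thermodynamic linkage between activation and reaction parameters.

For a reversible elementary step, transition-state theory links the reaction
thermodynamics to the activation parameters of the two directions:

    dH = dH_forward - dH_reverse,    dS = dS_forward - dS_reverse,
    dG(T) = dH - T dS / 1000,

and independently dG(T) = -R T ln(K) / 1000 from a measured equilibrium
constant (1 M standard state).  Agreement of the two routes is the
cross-consistency check on the kinetic analysis.

Units follow the reporting convention of the field: dH and dG in kJ/mol,
dS in J/(mol K); the factor of 1000 is applied here, once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .constants import R
from .regressions import EyringFit


@dataclass
class ThermoResult:
    dH: float | None  # kJ/mol (None when only dG is determinable)
    dS: float | None  # J/(mol K)
    dG: float  # kJ/mol at temperature T
    T: float  # K
    dH_se: float = np.nan
    dS_se: float = np.nan
    dG_se: float = np.nan
    source: Literal["linkage", "from_K"] = "linkage"


def linkage(forward: EyringFit, reverse: EyringFit, T: float) -> ThermoResult:
    """Reaction dH, dS, dG from forward and reverse activation parameters."""
    dH = forward.dH - reverse.dH
    dS = forward.dS - reverse.dS
    dG = dH - T * dS / 1000.0
    dH_se = float(np.hypot(forward.dH_se, reverse.dH_se))
    dS_se = float(np.hypot(forward.dS_se, reverse.dS_se))
    dG_se = float(np.hypot(dH_se, T * dS_se / 1000.0))
    return ThermoResult(dH=dH, dS=dS, dG=dG, T=T, dH_se=dH_se, dS_se=dS_se, dG_se=dG_se,
                        source="linkage")


def gibbs_from_K(K: float, T: float, K_se: float = 0.0) -> ThermoResult:
    """dG = -R T ln(K) / 1000 (kJ/mol, 1 M standard state)."""
    if K <= 0:
        raise ValueError("equilibrium constant must be > 0")
    dG = -R * T * np.log(K) / 1000.0
    dG_se = (R * T / 1000.0) * (K_se / K) if K_se else np.nan
    return ThermoResult(dH=None, dS=None, dG=float(dG), T=T, dG_se=float(dG_se), source="from_K")
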