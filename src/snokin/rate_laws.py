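"""Closed-form observed-rate laws for the two reactivity pathways.

Pathway 1 (NO added to the preformed ferric-thiolate complex) is governed by
the dead-end equilibrium: the thiol-bound ferric complex must first release
its thiol, the aqua complex is nitrosylated, and only then does thiolate
attack form the S-nitrosothiol adduct.  Steady-state treatment of the aqua
intermediate gives

    k_obs1 = (k_off_RS k_on_NO [NO] + k_on_RS [RS]_T k_off_NO)
             / (k_on_RS [RS]_T + k_on_NO [NO])

with the limits k_obs1 -> k_off_RS as [NO] -> inf (limiting dissociative
regime) and k_obs1 -> k_off_NO as [RS]_T -> inf (thiol traps the aqua form).
The form is valid as a single-exponential description when the aqua
intermediate is a fast, sparsely populated species, i.e.
k_on_RS[RS]_T << k_on_NO[NO] and k_on_RS k_off_NO [RS]_T << k_off_RS k_on_NO [NO].

Pathway 2 (thiol added to the preformed Fe2+(NO+) complex) is a one-step
reversible association, so the observed rate is affine in total thiol:

    k_obs2 = k_on_app [RS]_T + k_off

where k_on_app is the pH-dependent apparent association constant.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import RateConstants


@dataclass(frozen=True)
class OperatingPoint:
    """Clamped solution conditions for a rate-law evaluation."""

    no: float = 0.0  # [NO], mol/L
    rs_total: float = 0.0  # [RS]_T, mol/L
    ph: float = 7.4
    temperature: float = 278.15  # K

    def __post_init__(self) -> None:
        if self.no < 0 or self.rs_total < 0:
            raise ValueError("concentrations must be >= 0")
        if not 0.0 < self.ph < 14.0:
            raise ValueError("pH must lie in (0, 14)")


def kobs1_closed_form(k: RateConstants, op: OperatingPoint) -> float:
    """Dead-end-equilibrium observed rate for pathway 1 (s^-1)."""
    denom = k.k_on_RS * op.rs_total + k.k_on_NO * op.no
    if denom <= 0.0:
        raise ZeroDivisionError("both [NO] and [RS]_T are zero: observed rate undefined")
    return (k.k_off_RS * k.k_on_NO * op.no + k.k_on_RS * op.rs_total * k.k_off_NO) / denom


def kobs1_validity(k: RateConstants, op: OperatingPoint, margin: float = 10.0) -> bool:
    """True when both steady-state inequalities hold by at least ``margin``-fold."""
    c1 = margin * k.k_on_RS * op.rs_total <= k.k_on_NO * op.no
    c2 = margin * k.k_on_RS * k.k_off_NO * op.rs_total <= k.k_off_RS * k.k_on_NO * op.no
    return bool(c1 and c2)


def attack_relaxation(k: RateConstants, op: OperatingPoint, thiolate_fraction: float) -> float:
    """Relaxation rate of the downstream thiolate-attack step (s^-1).

    The dead-end-equilibrium rate law describes the heme-supply relaxation;
    it is the *observed* (slowest) mode only when the thiolate attack on the
    nitrosyl complex relaxes faster, i.e. when
    ``attack_relaxation / kobs1_closed_form`` is comfortably above 1.  The
    published pathway-1 experiments (3 mM total thiol) sit near 3x.
    """
    return k.k_on_RSminus * op.rs_total * thiolate_fraction + k.k_off_RSminus


def kobs2_closed_form(
    k_on_apparent: float, k_off: float, rs_total: float
) -> float:
    """Affine pathway-2 observed rate k_on_app*[RS]_T + k_off (s^-1)."""
    if k_on_apparent < 0 or k_off < 0:
        raise ValueError("rate constants must be >= 0")
    if rs_total < 0:
        raise ValueError("[RS]_T must be >= 0")
    return k_on_apparent * rs_total + k_off


def kobs2_from_constants(k: RateConstants, op: OperatingPoint, thiolate_fraction: float) -> float:
    """Pathway-2 observed rate from microscopic constants and the RS- fraction."""
    return kobs2_closed_form(k.k_on_RSminus * thiolate_fraction, k.k_off_RSminus, op.rs_total)
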