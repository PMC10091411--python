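"""Equilibrium-constant estimation for the S-nitrosothiol heme adduct.

Two independent routes to the same binding constant K for
Fe2+(NO+) + RS- <=> I1:

* spectral titration: the 413 nm equilibrium absorbance follows the 1:1
  isotherm A([L]) = (A0 + Ainf*K*[L]) / (1 + K*[L]) in free ligand [L];
* kinetics: K = k_on / k_off from the pathway-2 slope and intercept.

Titration ligand axes may be tagged as total thiol (converted to thiolate
through a :class:`~snokin.protonation.ProtonationModel` before fitting,
since only the anion binds) or as thiolate directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from lmfit import Model

from .protonation import ProtonationModel, thiolate_fraction


class UnidentifiableK(RuntimeError):
    """The titration shows no curvature; only a lower bound on K exists."""

    def __init__(self, lower_bound: float):
        super().__init__(
            f"no curvature in titration (K*[L] << 1 throughout); K > {lower_bound:.3g} M^-1 "
            "cannot be resolved into an estimate"
        )
        self.lower_bound = lower_bound


@dataclass
class TitrationSeries:
    """Equilibrium absorbances at 413 nm against ligand concentration."""

    ligand: np.ndarray  # mol/L, includes a zero point
    absorbance: np.ndarray  # AU
    ligand_scale: Literal["total", "thiolate"] = "thiolate"
    ph: float = 7.4
    temperature: float = 278.15
    no: float = 1.8e-4
    heme_total: float = 5e-6
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ligand = np.asarray(self.ligand, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if len(self.ligand) < 5:
            raise ValueError("need at least 5 titration points")
        if self.ligand[0] != 0.0:
            raise ValueError("titration must include a zero-ligand point")
        if np.any(np.diff(self.ligand) <= 0):
            raise ValueError("ligand concentrations must be strictly increasing")


@dataclass
class EquilibriumResult:
    K: float  # M^-1
    K_se: float
    A0: float = np.nan
    Ainf: float = np.nan
    A0_se: float = np.nan
    Ainf_se: float = np.nan
    source: Literal["titration", "kinetic_ratio"] = "titration"


def _free_ligand(total: np.ndarray, K: float, heme: float) -> np.ndarray:
    """Free [L] from total under 1:1 depletion: solves the binding quadratic."""
    b = K * (heme - total) + 1.0
    disc = np.sqrt(b * b + 4.0 * K * total)
    return (disc - b) / (2.0 * K)


def isotherm_fit(
    series: TitrationSeries,
    model: ProtonationModel | None = None,
    depletion_threshold: float = 0.10,
) -> EquilibriumResult:
    """Fit the 1:1 binding isotherm to an equilibrium titration.

    Only the thiolate binds, so for a total-thiol axis the isotherm is fitted
    on the total scale (apparent constant K*alpha) and the result divided by
    the thiolate fraction afterwards.  Mass balance also lives on the total
    scale: binding drains thiolate, but the protonated reservoir rebuffers
    it, so ligand depletion is the loss of *total* thiol to the complex.  The
    depletion correction (free-ligand quadratic inside the fit) engages when
    the heme total exceeds ``depletion_threshold`` of the smallest nonzero
    ligand concentration on the fitted scale.
    """
    lig = series.ligand.copy()
    alpha = 1.0
    if series.ligand_scale == "total":
        if model is None:
            raise ValueError("a ProtonationModel is required to convert a total-thiol axis")
        alpha = thiolate_fraction(model, series.ph, series.temperature)
    a = series.absorbance
    deplete = series.heme_total > depletion_threshold * lig[lig > 0].min()

    a0_guess, ainf_guess = float(a[0]), float(a[-1])
    # half-saturation guess: ligand where the response crosses its midpoint
    mid = 0.5 * (a0_guess + ainf_guess)
    idx = int(np.argmin(np.abs(a - mid)))
    k_guess = 1.0 / max(lig[idx], lig[lig > 0].min())

    def iso(L, K, A0, Ainf):
        Lf = _free_ligand(L, K, series.heme_total) if deplete else L
        return (A0 + Ainf * K * Lf) / (1.0 + K * Lf)

    m = Model(iso)
    params = m.make_params(K=k_guess, A0=a0_guess, Ainf=ainf_guess)
    params["K"].set(min=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = m.fit(a, params, L=lig)
    K = out.params["K"].value
    if K * lig.max() < 0.5:  # essentially linear: K unidentifiable
        span = abs(a[-1] - a[0])
        slope = span / lig.max() if lig.max() > 0 else 0.0
        raise UnidentifiableK(lower_bound=max(K, slope / max(abs(a[-1]), 1e-12)) / alpha)

    def se(name):
        s = out.params[name].stderr
        return s if s is not None else np.nan

    return EquilibriumResult(
        K=float(K / alpha),
        K_se=float(se("K")) / alpha,
        A0=float(out.params["A0"].value),
        Ainf=float(out.params["Ainf"].value),
        A0_se=float(se("A0")),
        Ainf_se=float(se("Ainf")),
        source="titration",
    )


def kinetic_equilibrium(
    k_on: float, k_off: float, k_on_se: float = 0.0, k_off_se: float = 0.0
) -> EquilibriumResult:
    """K = k_on/k_off with relative errors propagated in quadrature."""
    if k_on <= 0 or k_off <= 0:
        raise ValueError("both rate constants must be > 0")
    K = k_on / k_off
    rel = np.sqrt((k_on_se / k_on) ** 2 + (k_off_se / k_off) ** 2)
    return EquilibriumResult(K=float(K), K_se=float(K * rel), source="kinetic_ratio")


def saturation_excess(
    fold_excess_total: float, model: ProtonationModel, ph: float, temperature: float = 278.15
) -> float:
    """Fold excess of *thiolate* implied by a fold excess of total thiol.

    Converts the practitioner-facing total-thiol excess (e.g. the ~400-fold
    GSH excess needed for full conversion at pH 7.4) to the reactive-species
    scale (~5-fold thiolate).
    """
    if fold_excess_total <= 0:
        raise ValueError("fold excess must be > 0")
    return fold_excess_total * thiolate_fraction(model, ph, temperature)
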