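"""Secondary regressions: k_obs datasets -> mechanistic constants.

Three linear analyses turn observed-rate datasets into the constants the
mechanism is built from:

* concentration series (k_obs2 vs [RS]_T): slope = apparent association
  constant, intercept = dissociation constant;
* pH series (apparent k_on vs 1/[H+]): in the acid regime [H+] >> Ka the
  apparent constant is k_on(RS-)*Ka/[H+] + k_on(RSH), so the slope over Ka
  is the thiolate-specific constant and a zero-consistent intercept means
  the protonated thiol is unreactive;
* temperature series (Eyring): ln(k/T) = -dH/(R T) + ln(kB/h) + dS/R.

All fits are unweighted ordinary least squares via statsmodels, which also
supplies the studentized residuals used for outlier flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import statsmodels.api as sm
from statsmodels.stats.outliers_influence import OLSInfluence

from .constants import R, KB_OVER_H
from .protonation import ProtonationModel

DatasetKind = Literal["RS_T", "NO", "inverse_H", "inverse_T"]


@dataclass
class KobsDataset:
    """Observed rate constants against one independent variable."""

    x: np.ndarray  # independent variable (units by kind)
    k_obs: np.ndarray  # s^-1
    sd: np.ndarray | None  # s^-1, optional per-point SD (not used as weights)
    kind: DatasetKind
    ph: float = 7.4
    temperature: float = 278.15  # K
    no: float = 0.0  # mol/L, fixed condition where applicable
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.k_obs = np.asarray(self.k_obs, dtype=float)
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
        if self.kind not in ("RS_T", "NO", "inverse_H", "inverse_T"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if len(self.x) < 3:
            raise ValueError("need at least 3 records")
        if np.any(self.x <= 0):
            raise ValueError("independent variable must be strictly positive")


@dataclass
class LinearFitResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    r_squared: float
    outlier_indices: tuple[int, ...]
    intercept_zero_consistent: bool  # |intercept| <= 2 se


@dataclass
class EyringFit:
    """Activation parameters from a ln(k/T) vs 1/T regression."""

    dH: float  # kJ/mol
    dS: float  # J/(mol K)
    dG: float  # kJ/mol at report_T
    dH_se: float
    dS_se: float
    dG_se: float
    report_T: float
    r_squared: float


def _ols(x: np.ndarray, y: np.ndarray):
    res = sm.OLS(y, sm.add_constant(x)).fit()
    infl_t = OLSInfluence(res).resid_studentized_external if len(x) > 3 else np.zeros(len(x))
    return res, infl_t


def linear_kobs_fit(data: KobsDataset) -> LinearFitResult:
    """OLS of k_obs2 vs [RS]_T: slope = k_on apparent, intercept = k_off."""
    if data.kind != "RS_T":
        raise ValueError("dataset kind must be RS_T")
    res, student = _ols(data.x, data.k_obs)
    intercept, slope = res.params
    ise, sse = res.bse
    return LinearFitResult(
        slope=float(slope),
        intercept=float(intercept),
        slope_se=float(sse),
        intercept_se=float(ise),
        r_squared=float(res.rsquared),
        outlier_indices=tuple(int(i) for i in np.flatnonzero(np.abs(student) > 3)),
        intercept_zero_consistent=bool(abs(intercept) <= 2 * ise),
    )


@dataclass
class PhRegressionResult:
    k_on_thiolate: float  # M^-1 s^-1
    k_on_thiolate_se: float
    intercept: float  # apparent k_on of the protonated form, M^-1 s^-1
    intercept_se: float
    intercept_zero_consistent: bool
    r_squared: float


def ph_regression(
    data: KobsDataset, model: ProtonationModel, temperature: float | None = None
) -> PhRegressionResult:
    """Thiolate-specific k_on from apparent k_on values across a pH series.

    ``data.x`` is 1/[H+] in M^-1 and ``data.k_obs`` carries the apparent
    second-order constants (M^-1 s^-1).  slope/Ka gives k_on(RS-); the
    intercept estimates k_on of the protonated form and is reported with a
    zero-consistency verdict (|intercept| <= 2 se).
    """
    if data.kind != "inverse_H":
        raise ValueError("dataset kind must be inverse_H")
    T = data.temperature if temperature is None else temperature
    ka = 10.0 ** (-model.pka(T))
    res, _ = _ols(data.x, data.k_obs)
    intercept, slope = res.params
    ise, sse = res.bse
    return PhRegressionResult(
        k_on_thiolate=float(slope / ka),
        k_on_thiolate_se=float(sse / ka),
        intercept=float(intercept),
        intercept_se=float(ise),
        intercept_zero_consistent=bool(abs(intercept) <= 2 * ise),
        r_squared=float(res.rsquared),
    )


def eyring_fit(data: KobsDataset, report_T: float = 278.15) -> EyringFit:
    """Activation enthalpy/entropy from a temperature ladder of rate constants.

    ``data.x`` holds absolute temperatures (K); the regression is
    ln(k/T) vs 1/T, so dH = -slope*R and dS = (intercept - ln(kB/h))*R.
    """
    if data.kind != "inverse_T":
        raise ValueError("dataset kind must be inverse_T")
    if np.any(data.k_obs <= 0):
        raise ValueError("all rate constants must be > 0 for an Eyring analysis")
    inv_T = 1.0 / data.x
    y = np.log(data.k_obs / data.x)
    res, _ = _ols(inv_T, y)
    intercept, slope = res.params
    ise, sse = res.bse
    dH = -slope * R / 1000.0  # kJ/mol
    dS = (intercept - np.log(KB_OVER_H)) * R  # J/(mol K)
    dG = dH - report_T * dS / 1000.0
    # dG error from the (slope, intercept) covariance: dG = -R(slope)/1000 - T*R*(icpt-c)/1000
    cov = res.cov_params().values if hasattr(res.cov_params(), "values") else res.cov_params()
    g = np.array([-report_T * R / 1000.0, -R / 1000.0])  # d(dG)/d(intercept), d(dG)/d(slope)
    dG_se = float(np.sqrt(g @ cov @ g))
    return EyringFit(
        dH=float(dH),
        dS=float(dS),
        dG=float(dG),
        dH_se=float(sse * R / 1000.0),
        dS_se=float(ise * R),
        dG_se=dG_se,
        report_T=report_T,
        r_squared=float(res.rsquared),
    )


def eyring_rate(dH: float, dS: float, T: float) -> float:
    """Rate constant from activation parameters: k = (kB/h) T exp(dS/R) exp(-dH/(R T)).

    dH in kJ/mol, dS in J/(mol K).
    """
    return KB_OVER_H * T * np.exp(dS / R) * np.exp(-dH * 1000.0 / (R * T))


def fit_kobs1_curve(
    data: KobsDataset,
    k_on_NO: float,
    k_off_NO: float,
    rs_total: float,
    k_off_RS_guess: float = 10.0,
    k_on_RS_guess: float = 1e4,
) -> tuple[float, float]:
    """Estimate (k_off_RS, k_on_RS) from a pathway-1 k_obs vs [NO] dataset.

    The NO on/off constants are held at their independently known values; the
    dead-end-equilibrium rate law is fitted to the saturation curve by
    nonlinear least squares.
    """
    if data.kind != "NO":
        raise ValueError("dataset kind must be NO")
    from lmfit import Model as _LmModel

    def law(no, k_off_RS, k_on_RS):
        denom = k_on_RS * rs_total + k_on_NO * no
        return (k_off_RS * k_on_NO * no + k_on_RS * rs_total * k_off_NO) / denom

    m = _LmModel(law)
    p = m.make_params(k_off_RS=k_off_RS_guess, k_on_RS=k_on_RS_guess)
    p["k_off_RS"].set(min=0)
    p["k_on_RS"].set(min=0)
    out = m.fit(data.k_obs, p, no=data.x)
    return float(out.params["k_off_RS"].value), float(out.params["k_on_RS"].value)
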