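"""Exponential analysis of stopped-flow absorbance traces.

Observed rate constants come from nonlinear least-squares fits of

    A(t) = offset + sum_i a_i exp(-k_i t),   i = 1 or 2,

with deterministic initial guesses (no random restarts): the offset from the
tail of the trace, the rate from a log-linear regression over the early
decay.  Replicate runs are averaged; the instrument convention is a mean of
at least six runs per reported constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Model

from .kinetics import Trace


class FitFailure(RuntimeError):
    pass


@dataclass
class ExponentialFit:
    """Result of a 1- or 2-phase exponential fit."""

    amplitudes: tuple[float, ...]
    rates: tuple[float, ...]  # s^-1, descending
    offset: float
    amplitude_errors: tuple[float, ...]
    rate_errors: tuple[float, ...]
    offset_error: float
    residual_rms: float
    converged: bool
    ill_conditioned: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def rate(self) -> float:
        """The (slowest-phase) observed rate for single-phase reporting."""
        return self.rates[-1] if len(self.rates) > 1 else self.rates[0]


def _mono(t, a, k, offset):
    return offset + a * np.exp(-k * t)


def _bi(t, a1, k1, a2, k2, offset):
    return offset + a1 * np.exp(-k1 * t) + a2 * np.exp(-k2 * t)


def _initial_guess(t: np.ndarray, a: np.ndarray) -> tuple[float, float, float]:
    """Deterministic (amplitude, rate, offset) seed for the mono fit.

    Offset from the mean of the final 5% of points; rate from a log-linear
    regression of |A - offset| over the first 60% of the decay.
    """
    n = len(t)
    offset = float(np.mean(a[max(n - max(n // 20, 2), 0):]))
    amp = float(a[0] - offset)
    dev = np.abs(a - offset)
    m = max(int(0.6 * n), 3)
    mask = dev[:m] > 1e-3 * max(np.abs(amp), 1e-30)
    if mask.sum() >= 3:
        slope = np.polyfit(t[:m][mask], np.log(dev[:m][mask]), 1)[0]
        rate = max(-slope, 1e-9)
    else:
        rate = 1.0 / max(t[-1] - t[0], 1e-12)
    return amp, rate, offset


def fit_exponential(trace: Trace, n_phases: int = 1, dead_time: float = 0.0) -> ExponentialFit:
    """Fit a 1- or 2-phase exponential to a trace.

    Parameters
    ----------
    trace:
        Absorbance time course; needs >= 10 points for a stable fit.
    n_phases:
        1 for a single relaxation, 2 for biphasic traces.
    dead_time:
        Seconds masked from the start of the trace (mixing dead time).
    """
    if n_phases not in (1, 2):
        raise ValueError("n_phases must be 1 or 2")
    t, a = trace.time, trace.absorbance
    if dead_time > 0:
        keep = t >= t[0] + dead_time
        t, a = t[keep], a[keep]
    if len(t) < 10:
        raise ValueError("need at least 10 time points to fit")
    t = t - t[0]

    amp0, k0, off0 = _initial_guess(t, a)
    if n_phases == 1:
        model = Model(_mono)
        params = model.make_params(a=amp0, k=max(k0, 1e-9), offset=off0)
    else:
        model = Model(_bi)
        # split amplitude across a fast and ~20x slower phase
        params = model.make_params(
            a1=amp0 / 2, k1=max(k0 * 3, 1e-9), a2=amp0 / 2, k2=max(k0 / 10, 1e-10), offset=off0
        )
        params["k2"].set(min=0)
    for name in params:
        if name.startswith("k"):
            params[name].set(min=0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(a, params, t=t)
    if not result.success:
        raise FitFailure(f"exponential fit did not converge: {result.message}")

    def pv(name):  # value and stderr (stderr may be None if covariance failed)
        p = result.params[name]
        return p.value, (p.stderr if p.stderr is not None else np.nan)

    rms = float(np.sqrt(np.mean(result.residual**2)))
    if n_phases == 1:
        a_, ae = pv("a")
        k_, ke = pv("k")
        o_, oe = pv("offset")
        if k_ <= 0:
            raise FitFailure("fitted rate is non-positive")
        return ExponentialFit((a_,), (k_,), o_, (ae,), (ke,), oe, rms, True)
    a1, a1e = pv("a1")
    k1, k1e = pv("k1")
    a2, a2e = pv("a2")
    k2, k2e = pv("k2")
    o_, oe = pv("offset")
    # order phases fast-to-slow
    if k2 > k1:
        (a1, a1e, k1, k1e), (a2, a2e, k2, k2e) = (a2, a2e, k2, k2e), (a1, a1e, k1, k1e)
    ill = k2 > 0 and k1 / k2 < 3.0
    if ill:
        warnings.warn("biexponential rates differ by < 3x: fit is ill-conditioned", UserWarning)
    return ExponentialFit((a1, a2), (k1, k2), o_, (a1e, a2e), (k1e, k2e), oe, rms, True, ill)


def replicate_average(fits: list[ExponentialFit], phase: int = 0) -> tuple[float, float, int]:
    """Mean and sample SD of the observed rate over replicate fits.

    Non-converged fits are excluded with a warning; warns when fewer than six
    replicates remain (the instrument convention).
    Returns (mean, sd, n_used).
    """
    good = [f for f in fits if f.converged]
    if len(good) < len(fits):
        warnings.warn(f"excluded {len(fits) - len(good)} non-converged fit(s)", UserWarning)
    if len(good) < 2:
        raise ValueError("need at least two converged fits to average")
    if len(good) < 6:
        warnings.warn("fewer than six replicate runs", UserWarning)
    rates = np.array([f.rates[phase] for f in good])
    return float(rates.mean()), float(rates.std(ddof=1)), len(good)
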