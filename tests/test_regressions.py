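"""Secondary regressions: concentration, pH and Eyring analyses."""

import numpy as np
import pytest

from snokin.constants import R, KB_OVER_H
from snokin.protonation import ACCYS_5C, T5C, MissingPKaError, ProtonationModel
from snokin.regressions import (
    KobsDataset,
    eyring_fit,
    eyring_rate,
    fit_kobs1_curve,
    linear_kobs_fit,
    ph_regression,
)

T_LADDER = np.array([278.15, 283.15, 288.15, 293.15, 298.15])


def test_dataset_validation():
    with pytest.raises(ValueError, match="3 records"):
        KobsDataset(np.array([1.0, 2.0]), np.array([1.0, 2.0]), None, "RS_T")
    with pytest.raises(ValueError, match="strictly positive"):
        KobsDataset(np.array([0.0, 1.0, 2.0]), np.ones(3), None, "RS_T")
    with pytest.raises(ValueError, match="kind"):
        KobsDataset(np.ones(3), np.ones(3), None, "bogus")


def test_linear_fit_exact_on_noise_free_points():
    x = np.linspace(5e-4, 3e-3, 6)
    ds = KobsDataset(x, 1.76e4 * x + 5.9, None, "RS_T")
    fit = linear_kobs_fit(ds)
    assert fit.slope == pytest.approx(1.76e4, rel=1e-10)
    assert fit.intercept == pytest.approx(5.9, rel=1e-10)
    assert not fit.outlier_indices


def test_linear_fit_bias_and_coverage(rng):
    """2% noise, 6 concentrations, 200 replicates: slope bias < 1% and the
    1-se interval covers the truth at its nominal level.

    With 6 points (4 residual degrees of freedom) the nominal coverage of a
    +/-1 estimated-SE interval is P(|t_4| <= 1) ~ 0.626, not the Gaussian 68%.
    """
    from scipy import stats

    x = np.linspace(5e-4, 3e-3, 6)
    truth = 1.76e4 * x + 5.9
    slopes, covered = [], 0
    for _ in range(200):
        y = truth * (1 + rng.normal(0, 0.02, size=6))
        fit = linear_kobs_fit(KobsDataset(x, y, None, "RS_T"))
        slopes.append(fit.slope)
        covered += abs(fit.slope - 1.76e4) <= fit.slope_se
    nominal = 1 - 2 * stats.t.sf(1.0, df=4)
    assert abs(np.mean(slopes) / 1.76e4 - 1) < 0.01
    assert abs(covered / 200 - nominal) <= 0.075


def test_outlier_flagged_by_studentized_residual():
    x = np.linspace(5e-4, 3e-3, 6)
    y = 1.76e4 * x + 5.9
    y[3] *= 10.0
    fit = linear_kobs_fit(KobsDataset(x, y, None, "RS_T"))
    assert 3 in fit.outlier_indices


def test_ph_regression_recovers_published_thiolate_constant():
    """The four published apparent k_on values against 1/[H+] with pKa 9.95
    give the thiolate-specific constant within its published uncertainty."""
    ph = np.array([6.3, 6.8, 7.4, 8.0])
    k_app = np.array([0.14e4, 0.46e4, 1.76e4, 7.1e4])
    ds = KobsDataset(10.0**ph, k_app, None, "inverse_H", temperature=T5C)
    res = ph_regression(ds, ACCYS_5C)
    assert abs(res.k_on_thiolate - 6.32e6) <= 0.06e6
    assert res.intercept_zero_consistent


def test_ph_regression_exact_on_synthetic(accys_model):
    k_true = 5e6
    ph = np.array([6.0, 6.5, 7.0, 7.5])
    ka = 10.0**-9.95
    x = 10.0**ph
    k_app = k_true * ka * x  # acid-regime linearisation, zero intercept
    res = ph_regression(KobsDataset(x, k_app, None, "inverse_H", temperature=T5C), accys_model)
    assert res.k_on_thiolate == pytest.approx(k_true, rel=1e-10)
    assert res.intercept_zero_consistent


def test_ph_regression_detects_nonzero_intercept(accys_model):
    ph = np.array([6.0, 6.5, 7.0, 7.5])
    x = 10.0**ph
    slope = 5e6 * 10.0**-9.95
    k_app = slope * x + 0.1 * slope * x.min()  # deliberate intercept
    res = ph_regression(KobsDataset(x, k_app, None, "inverse_H", temperature=T5C), accys_model)
    assert not res.intercept_zero_consistent


def test_ph_regression_requires_pka():
    ds = KobsDataset(10.0 ** np.array([6.3, 6.8, 7.4]), np.ones(3), None, "inverse_H",
                     temperature=298.15)
    with pytest.raises(MissingPKaError):
        ph_regression(ds, ACCYS_5C)


def test_ph_regression_abscissa_unit_invariance(accys_model):
    """Converting 1/[H+] to mM^-1 (and the constants consistently) leaves the
    thiolate-specific result unchanged."""
    ph = np.array([6.3, 6.8, 7.4, 8.0])
    k_app = np.array([0.14e4, 0.46e4, 1.76e4, 7.1e4])
    res_M = ph_regression(KobsDataset(10.0**ph, k_app, None, "inverse_H", temperature=T5C),
                          accys_model)
    # abscissa in mM^-1: x' = x/1000, slope' = 1000*slope, same slope/Ka after
    # converting Ka to mM units (Ka' = Ka*1000)
    res_mM = ph_regression(KobsDataset(10.0**ph / 1e3, k_app, None, "inverse_H",
                                       temperature=T5C), accys_model)
    assert res_mM.k_on_thiolate / 1e3 == pytest.approx(res_M.k_on_thiolate, rel=1e-9)


def test_eyring_recovers_published_forward_parameters():
    ks = np.array([6.32e6, 7.0e6, 7.4e6, 8.0e6, 8.9e6])
    fit = eyring_fit(KobsDataset(T_LADDER, ks, None, "inverse_T"), report_T=T5C)
    assert abs(fit.dH - 9.4) <= 1.0
    assert abs(fit.dS - (-80.0)) <= 3.0
    assert fit.dG == pytest.approx(fit.dH - T5C * fit.dS / 1000.0, rel=1e-12)


def test_eyring_gibbs_from_published_parameters():
    """dG(278.15 K) from dH 9.4 and dS -80 is 31.7, printed as 32 +/- 1."""
    dG = 9.4 - T5C * (-80.0) / 1000.0
    assert dG == pytest.approx(31.65, abs=0.01)
    assert abs(dG - 32.0) <= 1.0


def test_eyring_generator_identity():
    """eyring_fit inverts eyring_rate exactly on noise-free ladders."""
    ks = np.array([eyring_rate(56.0, -27.0, t) for t in T_LADDER])
    fit = eyring_fit(KobsDataset(T_LADDER, ks, None, "inverse_T"), report_T=T5C)
    assert fit.dH == pytest.approx(56.0, rel=1e-9)
    assert fit.dS == pytest.approx(-27.0, rel=1e-9)


def test_eyring_rejects_nonpositive_rates():
    with pytest.raises(ValueError):
        eyring_fit(KobsDataset(T_LADDER[:3], np.array([1.0, 0.0, 2.0]), None, "inverse_T"))


def test_standard_errors_shrink_as_inverse_sqrt_n(rng):
    """Replicating a design n-fold shrinks regression SEs like 1/sqrt(n)."""
    x0 = np.linspace(5e-4, 3e-3, 4)
    ses = {}
    for reps in (4, 16, 64):
        x = np.tile(x0, reps)
        se_acc = []
        for _ in range(40):
            y = (1.76e4 * x + 5.9) + rng.normal(0, 0.5, size=x.size)
            se_acc.append(linear_kobs_fit(KobsDataset(x, y, None, "RS_T")).slope_se)
        ses[reps] = np.mean(se_acc)
    assert ses[4] / ses[16] == pytest.approx(2.0, rel=0.15)
    assert ses[16] / ses[64] == pytest.approx(2.0, rel=0.15)


def test_fit_kobs1_curve_recovers_dissociation_rate(k_published):
    from snokin.rate_laws import OperatingPoint, kobs1_closed_form

    no = np.linspace(5e-5, 8.5e-4, 8)
    y = np.array([kobs1_closed_form(k_published, OperatingPoint(no=v, rs_total=3e-3))
                  for v in no])
    ds = KobsDataset(no, y, None, "NO")
    k_off_rs, k_on_rs = fit_kobs1_curve(ds, k_published.k_on_NO, k_published.k_off_NO, 3e-3)
    assert k_off_rs == pytest.approx(k_published.k_off_RS, rel=1e-6)
    assert k_on_rs == pytest.approx(k_published.k_on_RS, rel=1e-4)
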