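"""Mass-action network: simulation, conservation, relaxation eigenvalues."""

import numpy as np
import pytest

from snokin.kinetics import (
    DegenerateRelaxation,
    IntegrationFailure,
    RateConstants,
    Reaction,
    Mechanism,
    absorbance_trace,
    heme_total,
    initial_state,
    relaxation_rate,
    scheme_network,
    simulate,
    single_step_network,
    species_vector,
    SPECIES,
)
from snokin.rate_laws import OperatingPoint, kobs1_closed_form
from snokin.traces import fit_exponential


ALPHA_74 = 1.0 / (1.0 + 10.0 ** (9.95 - 7.4))  # AcCys thiolate fraction at pH 7.4, 5 degC


def test_rate_constant_validation():
    with pytest.raises(ValueError):
        RateConstants(k_off_RS=-1.0)
    with pytest.raises(ValueError):
        RateConstants(k_on_NO=2e10)  # above the diffusion ceiling


def test_reaction_rejects_termolecular():
    with pytest.raises(ValueError):
        Reaction({"NO": 2, "Fe3_H2O": 1}, {"Fe2_NOplus": 1}, "k_on_NO")


def test_single_step_relaxation_is_kon_L_plus_koff():
    """Reversible one-step binding relaxes at exactly k_on[L] + k_off."""
    k = RateConstants(k_on_RSminus=1e6, k_off_RSminus=10.0, k2=0.0)
    op = species_vector(RSminus=1e-5)
    assert relaxation_rate(single_step_network(), k, op) == pytest.approx(20.0, rel=1e-10)

    # and the simulated trajectory is mono-exponential with that rate
    times = np.linspace(0, 0.5, 200)
    init = species_vector(Fe2_NOplus=5e-6, RSminus=1e-5)
    series = simulate(single_step_network(), k, init, times)
    i1 = series[:, SPECIES.index("I1")]
    resid = i1 - i1[-1] * (1 - np.exp(-20.0 * times))
    assert np.max(np.abs(resid)) < 1e-3 * i1[-1]


def test_all_zero_rates_freeze_the_state():
    k = RateConstants(k_on_RS=0, k_off_RS=0, k_on_NO=0, k_off_NO=0,
                      k_on_RSminus=0, k_off_RSminus=0, k2=0)
    init = initial_state(5e-6, 8e-4, 3e-3, ALPHA_74, heme_form="Fe3_RS")
    series = simulate(scheme_network(), k, init, np.linspace(0, 10, 50))
    assert np.allclose(series, series[0], atol=1e-15)


def test_irreversible_first_order_rate():
    mech = Mechanism((Reaction({"I1": 1}, {"Fe2_NO": 1, "RSNO_free": 1}, "k2"),))
    k = RateConstants(k2=5.0)
    assert relaxation_rate(mech, k, species_vector()) == pytest.approx(5.0, rel=1e-12)


def test_heme_conservation(k_published):
    init = initial_state(5e-6, 8e-4, 3e-3, ALPHA_74, heme_form="Fe3_RS")
    series = simulate(scheme_network(), k_published, init, np.linspace(0, 2, 300))
    drift = np.abs(heme_total(series) / 5e-6 - 1.0)
    assert drift.max() < 1e-6


def test_detailed_balance_equilibrium_ratio(k_published):
    """With the product step off, the simulated I1/(Fe2_NOplus*[RS-]) ratio at
    long times equals k_on_RSminus/k_off_RSminus."""
    mech = scheme_network(include_product_step=False)
    init = initial_state(5e-6, 8e-4, 3e-3, ALPHA_74, heme_form="Fe3_RS")
    series = simulate(mech, k_published, init, np.linspace(0, 60, 50))
    y = series[-1]
    rs_minus = 3e-3 * ALPHA_74
    ratio = y[SPECIES.index("I1")] / (y[SPECIES.index("Fe2_NOplus")] * rs_minus)
    assert ratio == pytest.approx(k_published.k_on_RSminus / k_published.k_off_RSminus, rel=1e-3)


def test_pseudo_first_order_matches_unclamped_with_excess(k_published):
    """>=10x reservoir excess: clamped and unclamped I1 trajectories agree within 2%."""
    times = np.linspace(0, 0.5, 120)
    alpha = ALPHA_74
    init = initial_state(5e-6, 8e-4, 3e-3, alpha, heme_form="Fe3_RS")
    clamped = simulate(scheme_network(pseudo_first_order=True), k_published, init, times)
    ratio = 10.0 ** (7.4 - 9.95)
    unclamped = simulate(
        scheme_network(pseudo_first_order=False, proton_exchange_ratio=ratio),
        k_published, init, times,
    )
    i1c = clamped[:, SPECIES.index("I1")]
    i1u = unclamped[:, SPECIES.index("I1")]
    assert np.max(np.abs(i1u - i1c)) <= 0.02 * i1c.max()


def test_scheme3_relaxation_matches_closed_form(k_published, op_fig3):
    """The numerical relaxation rate of I1 formation agrees with the dead-end
    equilibrium rate law in the steady-state-valid regime (5%)."""
    op = species_vector(NO=op_fig3.no, RSH=op_fig3.rs_total * (1 - ALPHA_74),
                        RSminus=op_fig3.rs_total * ALPHA_74)
    rr = relaxation_rate(scheme_network(include_product_step=False), k_published, op)
    cf = kobs1_closed_form(k_published, op_fig3)
    assert rr == pytest.approx(cf, rel=0.05)


def test_relaxation_rate_two_routes_agree(k_published, op_fig3):
    """Eigenvalue route vs exponential fit of the simulated observable: 2%.

    Starting from the thiol-bound ferric complex, the observable carries a
    fast attack transient on top of the slow supply relaxation, so the fit
    route uses two phases and compares the slow one.
    """
    op = species_vector(NO=op_fig3.no, RSH=op_fig3.rs_total * (1 - ALPHA_74),
                        RSminus=op_fig3.rs_total * ALPHA_74)
    mech = scheme_network(include_product_step=False)
    rr = relaxation_rate(mech, k_published, op)
    init = initial_state(5e-6, op_fig3.no, op_fig3.rs_total, ALPHA_74, heme_form="Fe3_RS")
    times = np.linspace(0, 7.0 / rr, 700)
    series = simulate(mech, k_published, init, times)
    tr = absorbance_trace(series, times)
    fit = fit_exponential(tr, n_phases=2)
    assert fit.rates[-1] == pytest.approx(rr, rel=0.02)


def test_high_no_limit_monotone_approach_to_koff_rs(k_published):
    """k_obs1 grows monotonically toward k_off_RS as [NO] increases."""
    rates = []
    for no in np.geomspace(1e-4, 1e-1, 8):
        op = species_vector(NO=no, RSH=3e-3 * (1 - ALPHA_74), RSminus=3e-3 * ALPHA_74)
        rates.append(relaxation_rate(scheme_network(include_product_step=False),
                                     k_published, op))
    assert np.all(np.diff(rates) > 0)
    assert rates[-1] == pytest.approx(k_published.k_off_RS, rel=0.01)


def test_degenerate_eigenvalues_warn():
    mech = Mechanism((
        Reaction({"Fe3_H2O": 1}, {"Fe2_NOplus": 1}, "_aux:5.0"),
        Reaction({"I1": 1}, {"Fe2_NO": 1}, "_aux:5.001"),
    ))
    with pytest.warns(DegenerateRelaxation):
        relaxation_rate(mech, RateConstants(), species_vector())


def test_absorbance_flat_when_epsilons_equal(k_published):
    """Equal molar absorptivities make the trace constant (heme conservation)."""
    init = initial_state(5e-6, 8e-4, 3e-3, ALPHA_74, heme_form="Fe3_RS")
    times = np.linspace(0, 1, 100)
    series = simulate(scheme_network(include_product_step=False), k_published, init, times)
    eps = {s: 1e5 for s in ("Fe3_H2O", "Fe3_RS", "Fe2_NOplus", "I1", "Fe2_NO")}
    tr = absorbance_trace(series, times, eps)
    assert np.allclose(tr.absorbance, 1e5 * 5e-6, rtol=1e-6)


def test_absorbance_missing_epsilon_raises(k_published):
    init = initial_state(5e-6, 8e-4, 3e-3, ALPHA_74, heme_form="Fe3_RS")
    times = np.linspace(0, 1, 20)
    series = simulate(scheme_network(), k_published, init, times)
    with pytest.raises(KeyError, match="Fe3_RS"):
        absorbance_trace(series, times, {"Fe3_H2O": 1e5})


def test_simulate_input_validation(k_published):
    init = initial_state(5e-6, 8e-4, 3e-3, 0.01)
    with pytest.raises(ValueError, match="strictly increasing"):
        simulate(scheme_network(), k_published, init, np.array([0.0, 1.0, 1.0]))
    init[0] = -1e-9
    with pytest.raises(ValueError, match="non-negative"):
        simulate(scheme_network(), k_published, init, np.linspace(0, 1, 10))


def test_mechanism_json_round_trip():
    mech = scheme_network()
    assert Mechanism.from_json(mech.to_json()) == mech
    k = RateConstants()
    assert RateConstants.from_json(k.to_json()) == k
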