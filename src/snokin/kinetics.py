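"""Mass-action reaction network for heme-mediated S-nitrosothiol formation.

The network couples three reversible elementary steps around the AcMP-11 heme
centre and one slow product-forming step:

    Fe3+(H2O) + RS(H/-)  <=>  Fe3+(RS)            (k_on_RS / k_off_RS)
    Fe3+(H2O) + NO       <=>  Fe2+(NO+)           (k_on_NO / k_off_NO)
    Fe2+(NO+) + RS-      <=>  I1                  (k_on_RSminus / k_off_RSminus)
    I1                   -->  Fe2+(NO) + RSNO     (k2, lumped, NO excess)

The thiol-binding step to the ferric centre is a dead end: product only forms
through thiolate attack on the nitrosylated ferrous centre.  k_on_RS is an
apparent constant against the total thiol pool, so both protonation states
bind with it (their clamped sum is [RS]_T); the thiolate-attack step uses the
RS- pool alone.

Simulations integrate the stiff mass-action ODEs (rate constants span seven
orders of magnitude) and serve as the numerical oracle for the closed-form
observed-rate laws in :mod:`snokin.rate_laws`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import solve_ivp

from .constants import DIFFUSION_LIMIT

#: Canonical species order. The first five are heme species whose total is
#: conserved (up to the k2 sink feeding Fe2_NO, itself a heme species).
HEME_SPECIES = ("Fe3_H2O", "Fe3_RS", "Fe2_NOplus", "I1", "Fe2_NO")
RESERVOIR_SPECIES = ("NO", "RSH", "RSminus", "RSNO_free")
SPECIES = HEME_SPECIES + RESERVOIR_SPECIES


class IntegrationFailure(RuntimeError):
    pass


class DegenerateRelaxation(UserWarning):
    """Two relaxation eigenvalues are too close for a single-exponential read-out."""


@dataclass(frozen=True)
class RateConstants:
    """Microscopic rate constants of the network (M^-1 s^-1 / s^-1)."""

    k_on_RS: float = 1.0e4
    k_off_RS: float = 20.0
    k_on_NO: float = 3.7e6
    k_off_NO: float = 3.4
    k_on_RSminus: float = 6.32e6
    k_off_RSminus: float = 5.9
    k2: float = 0.05

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name in ("k_on_NO", "k_on_RSminus"):
            if getattr(self, name) > DIFFUSION_LIMIT:
                raise ValueError(f"{name} exceeds the diffusion ceiling {DIFFUSION_LIMIT:g}")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "RateConstants":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class Reaction:
    """One elementary reaction: stoichiometry maps plus a rate-constant name."""

    reactants: dict[str, int]
    products: dict[str, int]
    rate: str  # attribute name on RateConstants, or "_aux:<value>" literal

    def __post_init__(self) -> None:
        if sum(self.reactants.values()) > 2:
            raise ValueError("only elementary reactions (molecularity <= 2) are allowed")
        for sp in list(self.reactants) + list(self.products):
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r}")

    def rate_value(self, k: RateConstants) -> float:
        if self.rate.startswith("_aux:"):
            return float(self.rate.split(":", 1)[1])
        return getattr(k, self.rate)


@dataclass(frozen=True)
class Mechanism:
    reactions: tuple[Reaction, ...]
    clamped: frozenset[str] = frozenset()

    def to_json(self) -> str:
        return json.dumps(
            {
                "reactions": [
                    {"reactants": r.reactants, "products": r.products, "rate": r.rate}
                    for r in self.reactions
                ],
                "clamped": sorted(self.clamped),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "Mechanism":
        d = json.loads(text)
        return cls(
            reactions=tuple(Reaction(r["reactants"], r["products"], r["rate"]) for r in d["reactions"]),
            clamped=frozenset(d["clamped"]),
        )


def scheme_network(
    pseudo_first_order: bool = True,
    include_product_step: bool = True,
    proton_exchange_ratio: float | None = None,
) -> Mechanism:
    """The default dead-end-equilibrium network.

    Parameters
    ----------
    pseudo_first_order:
        Clamp NO and both thiol pools at their initial values (reservoir
        excess). This is the stopped-flow operating regime.
    include_product_step:
        Keep the lumped I1 -> Fe2+(NO) + RSNO step (k2). Switch off to study
        the pure binding equilibrium.
    proton_exchange_ratio:
        [RS-]/[RSH] ratio (= 10**(pH - pKa)). When given and the thiol pools
        are unclamped, a fast exchange pair re-partitions released thiol;
        irrelevant under clamping.
    """
    rxns = [
        Reaction({"Fe3_H2O": 1, "RSH": 1}, {"Fe3_RS": 1}, "k_on_RS"),
        Reaction({"Fe3_H2O": 1, "RSminus": 1}, {"Fe3_RS": 1}, "k_on_RS"),
        Reaction({"Fe3_RS": 1}, {"Fe3_H2O": 1, "RSH": 1}, "k_off_RS"),
        Reaction({"Fe3_H2O": 1, "NO": 1}, {"Fe2_NOplus": 1}, "k_on_NO"),
        Reaction({"Fe2_NOplus": 1}, {"Fe3_H2O": 1, "NO": 1}, "k_off_NO"),
        Reaction({"Fe2_NOplus": 1, "RSminus": 1}, {"I1": 1}, "k_on_RSminus"),
        Reaction({"I1": 1}, {"Fe2_NOplus": 1, "RSminus": 1}, "k_off_RSminus"),
    ]
    if include_product_step:
        rxns.append(Reaction({"I1": 1}, {"Fe2_NO": 1, "RSNO_free": 1}, "k2"))
    clamped: frozenset[str] = frozenset()
    if pseudo_first_order:
        clamped = frozenset({"NO", "RSH", "RSminus"})
    elif proton_exchange_ratio is not None:
        k_ex = 1.0e6  # fast relative to every binding step
        rxns.append(Reaction({"RSH": 1}, {"RSminus": 1}, f"_aux:{k_ex * proton_exchange_ratio}"))
        rxns.append(Reaction({"RSminus": 1}, {"RSH": 1}, f"_aux:{k_ex}"))
    return Mechanism(tuple(rxns), clamped)


def single_step_network(clamp_ligand: bool = True) -> Mechanism:
    """Just the reversible thiolate attack Fe2+(NO+) + RS- <=> I1."""
    rxns = (
        Reaction({"Fe2_NOplus": 1, "RSminus": 1}, {"I1": 1}, "k_on_RSminus"),
        Reaction({"I1": 1}, {"Fe2_NOplus": 1, "RSminus": 1}, "k_off_RSminus"),
    )
    return Mechanism(rxns, frozenset({"RSminus"}) if clamp_ligand else frozenset())


def species_vector(**conc: float) -> np.ndarray:
    """Concentration vector in canonical order from keyword species names."""
    y = np.zeros(len(SPECIES))
    for name, c in conc.items():
        if name not in SPECIES:
            raise ValueError(f"unknown species {name!r}")
        if c < 0:
            raise ValueError(f"negative concentration for {name}")
        y[SPECIES.index(name)] = c
    return y


def initial_state(
    heme_total: float,
    no: float,
    rs_total: float,
    thiolate_fraction: float,
    heme_form: str = "Fe3_RS",
) -> np.ndarray:
    """Initial SpeciesVector with all heme in one form and partitioned thiol."""
    return species_vector(
        **{
            heme_form: heme_total,
            "NO": no,
            "RSH": rs_total * (1.0 - thiolate_fraction),
            "RSminus": rs_total * thiolate_fraction,
        }
    )


def _rates(mech: Mechanism, k: RateConstants) -> np.ndarray:
    return np.array([r.rate_value(k) for r in mech.reactions])


def _stoich(mech: Mechanism) -> tuple[np.ndarray, np.ndarray]:
    """Reactant-order matrix and net stoichiometry matrix (species x reactions)."""
    n_sp, n_rx = len(SPECIES), len(mech.reactions)
    order = np.zeros((n_sp, n_rx))
    net = np.zeros((n_sp, n_rx))
    for j, r in enumerate(mech.reactions):
        for sp, nu in r.reactants.items():
            order[SPECIES.index(sp), j] = nu
            net[SPECIES.index(sp), j] -= nu
        for sp, nu in r.products.items():
            net[SPECIES.index(sp), j] += nu
    # a clamped species participates in reactions but its net change is zeroed
    for sp in mech.clamped:
        net[SPECIES.index(sp), :] = 0.0
    return order, net


def simulate(
    mech: Mechanism,
    k: RateConstants,
    init: np.ndarray,
    times: np.ndarray,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> np.ndarray:
    """Integrate the mass-action ODEs on a fixed time grid.

    Returns an array of shape (len(times), n_species) in canonical order.
    Raises :class:`IntegrationFailure` on non-finite output or negative
    concentrations beyond the absolute tolerance.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    init = np.asarray(init, dtype=float)
    if np.any(init < 0):
        raise ValueError("initial concentrations must be non-negative")
    kvec = _rates(mech, k)
    order, net = _stoich(mech)

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        yc = np.clip(y, 0.0, None)
        # product of reactant concentrations to their stoichiometric order
        flux = kvec * np.prod(np.where(order > 0, yc[:, None] ** order, 1.0), axis=0)
        return net @ flux

    t0, t1 = (times[0], times[-1]) if len(times) > 1 else (0.0, times[0])
    sol = solve_ivp(
        rhs, (min(t0, 0.0), t1), init, t_eval=times, method="LSODA", rtol=rtol, atol=atol
    )
    if not sol.success:
        raise IntegrationFailure(f"ODE integration failed: {sol.message}")
    y = sol.y.T
    if not np.all(np.isfinite(y)):
        bad = SPECIES[int(np.argwhere(~np.isfinite(y))[0][1])]
        raise IntegrationFailure(f"non-finite concentration for species {bad}")
    neg = y < -100 * atol
    if np.any(neg):
        bad = SPECIES[int(np.argwhere(neg)[0][1])]
        raise IntegrationFailure(f"negative concentration beyond tolerance for species {bad}")
    return np.clip(y, 0.0, None)


def heme_total(series: np.ndarray) -> np.ndarray:
    """Total heme concentration along a simulated trajectory."""
    idx = [SPECIES.index(s) for s in HEME_SPECIES]
    return series[..., idx].sum(axis=-1)


@dataclass
class Trace:
    """Single-wavelength absorbance time course with its experimental metadata."""

    time: np.ndarray
    absorbance: np.ndarray
    wavelength_nm: float = 413.0
    no: float = 0.0  # mol/L
    rs_total: float = 0.0  # mol/L
    ph: float = 7.4
    temperature: float = 278.15  # K
    heme_total: float = 5e-6  # mol/L
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.shape != self.absorbance.shape:
            raise ValueError("time and absorbance must have the same shape")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.absorbance)):
            raise ValueError("absorbance must be finite")


#: Default per-species molar absorptivities at 413 nm (M^-1 cm^-1). Free
#: parameters of the synthetic observable: the study reports band positions,
#: not extinction coefficients, so these are package defaults chosen to give
#: distinct, Soret-scale contrasts between the coordination states.
DEFAULT_EPSILONS = {
    "Fe3_H2O": 9.0e4,
    "Fe3_RS": 6.0e4,
    "Fe2_NOplus": 7.0e4,
    "I1": 1.5e5,
    "Fe2_NO": 1.1e5,
}


def absorbance_trace(
    series: np.ndarray,
    times: np.ndarray,
    epsilons: dict[str, float] | None = None,
    pathlength_cm: float = 1.0,
    **trace_meta,
) -> Trace:
    """Beer-Lambert observable A(t) = sum_i eps_i * c_i(t) * path over heme species."""
    eps = DEFAULT_EPSILONS if epsilons is None else epsilons
    for name, v in eps.items():
        if v < 0:
            raise ValueError(f"negative epsilon for {name}")
    a = np.zeros(series.shape[0])
    for i, sp in enumerate(HEME_SPECIES):
        col = series[:, SPECIES.index(sp)]
        if np.any(col > 0):
            if sp not in eps:
                raise KeyError(f"no molar absorptivity configured for populated species {sp}")
            a += eps[sp] * col * pathlength_cm
    return Trace(time=np.asarray(times, float), absorbance=a, **trace_meta)


def _kinetic_matrix(mech: Mechanism, k: RateConstants, operating: np.ndarray) -> np.ndarray:
    """Jacobian of the heme subsystem at an operating point (reservoirs fixed).

    With reservoir species clamped every remaining reaction is (pseudo-)first
    order in one heme species, so the heme block is exactly linear and the
    Jacobian is state-independent.
    """
    n = len(HEME_SPECIES)
    a = np.zeros((n, n))
    for r in mech.reactions:
        kv = r.rate_value(k)
        heme_in = [sp for sp in r.reactants if sp in HEME_SPECIES]
        if not heme_in:
            continue  # pure reservoir reaction does not move heme
        if len(heme_in) != 1 or r.reactants[heme_in[0]] != 1:
            raise ValueError("heme subsystem is not linear: reaction with >1 heme reactant")
        src = HEME_SPECIES.index(heme_in[0])
        for sp, nu in r.reactants.items():
            if sp in RESERVOIR_SPECIES:
                kv *= operating[SPECIES.index(sp)] ** nu
        a[src, src] -= kv
        for sp, nu in r.products.items():
            if sp in HEME_SPECIES:
                a[HEME_SPECIES.index(sp), src] += nu * kv
    return a


def relaxation_rate(
    mech: Mechanism,
    k: RateConstants,
    operating: np.ndarray,
    degeneracy_tol: float = 0.01,
) -> float:
    """Slowest non-zero relaxation rate (s^-1) at an operating point.

    Eigen-analysis of the linearised (clamped-reservoir) heme kinetic matrix.
    Warns with :class:`DegenerateRelaxation` when the two slowest non-zero
    eigenvalues differ by less than ``degeneracy_tol`` (relative), in which
    case a single-exponential description of the observable is unreliable.
    """
    a = _kinetic_matrix(mech, k, np.asarray(operating, float))
    ev = np.linalg.eigvals(a)
    mags = np.sort(np.abs(ev.real))
    scale = mags[-1] if mags[-1] > 0 else 1.0
    nonzero = mags[mags > 1e-9 * scale]
    if nonzero.size == 0:
        return 0.0
    if nonzero.size >= 2 and (nonzero[1] - nonzero[0]) < degeneracy_tol * nonzero[0]:
        warnings.warn(
            "two slowest relaxation eigenvalues within 1%: single-exponential fit invalid",
            DegenerateRelaxation,
            stacklevel=2,
        )
    return float(nonzero[0])
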