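"""Synthetic stopped-flow data with the statistical structure the analysis assumes.

Every input the pipeline consumes can be generated here from known ground
truth: absorbance traces (mass-action simulation + Beer-Lambert observable +
i.i.d. Gaussian noise), observed-rate datasets shaped like the concentration,
pH and temperature series, and equilibrium titrations.  The default scenario
mirrors the published experiment: 5 uM heme, 0.18 mM NO in the nitrosyl
premix, 0.5-3 mM thiol, pH 6.3-8.0, 5-25 degC, with the measured AcCys/GSH
rate constants and pKa values as truth; the ferric thiol-binding pair
(k_on_RS/k_off_RS), unquantified in the published tables available here, uses
package placeholder values and is flagged as such in the manifest.

Premixes are assumed fully equilibrated before the second mixing drive; the
mixing dead time is not modelled (traces start at t=0 of the second mix).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import celsius_to_kelvin
from .kinetics import (
    DEFAULT_EPSILONS,
    RateConstants,
    Trace,
    absorbance_trace,
    initial_state,
    scheme_network,
    simulate,
)
from .protonation import ProtonationModel, thiolate_fraction
from .rate_laws import OperatingPoint, kobs1_closed_form, kobs2_from_constants
from .regressions import KobsDataset, eyring_rate
from .equilibria import TitrationSeries, _free_ligand

#: Aqueous NO solubility ceiling (mol/L); grids beyond this are rejected.
NO_SOLUBILITY = 1.7e-3


@dataclass
class ScenarioConfig:
    """Ground truth and experimental design for one synthetic study."""

    rate_constants: RateConstants = field(default_factory=RateConstants)
    protonation: ProtonationModel = field(
        default_factory=lambda: ProtonationModel({278.15: 9.95}, thiol="AcCys")
    )
    thiol: str = "AcCys"
    heme_total: float = 5e-6  # mol/L
    no_premix: float = 1.8e-4  # mol/L, pathway-2 nitrosylation premix
    no_grid: tuple[float, ...] = tuple(np.linspace(5e-5, 8.5e-4, 8))
    rs_grid: tuple[float, ...] = tuple(np.linspace(5e-4, 3e-3, 6))
    rs_premix: float = 3e-3  # mol/L, pathway-1 thiol premix
    ph_grid: tuple[float, ...] = (6.3, 6.8, 7.4, 8.0)
    temp_grid_C: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0)
    ph: float = 7.4
    temperature: float = 278.15  # K
    # forward/back activation parameters used by temperature-ladder tables;
    # chosen consistent with the 5 degC rate constants above
    dH_fwd: float = 9.4  # kJ/mol
    dS_fwd: float = -80.0  # J/(mol K)
    dH_back: float = 56.0
    dS_back: float = -27.0
    noise: float = 0.005  # relative, on absorbance amplitude / k_obs
    n_points: int = 400  # samples per trace
    epsilons: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EPSILONS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise < 0:
            raise ValueError("noise must be >= 0")
        if max(self.no_grid) > NO_SOLUBILITY or self.no_premix > NO_SOLUBILITY:
            raise ValueError(f"[NO] above the aqueous solubility window ({NO_SOLUBILITY:g} M)")

    def alpha(self, ph: float | None = None, temperature: float | None = None) -> float:
        return thiolate_fraction(
            self.protonation,
            self.ph if ph is None else ph,
            self.temperature if temperature is None else temperature,
        )


def published_scenario(seed: int = 0, thiol: str = "AcCys") -> ScenarioConfig:
    """The default published-experiment-shaped scenario for AcCys or GSH."""
    if thiol == "AcCys":
        k = RateConstants(k_on_RSminus=6.32e6, k_off_RSminus=5.9)
        prot = ProtonationModel({278.15: 9.95}, thiol="AcCys")
    elif thiol == "GSH":
        k = RateConstants(k_on_RSminus=4.3e6, k_off_RSminus=28.0)
        prot = ProtonationModel({278.15: 9.32}, thiol="GSH")
    else:
        raise ValueError(f"no built-in scenario for thiol {thiol!r}")
    return ScenarioConfig(rate_constants=k, protonation=prot, thiol=thiol, seed=seed)


def _noisy(rng: np.random.Generator, values: np.ndarray, scale) -> np.ndarray:
    scale = np.asarray(scale, dtype=float)
    if not np.any(scale > 0):
        return values.copy()
    return values + rng.normal(0.0, 1.0, size=values.shape) * scale


def make_trace_set(cfg: ScenarioConfig, pathway: int) -> list[Trace]:
    """Simulated noisy traces for one reactivity pathway.

    Pathway 1: ferric heme pre-equilibrated with thiol, then mixed with NO
    over ``cfg.no_grid``.  Pathway 2: heme pre-nitrosylated in NO excess,
    then mixed with thiol over ``cfg.rs_grid``.
    """
    if pathway not in (1, 2):
        raise ValueError("pathway must be 1 or 2")
    rng = np.random.default_rng(cfg.seed)
    k = cfg.rate_constants
    alpha = cfg.alpha()
    mech = scheme_network(pseudo_first_order=True)
    traces: list[Trace] = []

    if pathway == 1:
        # premix: Fe3_H2O <=> Fe3_RS at the premix thiol concentration
        Keq_rs = k.k_on_RS / k.k_off_RS if k.k_off_RS > 0 else np.inf
        f_bound = (
            1.0 if np.isinf(Keq_rs) else (Keq_rs * cfg.rs_premix) / (1.0 + Keq_rs * cfg.rs_premix)
        )
        for no in cfg.no_grid:
            op = OperatingPoint(no=no, rs_total=cfg.rs_premix, ph=cfg.ph,
                                temperature=cfg.temperature)
            k_exp = kobs1_closed_form(k, op)
            times = np.linspace(0.0, 5.0 / k_exp, cfg.n_points)
            init = initial_state(cfg.heme_total, no, cfg.rs_premix, alpha, heme_form="Fe3_RS")
            init[0] = cfg.heme_total * (1.0 - f_bound)  # Fe3_H2O
            init[1] = cfg.heme_total * f_bound  # Fe3_RS
            series = simulate(mech, k, init, times)
            tr = absorbance_trace(series, times, cfg.epsilons, no=no, rs_total=cfg.rs_premix,
                                  ph=cfg.ph, temperature=cfg.temperature,
                                  heme_total=cfg.heme_total)
            amp = np.ptp(tr.absorbance)
            tr.absorbance = _noisy(rng, tr.absorbance, cfg.noise * amp)
            tr.meta["pathway"] = 1
            traces.append(tr)
        return traces

    # pathway 2: premix nitrosylation equilibrium
    Keq_no = k.k_on_NO / k.k_off_NO if k.k_off_NO > 0 else np.inf
    f_nitros = (
        1.0 if np.isinf(Keq_no)
        else (Keq_no * cfg.no_premix) / (1.0 + Keq_no * cfg.no_premix)
    )
    for rs_t in cfg.rs_grid:
        op = OperatingPoint(no=cfg.no_premix, rs_total=rs_t, ph=cfg.ph,
                            temperature=cfg.temperature)
        k_exp = kobs2_from_constants(k, op, alpha)
        times = np.linspace(0.0, 5.0 / k_exp, cfg.n_points)
        init = initial_state(cfg.heme_total, cfg.no_premix, rs_t, alpha, heme_form="Fe2_NOplus")
        init[0] = cfg.heme_total * (1.0 - f_nitros)
        init[2] = cfg.heme_total * f_nitros
        series = simulate(mech, k, init, times)
        tr = absorbance_trace(series, times, cfg.epsilons, no=cfg.no_premix, rs_total=rs_t,
                              ph=cfg.ph, temperature=cfg.temperature, heme_total=cfg.heme_total)
        amp = np.ptp(tr.absorbance)
        tr.absorbance = _noisy(rng, tr.absorbance, cfg.noise * amp)
        tr.meta["pathway"] = 2
        traces.append(tr)
    return traces


def make_titration(cfg: ScenarioConfig, n_points: int = 10, max_total: float = 2e-3) -> TitrationSeries:
    """Equilibrium 413 nm titration of the nitrosyl complex with thiol.

    Generated with the product step switched off (true binding equilibrium):
    the bound fraction follows the 1:1 isotherm in free thiolate.  Binding
    drains the *total* thiol pool (the protonated reservoir rebuffers the
    thiolate), so depletion is modelled on the total scale with the apparent
    constant K*alpha.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    k = cfg.rate_constants
    K = k.k_on_RSminus / k.k_off_RSminus  # thiolate-scale binding constant
    alpha = cfg.alpha()
    total = np.concatenate([[0.0], np.geomspace(max_total / 30.0, max_total, n_points - 1)])
    k_tot = K * alpha  # apparent constant on the total-thiol scale
    free = np.where(total > 0, _free_ligand(total, k_tot, cfg.heme_total), 0.0)
    f_bound = k_tot * free / (1.0 + k_tot * free)
    a0 = cfg.epsilons["Fe2_NOplus"] * cfg.heme_total
    ainf = cfg.epsilons["I1"] * cfg.heme_total
    a = a0 + (ainf - a0) * f_bound
    a = _noisy(rng, a, cfg.noise * abs(ainf - a0))
    return TitrationSeries(
        ligand=total, absorbance=a, ligand_scale="total", ph=cfg.ph,
        temperature=cfg.temperature, no=cfg.no_premix, heme_total=cfg.heme_total,
        meta={"true_K": K, "seed": cfg.seed},
    )


def make_kobs_tables(cfg: ScenarioConfig, kinds: tuple[str, ...] = ("RS_T", "NO", "inverse_H", "inverse_T")) -> dict[str, KobsDataset]:
    """Closed-form-generated observed-rate datasets for fast regression tests.

    ``inverse_T`` produces the forward (association) ladder from the
    scenario's activation parameters; a second entry ``inverse_T_back`` holds
    the dissociation ladder.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    k = cfg.rate_constants
    alpha = cfg.alpha()
    out: dict[str, KobsDataset] = {}
    for kind in kinds:
        if kind == "RS_T":
            x = np.array(cfg.rs_grid)
            y = np.array([
                kobs2_from_constants(k, OperatingPoint(no=cfg.no_premix, rs_total=v,
                                                       ph=cfg.ph, temperature=cfg.temperature),
                                     alpha)
                for v in x
            ])
            y = _noisy(rng, y, cfg.noise * y.mean())
            out[kind] = KobsDataset(x, y, None, "RS_T", ph=cfg.ph,
                                    temperature=cfg.temperature, no=cfg.no_premix)
        elif kind == "NO":
            x = np.array(cfg.no_grid)
            y = np.array([
                kobs1_closed_form(k, OperatingPoint(no=v, rs_total=cfg.rs_premix,
                                                    ph=cfg.ph, temperature=cfg.temperature))
                for v in x
            ])
            y = _noisy(rng, y, cfg.noise * y.mean())
            out[kind] = KobsDataset(x, y, None, "NO", ph=cfg.ph,
                                    temperature=cfg.temperature, no=np.nan)
        elif kind == "inverse_H":
            ph = np.array(cfg.ph_grid)
            x = 10.0**ph  # 1/[H+]
            k_app = k.k_on_RSminus * np.array([
                thiolate_fraction(cfg.protonation, p, cfg.temperature) for p in ph
            ])
            k_app = _noisy(rng, k_app, cfg.noise * k_app.mean())
            ds = KobsDataset(x, k_app, None, "inverse_H", ph=np.nan,
                             temperature=cfg.temperature, no=cfg.no_premix)
            ds.meta["ph_values"] = tuple(ph)
            out[kind] = ds
        elif kind == "inverse_T":
            T = np.array([celsius_to_kelvin(c) for c in cfg.temp_grid_C])
            for tag, dh, ds_ in (("inverse_T", cfg.dH_fwd, cfg.dS_fwd),
                                 ("inverse_T_back", cfg.dH_back, cfg.dS_back)):
                y = np.array([eyring_rate(dh, ds_, t) for t in T])
                y = _noisy(rng, y, cfg.noise * y)  # heteroscedastic: relative noise
                out[tag] = KobsDataset(T, y, None, "inverse_T", ph=cfg.ph,
                                       temperature=np.nan, no=cfg.no_premix)
        else:
            raise ValueError(f"unknown dataset kind {kind!r}")
    return out


def manifest(cfg: ScenarioConfig) -> dict:
    """Ground-truth record written next to generated datasets."""
    from dataclasses import asdict

    return {
        "seed": cfg.seed,
        "thiol": cfg.thiol,
        "rate_constants": asdict(cfg.rate_constants),
        "non_published_placeholders": ["k_on_RS", "k_off_RS", "k2"],
        "pKa": cfg.protonation.pka_by_temperature,
        "noise": cfg.noise,
        "heme_total": cfg.heme_total,
        "activation": {
            "forward": {"dH_kJ_mol": cfg.dH_fwd, "dS_J_mol_K": cfg.dS_fwd},
            "back": {"dH_kJ_mol": cfg.dH_back, "dS_J_mol_K": cfg.dS_back},
        },
    }
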