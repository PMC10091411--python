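"""Thiol acid-base speciation and apparent/intrinsic rate-constant conversion.

Only the thiolate anion RS- attacks the electrophilic Fe2+(NO+) centre, so a
rate constant measured against the *total* thiol pool at a given pH (an
"apparent" constant) understates the intrinsic thiolate-specific constant by
the deprotonated fraction

    alpha(pH) = 1 / (1 + 10**(pKa - pH)).

Conversions between the two scales are exact inverses of each other.  In the
acidic regime [H+] >> Ka the apparent constant reduces to
k_intrinsic * Ka / [H+], which is the linearisation exploited by the
1/[H+] regression in :mod:`snokin.regressions`.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class MissingPKaError(KeyError):
    """No pKa is tabulated at the requested temperature."""


@dataclass(frozen=True)
class ProtonationModel:
    """Temperature-resolved pKa table for one thiol.

    Parameters
    ----------
    pka_by_temperature:
        Mapping of temperature (K) to pKa. Ships with the two measured
        5 degC values for N-acetylcysteine (9.95) and glutathione (9.32);
        users supply their own table for other conditions.
    thiol:
        Identity tag, e.g. ``"GSH"``, ``"Cys"``, ``"AcCys"`` or a custom name.
    interpolate:
        Allow linear interpolation of pKa between tabulated temperatures.
        Off by default: extrapolating thermochemistry is the user's call.
    """

    pka_by_temperature: dict[float, float] = field(default_factory=dict)
    thiol: str = "custom"
    interpolate: bool = False

    def __post_init__(self) -> None:
        if not self.pka_by_temperature:
            raise ValueError("pKa table must be non-empty")
        for t, pka in self.pka_by_temperature.items():
            if not 5.0 < pka < 13.0:
                raise ValueError(f"pKa {pka} at T={t} K outside plausible thiol range (5, 13)")

    def pka(self, temperature: float) -> float:
        table = self.pka_by_temperature
        # exact hit, with a small tolerance for float round-trip of Celsius
        for t, v in table.items():
            if abs(t - temperature) < 1e-6:
                return v
        if not self.interpolate:
            raise MissingPKaError(
                f"no pKa for {self.thiol} at T={temperature} K "
                f"(tabulated: {sorted(table)}); enable interpolation or extend the table"
            )
        ts = sorted(table)
        if temperature < ts[0] or temperature > ts[-1]:
            raise MissingPKaError(
                f"T={temperature} K outside tabulated range [{ts[0]}, {ts[-1]}] for {self.thiol}"
            )
        import numpy as np

        return float(np.interp(temperature, ts, [table[t] for t in ts]))


T5C = 278.15

#: Measured 5 degC pKa values for the two thiols with quantified kinetics.
ACCYS_5C = ProtonationModel({T5C: 9.95}, thiol="AcCys")
GSH_5C = ProtonationModel({T5C: 9.32}, thiol="GSH")


def thiolate_fraction(model: ProtonationModel, ph: float, temperature: float = T5C) -> float:
    """Deprotonated fraction alpha = 1/(1 + 10**(pKa - pH)) in [0, 1]."""
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH {ph} outside (0, 14)")
    pka = model.pka(temperature)
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def apparent_to_intrinsic(
    k_apparent: float, model: ProtonationModel, ph: float, temperature: float = T5C
) -> float:
    """Thiolate-specific constant from one measured against the total pool.

    k_intrinsic = k_apparent / alpha(pH, T).
    """
    if k_apparent < 0:
        raise ValueError("rate constant must be >= 0")
    alpha = thiolate_fraction(model, ph, temperature)
    if alpha == 0.0:
        raise ZeroDivisionError("thiolate fraction is zero; conversion undefined")
    return k_apparent / alpha


def intrinsic_to_apparent(
    k_intrinsic: float, model: ProtonationModel, ph: float, temperature: float = T5C
) -> float:
    """Inverse of :func:`apparent_to_intrinsic`; round-trips to machine precision."""
    if k_intrinsic < 0:
        raise ValueError("rate constant must be >= 0")
    return k_intrinsic * thiolate_fraction(model, ph, temperature)
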