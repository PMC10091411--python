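"""Physical constants and unit helpers.

All concentrations are mol/L, times in seconds, temperatures in kelvin
internally; configuration files may state temperatures in Celsius and are
converted on load.
"""

# Gas constant, J mol^-1 K^-1
R = 8.314

# Boltzmann/Planck ratio k_B/h, K^-1 s^-1 (Eyring pre-factor)
KB_OVER_H = 2.0837e10

# Kelvin offset
T0_C = 273.15

# Diffusion-controlled ceiling for second-order rate constants, M^-1 s^-1
DIFFUSION_LIMIT = 1.0e10


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + T0_C


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - T0_C
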