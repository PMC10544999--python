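"""Physical constants and unit conversions.

The package works in the spectroscopist's mixed unit system: energies and
wavenumbers in cm^-1, time in fs, transition dipoles in Debye, distances in
Angstrom.  A phase ``omega * t`` is therefore ``TWO_PI_C * nu_cm1 * t_fs``.
"""

# speed of light in cm/fs
C_CM_PER_FS = 2.99792458e-5

# 2*pi*c: converts (cm^-1 * fs) products to radians
TWO_PI_C = 2.0 * 3.141592653589793 * C_CM_PER_FS

# Boltzmann constant in cm^-1 / K
KB_CM1 = 0.6950348004

DEFAULT_TEMPERATURE = 300.0  # K


def thermal_energy(temperature: float) -> float:
    """k_B * T in cm^-1."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return KB_CM1 * temperature
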