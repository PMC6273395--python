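"""Physical constants and unit conversions.

The internal unit system is Angstrom / femtosecond / electronvolt / amu.
Energies are eV everywhere inside the package; Hartree is accepted at user
interfaces (the decoherence parameter alpha is conventionally quoted in
Hartree) and converted on entry.
"""

# hbar in eV * fs
HBAR_EV_FS = 0.6582119569

# 1 eV expressed in amu * Angstrom^2 / fs^2  (kinetic-energy conversion)
EV_TO_AMU_AA_FS = 0.009648533212

# 1 Hartree in eV
HARTREE_TO_EV = 27.211386245988

# speed of light in cm / fs (for wavenumber -> angular frequency)
C_CM_FS = 2.99792458e-5

import math


def wavenumber_to_angular_fs(wavenumber_cm: float) -> float:
    """Convert a vibrational wavenumber (cm^-1) to angular frequency (rad/fs)."""
    return 2.0 * math.pi * C_CM_FS * wavenumber_cm


# hbar in amu * Angstrom^2 / fs (= HBAR_EV_FS * EV_TO_AMU_AA_FS)
HBAR_AMU_AA_FS = HBAR_EV_FS * EV_TO_AMU_AA_FS
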