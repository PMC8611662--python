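"""Physical constants and unit conversions.

All Hamiltonian terms inside the package are held in angular frequency
(rad s^-1).  Couplings are accepted from users in MHz or mT and converted
once, at construction time.
"""

import math

#: Bohr magneton (J T^-1), CODATA 2018.
MU_B = 9.2740100783e-24

#: Planck constant (J s), exact (SI 2019).
H_PLANCK = 6.62607015e-34

#: Reduced Planck constant (J s).
HBAR = H_PLANCK / (2.0 * math.pi)

#: Vacuum permeability (T m A^-1), CODATA 2018.
MU_0 = 1.25663706212e-6

#: Isotropic g-value used for organic radicals (close to the free electron).
G_ELECTRON = 2.0023

#: Electron gyromagnetic conversion for g = 2.0023: hyperfine couplings
#: quoted in mT are multiplied by this to obtain MHz.  Pinned in one place.
MHZ_PER_MT = 28.0249514242

#: rad s^-1 per MHz.
RAD_PER_MHZ = 2.0 * math.pi * 1e6

#: metres per angstrom.
M_PER_ANGSTROM = 1e-10


def mt_to_mhz(value_mt: float) -> float:
    """Convert a coupling from millitesla to MHz (g = 2.0023 convention)."""
    return value_mt * MHZ_PER_MT


def mhz_to_angular(value_mhz: float) -> float:
    """Convert a coupling from MHz to angular frequency (rad s^-1)."""
    return value_mhz * RAD_PER_MHZ


def larmor_frequency_hz(b0_tesla: float, g: float = G_ELECTRON) -> float:
    """Electron Larmor frequency g*mu_B*B0/h in Hz.

    At the geomagnetic 50 uT and g = 2.0023 this is about 1.4 MHz.
    """
    return g * MU_B * b0_tesla / H_PLANCK
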