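"""Physical constants and unit conversions.

External units follow MD-file conventions: lengths in Å, times in fs,
masses in amu, temperatures in K.  The spectral axis is reported in
wavenumbers (cm⁻¹).  Dipole/magnetic tensors are treated in arbitrary
consistent units, so spectra are arbitrary-unit; only positions, signs
and ratios of bands are physically meaningful.
"""

from __future__ import annotations

import scipy.constants as _c

#: Boltzmann constant in amu·Å²/fs²/K (1 amu·Å²/fs² = 1.66054e-17 J)
KB_AMU_A2_FS2 = _c.k / (_c.atomic_mass * 1e-10**2 / 1e-15**2)

#: Speed of light in cm/fs — converts a frequency in fs⁻¹ to cm⁻¹ via f/c.
C_CM_FS = _c.c * 100.0 * 1e-15

#: Speed of light in atomic units (dimensionless fine-structure inverse).
C_AU = 1.0 / _c.fine_structure

#: Bohr radius in Å.
BOHR_A = _c.physical_constants["Bohr radius"][0] * 1e10

#: Second radiation constant h·c/k_B in cm·K: βℏω = C2_CM_K * (ν̃/T).
C2_CM_K = _c.h * _c.c * 100.0 / _c.k


def wavenumber_to_angular_fs(nu_cm: float) -> float:
    """Convert a wavenumber ν̃ (cm⁻¹) to angular frequency ω (rad/fs)."""
    return 2.0 * _c.pi * C_CM_FS * nu_cm


def angular_fs_to_wavenumber(omega: float) -> float:
    """Convert an angular frequency ω (rad/fs) to wavenumber ν̃ (cm⁻¹)."""
    return omega / (2.0 * _c.pi * C_CM_FS)


#: Standard atomic masses (amu) for the elements this package meets in
#: practice; extend as needed.  Values from CODATA/IUPAC 2021 rounding.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "D": 2.014, "He": 4.0026,
    "Li": 6.94, "Be": 9.0122, "B": 10.81, "C": 12.011, "N": 14.007,
    "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085,
    "P": 30.974, "S": 32.06, "Cl": 35.45, "Ar": 39.948,
    "K": 39.098, "Ca": 40.078, "Fe": 55.845, "Cu": 63.546,
    "Zn": 65.38, "Br": 79.904, "I": 126.90,
    # single-letter placeholders used by synthetic fixtures
    "X": 1.0,
}


def mass_of(element: str) -> float:
    """Standard atomic mass (amu) of an element symbol.

    Raises ``KeyError`` with a helpful message for unknown symbols.
    """
    try:
        return ATOMIC_MASSES[element]
    except KeyError:
        raise KeyError(
            f"unknown element symbol {element!r}; add it to awv.units.ATOMIC_MASSES"
        ) from None
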