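"""Physical constants and unit conversions (Hartree atomic units throughout).

All tensors in this package are stored in atomic units; conversions to and
from laboratory units happen only at I/O boundaries.
"""

#: Speed of light in atomic units (inverse fine-structure constant).
C_AU: float = 137.035999084

#: Length conversion: 1 nm expressed in Bohr radii.
NM_TO_BOHR: float = 18.897261246

TWO_PI = 6.283185307179586


def omega_from_wavelength_nm(wavelength_nm: float) -> float:
    """Angular frequency (a.u.) of light with the given vacuum wavelength.

    omega = 2*pi*c / lambda, with c and lambda both in atomic units.
    """
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    return TWO_PI * C_AU / (wavelength_nm * NM_TO_BOHR)


def wavelength_nm_from_omega(omega: float) -> float:
    """Vacuum wavelength (nm) for an angular frequency in atomic units."""
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    return TWO_PI * C_AU / (omega * NM_TO_BOHR)
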