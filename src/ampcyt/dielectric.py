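"""Single-shell dielectric model of suspended particles.

A biological cell in suspension is modelled as a conductive sphere
(cytoplasm) covered by a thin, poorly conducting shell (membrane).  The
shelled sphere is reduced to an equivalent homogeneous sphere whose complex
permittivity reproduces the same induced dipole, and the impedance signal of
a particle is proportional to its volume times the Clausius-Mossotti factor,
i.e. the dielectric contrast between the equivalent particle and the
suspending medium.  At low stimulation frequency an intact membrane makes
the cell behave as an insulator (the signal probes cell volume); at high
frequency the membrane is capacitively shorted and the signal probes the
cytoplasm interior.

All radii are expressed in micrometres and membrane thicknesses in
nanometres; conductivities in S/m, relative permittivities dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateInputError, InvalidArgumentError

#: Vacuum permittivity, F/m.
EPS0 = 8.8541878128e-12


@dataclass(frozen=True)
class Medium:
    """Suspending electrolyte.

    Parameters
    ----------
    conductivity : float
        Electrical conductivity, S/m. Must be positive.
    relative_permittivity : float
        Relative permittivity. Must be positive.
    """

    conductivity: float
    relative_permittivity: float

    def __post_init__(self) -> None:
        if self.conductivity <= 0:
            raise InvalidArgumentError("medium conductivity must be > 0")
        if self.relative_permittivity <= 0:
            raise InvalidArgumentError("medium relative permittivity must be > 0")

    def complex_permittivity(self, frequency: float) -> complex:
        return complex_permittivity(self.conductivity, self.relative_permittivity, frequency)


@dataclass(frozen=True)
class Bead:
    """Homogeneous insulating reference bead (polystyrene)."""

    diameter_um: float = 4.5
    conductivity: float = 1e-6
    rel_permittivity: float = 2.55

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise InvalidArgumentError("bead diameter must be > 0")
        if self.conductivity < 0 or self.rel_permittivity <= 0:
            raise InvalidArgumentError("bead dielectric parameters out of range")


@dataclass(frozen=True)
class ShellCell:
    """Single-shell description of a cell: cytoplasm sphere + membrane shell.

    Parameters
    ----------
    radius_um : float
        Outer radius (including the membrane), micrometres.
    membrane_thickness_nm : float
        Shell thickness, nanometres; must be much smaller than the radius.
    membrane_conductivity, cytoplasm_conductivity : float
        S/m, non-negative.
    membrane_rel_permittivity, cytoplasm_rel_permittivity : float
        Dimensionless, positive.
    """

    radius_um: float
    membrane_thickness_nm: float
    membrane_conductivity: float
    membrane_rel_permittivity: float
    cytoplasm_conductivity: float
    cytoplasm_rel_permittivity: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise InvalidArgumentError("cell radius must be > 0")
        if self.membrane_thickness_nm <= 0:
            raise InvalidArgumentError("membrane thickness must be > 0")
        if self.membrane_thickness_nm * 1e-3 >= self.radius_um:
            raise InvalidArgumentError("membrane thickness must be smaller than the radius")
        if self.membrane_conductivity < 0 or self.cytoplasm_conductivity < 0:
            raise InvalidArgumentError("conductivities must be >= 0")
        if self.membrane_rel_permittivity <= 0 or self.cytoplasm_rel_permittivity <= 0:
            raise InvalidArgumentError("relative permittivities must be > 0")

    @property
    def diameter_um(self) -> float:
        return 2.0 * self.radius_um


def complex_permittivity(conductivity: float, rel_permittivity: float, frequency: float) -> complex:
    """Complex permittivity eps* = eps0*eps_r - j*sigma/(2*pi*f).

    The imaginary part is non-positive (passive, lossy material).
    """
    if frequency <= 0:
        raise InvalidArgumentError("frequency must be > 0")
    return EPS0 * rel_permittivity - 1j * conductivity / (2.0 * np.pi * frequency)


def shelled_sphere_permittivity(cell: ShellCell, frequency: float) -> complex:
    """Equivalent homogeneous complex permittivity of a shelled sphere.

    With gamma = R_outer / R_inner and Delta the Clausius-Mossotti contrast
    between cytoplasm and membrane material,

        eps_eq* = eps_mem* * (gamma^3 + 2*Delta) / (gamma^3 - Delta).

    The equivalent sphere has the same induced dipole as the layered one.
    """
    r_out = cell.radius_um
    r_in = r_out - cell.membrane_thickness_nm * 1e-3
    if r_in <= 0:
        raise InvalidArgumentError("membrane thickness must be smaller than the radius")
    e_mem = complex_permittivity(
        cell.membrane_conductivity, cell.membrane_rel_permittivity, frequency
    )
    e_cyt = complex_permittivity(
        cell.cytoplasm_conductivity, cell.cytoplasm_rel_permittivity, frequency
    )
    gamma3 = (r_out / r_in) ** 3
    delta = (e_cyt - e_mem) / (e_cyt + 2.0 * e_mem)
    return e_mem * (gamma3 + 2.0 * delta) / (gamma3 - delta)


def clausius_mossotti(particle_permittivity: complex, medium_permittivity: complex) -> complex:
    """Clausius-Mossotti dipole factor (eps_p* - eps_m*)/(eps_p* + 2*eps_m*).

    For passive materials the factor lies between -0.5 (insulating particle
    in a conductive medium) and +1.0 (highly conductive particle).
    """
    den = particle_permittivity + 2.0 * medium_permittivity
    scale = abs(particle_permittivity) + abs(medium_permittivity)
    if scale == 0 or abs(den) < 1e-12 * scale:
        raise DegenerateInputError("Clausius-Mossotti denominator vanishes")
    return (particle_permittivity - medium_permittivity) / den


def particle_permittivity(particle: "Bead | ShellCell", frequency: float) -> complex:
    """Complex permittivity of a bead or equivalent permittivity of a cell."""
    if isinstance(particle, Bead):
        return complex_permittivity(particle.conductivity, particle.rel_permittivity, frequency)
    if isinstance(particle, ShellCell):
        return shelled_sphere_permittivity(particle, frequency)
    raise InvalidArgumentError(f"unsupported particle model: {type(particle).__name__}")


def particle_diameter_um(particle: "Bead | ShellCell") -> float:
    return particle.diameter_um
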