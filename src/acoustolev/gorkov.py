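"""Gor'kov potential and acoustic radiation force.

For a compressible sphere much smaller than the wavelength the
time-averaged radiation force is F = -grad(U) with

    U = V * [ f1 * <p^2> / (2 rho_m c^2)  -  f2 * (3/4) * rho_m * <v^2> ],

where V is the particle volume, <.> the time average (|.|^2 / 2 for
complex amplitudes under e^{-i omega t}), and the scattering
(contrast) coefficients are

    f1 = 1 - kappa_p / kappa_m,
    f2 = 2 (rho_p - rho_m) / (2 rho_p + rho_m).

In a planar standing wave p = P cos(kz) this reduces to the classical
F_z = 4 pi Phi k a^3 E_ac sin(2kz) with Phi = f1/3 + f2/2 and
E_ac = P^2 / (4 rho c^2); that closed form is used as the oracle in
the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .device import Material, ParticleSpec
from .helmholtz import AcousticField, node_plane

__all__ = [
    "ContrastFactors",
    "PotentialField",
    "ForceField",
    "contrast_factors",
    "gorkov_potential",
    "radiation_force",
    "unit_force_comparison",
    "make_planar_standing_wave",
]


@dataclass(frozen=True)
class ContrastFactors:
    f1: float
    f2: float

    @property
    def phi(self) -> float:
        """Planar standing-wave contrast factor f1/3 + f2/2."""
        return self.f1 / 3 + self.f2 / 2


def contrast_factors(particle: ParticleSpec, medium: Material) -> ContrastFactors:
    """Monopole (f1) and dipole (f2) scattering coefficients."""
    f1 = 1.0 - particle.compressibility / medium.compressibility
    f2 = 2.0 * (particle.density - medium.density) / (
        2.0 * particle.density + medium.density
    )
    return ContrastFactors(f1=f1, f2=f2)


@dataclass
class PotentialField:
    """Gor'kov potential U [J] on the acoustic-field grid."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    U: np.ndarray
    particle: ParticleSpec
    source: AcousticField | None = field(default=None, repr=False)


@dataclass
class ForceField:
    """Radiation force F = -grad(U) [N] on the grid; F has shape (3, ...)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    F: np.ndarray
    particle: ParticleSpec
    potential: PotentialField | None = field(default=None, repr=False)

    @property
    def Fz(self) -> np.ndarray:
        return self.F[2]


def gorkov_potential(field: AcousticField, particle: ParticleSpec) -> PotentialField:
    """Evaluate U pointwise on the field grid.

    Warns when the particle radius exceeds lambda/10, the nominal
    validity limit of the long-wavelength (Rayleigh) scattering model.
    """
    lam = 2 * np.pi * field.medium.sound_speed / field.omega
    if particle.radius > lam / 10:
        warnings.warn(
            f"particle radius {particle.radius:.2e} m exceeds lambda/10 "
            f"({lam / 10:.2e} m); Gor'kov model marginal", stacklevel=2
        )
    cf = contrast_factors(particle, field.medium)
    rho, c = field.medium.density, field.medium.sound_speed
    p2 = 0.5 * np.abs(field.p) ** 2                 # <p^2>
    v2 = 0.5 * np.sum(np.abs(field.v) ** 2, axis=0)  # <v.v>
    U = particle.volume * (
        cf.f1 * p2 / (2 * rho * c**2) - cf.f2 * 0.75 * rho * v2
    )
    return PotentialField(x=field.x, y=field.y, z=field.z, U=U,
                          particle=particle, source=field)


def radiation_force(potential: PotentialField) -> ForceField:
    """F = -grad(U), central differences (one-sided at boundaries)."""
    grad = np.gradient(potential.U, potential.x, potential.y, potential.z)
    F = -np.stack(grad)
    return ForceField(x=potential.x, y=potential.y, z=potential.z, F=F,
                      particle=potential.particle, potential=potential)


def _class_units(tmap) -> dict[str, list[tuple[float, float]]]:
    """Unit centers by symmetry class, restricted to the x,y >= 0 quadrant."""
    classes: dict[str, list[tuple[float, float]]] = {
        "center": [], "edge": [], "corner": []
    }
    rows, cols = tmap.array_shape
    for i in range(rows):
        for j in range(cols):
            cx, cy = tmap.unit_center(i, j)
            if cx < 0 or cy < 0:
                continue
            n_center = (i == (rows - 1) // 2) + (j == (cols - 1) // 2)
            label = {2: "center", 1: "edge", 0: "corner"}[n_center]
            classes[label].append((cx, cy))
    return classes


def unit_force_comparison(field: AcousticField, particle: ParticleSpec,
                          z_window: float | None = None) -> pd.DataFrame:
    """Max vertical radiation force above each unit class, plus ratios.

    For every center/edge/corner unit, |F_z| is evaluated along the
    vertical line through the unit center and its maximum taken inside
    a +/- lambda/8 window around that unit's pressure node — the
    standing-wave force peak above the unit, the quantity per-unit
    force profiles report.  The class value is the maximum over its
    units; the table carries the class maxima and center/class ratios.
    """
    if field.tmap is None:
        raise ValueError("field must carry its transducer map")
    tmap = field.tmap
    pot = gorkov_potential(field, particle)
    force = radiation_force(pot)
    lam = 2 * np.pi * field.medium.sound_speed / field.omega
    if z_window is None:
        z_window = lam / 8

    from scipy.interpolate import RegularGridInterpolator
    fz_interp = RegularGridInterpolator((field.x, field.y, field.z),
                                        force.Fz, bounds_error=True)
    rows = []
    for label, centers in _class_units(tmap).items():
        best = 0.0
        node = None
        for cx, cy in centers:
            nd = node_plane(field, cx, cy)
            if nd is None:
                continue
            zs = np.linspace(max(field.z[0], nd - z_window),
                             min(field.z[-1], nd + z_window), 256)
            prof = np.abs(fz_interp(np.column_stack(
                [np.full_like(zs, cx), np.full_like(zs, cy), zs])))
            if prof.max() > best:
                best = float(prof.max())
                node = nd
        rows.append({"unit_class": label, "max_vertical_force": best,
                     "node_z": node})
    df = pd.DataFrame(rows).set_index("unit_class")
    center = df.loc["center", "max_vertical_force"]
    df["center_ratio"] = center / df["max_vertical_force"]
    return df.reset_index()


def make_planar_standing_wave(P: float, f: float, medium: Material,
                              h: float, nz: int = 401, nx: int = 3,
                              ny: int = 3, lateral: float = 1e-3) -> AcousticField:
    """Analytic planar standing wave p = P cos(kz), uniform laterally.

    Reference field for validating the Gor'kov implementation against
    the closed-form radiation force; not a chamber solution.
    """
    omega = 2 * np.pi * f
    rho, c = medium.density, medium.sound_speed
    k = omega / c
    x = np.linspace(0, lateral, nx)
    y = np.linspace(0, lateral, ny)
    z = np.linspace(0, h, nz)
    p1d = P * np.cos(k * z)
    vz1d = -P * k * np.sin(k * z) / (1j * omega * rho)
    p = np.broadcast_to(p1d, (nx, ny, nz)).astype(complex)
    v = np.zeros((3, nx, ny, nz), dtype=complex)
    v[2] = np.broadcast_to(vz1d, (nx, ny, nz))
    return AcousticField(x=x, y=y, z=z, p=p.copy(), v=v, omega=omega,
                         medium=medium, quarter=False)
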