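"""Closed-form 1D driven acoustic column.

A piston at z=0 oscillates with displacement amplitude D at angular
frequency omega (time convention e^{-i omega t} throughout the
package); the lid at z=h is an impedance boundary Z_top.  The pressure
is p(z) = A e^{ikz} + B e^{-ikz} with

* bottom: dp/dz|_0 = rho omega^2 D    (piston velocity -i omega D),
* top:    p(h) = Z_top * u_z(h),      u = dp/dz / (i omega rho).

This is the vertical-standing-wave physics of the levitation chamber
reduced to one dimension; it serves both as a fast node-height
predictor and as the analytic oracle for the 3D solver.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .device import Material

__all__ = [
    "ColumnSolution",
    "solve_column",
    "node_positions",
    "max_pressure",
    "resonance_sweep",
    "ResonanceError",
]

#: impedance at or above this value is treated as numerically rigid
RIGID = 1e12


class ResonanceError(ArithmeticError):
    """Singular column (lossless resonance); add a loss factor."""


@dataclass(frozen=True)
class ColumnSolution:
    """Two-wave solution p(z) = A e^{ikz} + B e^{-ikz} on [0, h]."""

    A: complex
    B: complex
    k: complex
    height: float
    medium: Material
    omega: float

    def pressure(self, z):
        z = np.asarray(z, dtype=float)
        return self.A * np.exp(1j * self.k * z) + self.B * np.exp(-1j * self.k * z)

    def velocity(self, z):
        """Axial acoustic velocity u_z = (dp/dz)/(i omega rho)."""
        z = np.asarray(z, dtype=float)
        dpdz = 1j * self.k * (
            self.A * np.exp(1j * self.k * z) - self.B * np.exp(-1j * self.k * z)
        )
        return dpdz / (1j * self.omega * self.medium.density)


def solve_column(h: float, medium: Material, bottom_displacement: float,
                 Z_top: float, f: float, loss_factor: float = 0.0) -> ColumnSolution:
    """Solve the driven column for coefficients A, B.

    Parameters
    ----------
    h : fluid height [m]
    medium : acoustic medium
    bottom_displacement : piston displacement amplitude D [m]
    Z_top : lid impedance [Pa s/m]; >= 1e12 acts rigid, -> 0 is a free surface
    f : drive frequency [Hz]
    loss_factor : dimensionless imaginary part added to k (k -> k(1 + i*lf/2))
        to regularise exact lossless resonances.
    """
    if h <= 0 or f <= 0 or bottom_displacement < 0:
        raise ValueError("h, f must be > 0 and displacement >= 0")
    omega = 2 * np.pi * f
    rho, c = medium.density, medium.sound_speed
    k = (omega / c) * (1 + 0.5j * loss_factor)
    zeta = Z_top * k / (omega * rho)  # = Z_top/(rho c) for lossless k

    # rows: bottom piston BC; top impedance BC  p(h) - Z u(h) = 0
    eikh = np.exp(1j * k * h)
    M = np.array(
        [
            [1j * k, -1j * k],
            [eikh * (1 - zeta), (1 + zeta) / eikh],
        ],
        dtype=complex,
    )
    rhs = np.array([rho * omega**2 * bottom_displacement, 0.0], dtype=complex)
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    scale = np.abs(M).max() ** 2
    if scale == 0 or abs(det) < 1e-12 * scale:
        raise ResonanceError(
            "column is at an (anti)resonance of the lossless system; "
            "pass loss_factor > 0 to regularise"
        )
    A, B = np.linalg.solve(M, rhs)
    return ColumnSolution(A=complex(A), B=complex(B), k=complex(k),
                          height=h, medium=medium, omega=omega)


def _parabolic_refine(z: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex of the parabola through (z[i-1..i+1], y[i-1..i+1])."""
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom <= 0:
        return float(z[i])
    shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
    return float(z[i] + shift * (z[i + 1] - z[i]))


def node_positions(sol: ColumnSolution, resolution: float,
                   min_modulation: float = 0.01) -> list[float]:
    """Interior local minima of |p(z)| (pressure nodes), ascending.

    A minimum is only reported if it sits at least ``min_modulation``
    below the global |p| maximum — a matched (travelling-wave) column
    has constant |p| and yields no nodes.
    """
    if not resolution < sol.height / 10:
        raise ValueError("resolution must be finer than h/10")
    n = max(int(np.ceil(sol.height / resolution)) + 1, 32)
    z = np.linspace(0.0, sol.height, n)
    mag = np.abs(sol.pressure(z))
    pmax = mag.max()
    if pmax == 0:
        return []
    out = []
    for i in range(1, n - 1):
        if mag[i] <= mag[i - 1] and mag[i] < mag[i + 1]:
            if mag[i] < (1 - min_modulation) * pmax:
                out.append(_parabolic_refine(z, mag, i))
    return sorted(out)


def max_pressure(sol: ColumnSolution, n: int = 8193) -> float:
    """max_z |p(z)| over [0, h] by dense sampling + parabolic refinement."""
    z = np.linspace(0.0, sol.height, n)
    mag = np.abs(sol.pressure(z))
    i = int(np.argmax(mag))
    if 0 < i < n - 1:
        zv = _parabolic_refine(z, -mag, i)
        return float(max(mag[i], abs(sol.pressure(zv))))
    return float(mag[i])


class SweepResult(NamedTuple):
    table: pd.DataFrame          # columns: frequency, max_pressure
    peak_frequency: float


def resonance_sweep(h: float, medium: Material, D: float, Z_top: float,
                    f_range, n: int = 201) -> SweepResult:
    """Frequency response max|p|(f) over ``f_range`` = (f_lo, f_hi)."""
    f_lo, f_hi = f_range
    if not (0 < f_lo < f_hi <= 5e6):
        raise ValueError("f_range must lie within (0, 5 MHz)")
    freqs = np.linspace(f_lo, f_hi, n)
    amps = np.array([
        max_pressure(solve_column(h, medium, D, Z_top, f), n=2049)
        for f in freqs
    ])
    table = pd.DataFrame({"frequency": freqs, "max_pressure": amps})
    i = int(np.argmax(amps))
    f_peak = freqs[i]
    if 0 < i < n - 1:
        f_peak = _parabolic_refine(freqs, -amps, i)
    return SweepResult(table=table, peak_frequency=float(f_peak))
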