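"""Overdamped spheroid dynamics in the radiation-force field.

A spheroid of radius a in the low-viscosity hydrogel precursor has a
momentum relaxation time 2 a^2 rho_p / (9 mu) of order a millisecond,
far shorter than the seconds-scale transport, so inertia is dropped:

    dx/dt = F_net(x) / (6 pi mu a),

with F_net the trilinear-interpolated radiation force plus the
buoyancy-corrected weight (rho_m - rho_p) V g z_hat.  The fluid is
quiescent (no streaming or bulk flow).  Positions are clipped to the
chamber interior; a particle resting on the floor may later be lifted
when the acoustic force exceeds its net weight.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq

from .device import Material, ParticleSpec, DomainError
from .gorkov import ForceField

__all__ = [
    "Trajectory",
    "net_force",
    "simulate_trajectory",
    "equilibrium_height",
    "trap_positions",
    "NoEquilibriumError",
    "G",
]

G = 9.81  # m/s^2


class NoEquilibriumError(RuntimeError):
    """No vertical force balance exists on this column (not levitatable)."""


@dataclass
class Trajectory:
    times: np.ndarray        # s, strictly increasing
    positions: np.ndarray    # (n, 3) m
    converged: bool

    @property
    def terminal_position(self) -> np.ndarray:
        return self.positions[-1]


def _force_interpolators(field: ForceField):
    interps = getattr(field, "_interps", None)
    if interps is None:
        interps = [
            RegularGridInterpolator((field.x, field.y, field.z), field.F[i],
                                    bounds_error=True)
            for i in range(3)
        ]
        field._interps = interps
    return interps


def buoyant_weight(particle: ParticleSpec, medium: Material,
                   g: float = G) -> float:
    """Signed vertical body force (rho_m - rho_p) V g; negative = sinks."""
    return (medium.density - particle.density) * particle.volume * g


def net_force(particle: ParticleSpec, position, force_field: ForceField | None,
              medium: Material, g: float = G) -> np.ndarray:
    """Radiation force (trilinear) + buoyancy-corrected weight at a point."""
    pos = np.asarray(position, dtype=float)
    out = np.zeros(3)
    if force_field is not None:
        try:
            fi = _force_interpolators(force_field)
            out[:] = [fi[i](pos).item() for i in range(3)]
        except ValueError as exc:
            raise DomainError(f"position {pos} outside field domain") from exc
    out[2] += buoyant_weight(particle, medium, g)
    return out


def simulate_trajectory(particle: ParticleSpec, start, force_field: ForceField,
                        medium: Material, viscosity: float = 1e-3,
                        dt: float = 1e-4, t_end: float = 10.0,
                        position_tolerance: float = 1e-8,
                        g: float = G) -> Trajectory:
    """Integrate the overdamped equation of motion from ``start``.

    Adaptive explicit stepping: the step is shrunk so no single move
    exceeds a quarter of the local grid spacing.  Integration stops
    early once the step displacement falls below
    ``position_tolerance`` [m] (converged trap/floor position).

    The explicit scheme is stable near a trap when
    dt < 2 * (6 pi mu a) / |dF_z/dz|; the 0.1 ms default leaves a
    factor ~5 margin for the stock chamber fields.
    """
    if dt <= 0 or viscosity <= 0:
        raise ValueError("dt and viscosity must be > 0")
    gamma = 6 * np.pi * viscosity * particle.radius
    a = particle.radius
    lo = np.array([force_field.x[0], force_field.y[0], force_field.z[0] + a])
    hi = np.array([force_field.x[-1], force_field.y[-1], force_field.z[-1] - a])
    max_step = 0.25 * min(
        np.diff(force_field.x).min(),
        np.diff(force_field.y).min(),
        np.diff(force_field.z).min(),
    )
    pos = np.clip(np.asarray(start, dtype=float), lo, hi)
    t = 0.0
    times = [t]
    path = [pos.copy()]
    converged = False
    while t < t_end:
        F = net_force(particle, pos, force_field, medium, g)
        if not np.all(np.isfinite(F)):
            raise ArithmeticError(f"non-finite force at position {pos}")
        vel = F / gamma
        speed = float(np.linalg.norm(vel))
        step = dt if speed * dt <= max_step else max_step / speed
        step = min(step, t_end - t)
        new = np.clip(pos + vel * step, lo, hi)
        t += step
        moved = float(np.linalg.norm(new - pos))
        pos = new
        times.append(t)
        path.append(pos.copy())
        if moved < position_tolerance * (step / dt if step < dt else 1.0):
            converged = True
            break
    return Trajectory(times=np.array(times), positions=np.array(path),
                      converged=converged)


def _vertical_net(particle, force_field, medium, x, y, g):
    fi = _force_interpolators(force_field)
    w = buoyant_weight(particle, medium, g)

    def f(z):
        return fi[2]([x, y, z]).item() + w

    return f


def equilibrium_height(particle: ParticleSpec, force_field: ForceField,
                       medium: Material, x: float, y: float,
                       g: float = G, xtol: float = 1e-7) -> float:
    """Levitation height: root of net vertical force nearest below the node.

    The vertical profile of F_z + buoyant weight is scanned on a fine
    grid; the sign change whose root lies highest (the equilibrium just
    below the pressure node for a denser-than-fluid particle) is
    bracketed and solved by bisection to ``xtol`` (default 0.1 um).
    """
    f = _vertical_net(particle, force_field, medium, x, y, g)
    zgrid = np.linspace(force_field.z[0], force_field.z[-1], 512)
    vals = np.array([f(z) for z in zgrid])
    sign = np.sign(vals)
    # descending stable crossings: f > 0 below, f < 0 above
    idx = np.nonzero((sign[:-1] > 0) & (sign[1:] <= 0))[0]
    if len(idx) == 0:
        raise NoEquilibriumError(
            f"no stable vertical force balance on column ({x}, {y})"
        )
    i = idx[-1]
    return float(brentq(f, zgrid[i], zgrid[i + 1], xtol=xtol))


def trap_positions(force_field: ForceField, particle: ParticleSpec | None = None,
                   min_depth: float = 1e-3) -> list[tuple[float, float, float]]:
    """Lateral acoustic traps: local minima of U on the node plane.

    The Gor'kov potential is sliced at the height of its vertical
    minimum above the domain center and, for quarter-domain fields,
    mirrored to the full plane.  A grid point is a trap if it is a
    strict 2D local minimum and sits at least ``min_depth`` of the
    slice's dynamic range below the slice maximum; a laterally uniform
    field therefore reports no traps.
    """
    pot = force_field.potential
    if pot is None:
        raise ValueError("force field must carry its potential")
    U = pot.U
    # vertical index of the potential minimum above the domain origin column
    kz = int(np.argmin(U[0, 0, :])) if pot.source is None or pot.source.quarter \
        else int(np.argmin(U[len(pot.x) // 2, len(pot.y) // 2, :]))
    slab = U[:, :, kz]
    x, y = pot.x, pot.y
    if pot.source is not None and pot.source.quarter:
        from .helmholtz import mirror_axis
        slab, x = mirror_axis(slab, x, axis=0)
        slab, y = mirror_axis(slab, y, axis=1)
    rng = float(slab.max() - slab.min())
    if rng <= 0 or rng < min_depth * max(abs(slab).max(), 1e-300):
        return []
    traps = []
    for i in range(1, slab.shape[0] - 1):
        for j in range(1, slab.shape[1] - 1):
            c = slab[i, j]
            neigh = [slab[i - 1, j], slab[i + 1, j], slab[i, j - 1], slab[i, j + 1]]
            if all(c < nb for nb in neigh) and (slab.max() - c) > min_depth * rng:
                traps.append((float(x[i]), float(y[j]), float(pot.z[kz])))
    return traps
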