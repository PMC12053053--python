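"""Chamber, materials and transducer-array description.

The device is a fluid-filled levitation chamber driven from below by a
diced 3x3 piezoelectric (PZT) array embedded in epoxy.  The bottom
boundary is described by a piecewise-constant normal-displacement map
(nm per volt of drive), the lid and side walls by acoustic impedances.
Two stock configurations are provided:

* model A -- every PZT unit vibrates with the same amplitude
  (1.15 nm/V, epoxy 0.6 nm/V);
* model B -- amplitude depends on array position (center 1.7, edge 1.2,
  corner 1.0 nm/V), mimicking the edge effect of a real array.

All quantities are stored in SI units (m, kg, s, Pa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "Material",
    "TransducerMap",
    "ChamberConfig",
    "ParticleSpec",
    "make_material",
    "water",
    "model_A_config",
    "model_B_config",
    "displacement_at",
    "ValidationError",
    "DomainError",
]


class ValidationError(ValueError):
    """Raised when a physical parameter fails its validity check."""


class DomainError(ValueError):
    """Raised when a query point lies outside the modelled domain."""


@dataclass(frozen=True)
class Material:
    """Acoustic medium: density rho [kg/m^3] and sound speed c [m/s].

    Compressibility kappa = 1/(rho c^2) [1/Pa] and characteristic
    impedance Z = rho c [Pa s/m] are derived on construction.
    """

    name: str
    density: float
    sound_speed: float

    def __post_init__(self) -> None:
        if not self.density > 0:
            raise ValidationError(f"density must be > 0, got {self.density}")
        if not self.sound_speed > 0:
            raise ValidationError(
                f"sound_speed must be > 0, got {self.sound_speed}"
            )

    @property
    def compressibility(self) -> float:
        return 1.0 / (self.density * self.sound_speed**2)

    @property
    def impedance(self) -> float:
        return self.density * self.sound_speed


def make_material(name: str, density: float, sound_speed: float) -> Material:
    """Build a :class:`Material` from density [kg/m^3] and c [m/s]."""
    return Material(name=name, density=density, sound_speed=sound_speed)


def water() -> Material:
    """Water at 25 degC; also stands in for the >80%-water hydrogel precursor."""
    return make_material("water", 1000.0, 1480.0)


@dataclass(frozen=True)
class TransducerMap:
    """Piecewise-constant bottom displacement map of the PZT array.

    ``displacement_per_volt`` maps region labels ``"unit(i,j)"`` (row i,
    column j, 0-based) and ``"epoxy"`` to nm/V.  The array is centered
    on the chamber origin; unit (i, j) is centered at
    ``((j - (cols-1)/2) * pitch, (i - (rows-1)/2) * pitch)``.
    The map is real (all regions in phase): a single sinusoidal drive.
    """

    array_shape: tuple[int, int] = (3, 3)
    unit_size: float = 2.0e-3
    pitch: float = 2.4e-3
    displacement_per_volt: dict[str, float] = field(default_factory=dict)
    drive_voltage: float = 60.0
    frequency: float = 660e3

    def __post_init__(self) -> None:
        if self.unit_size > self.pitch:
            raise ValidationError("unit_size must not exceed pitch")
        if not self.frequency > 0:
            raise ValidationError("frequency must be > 0")
        if self.drive_voltage < 0:
            raise ValidationError("drive_voltage must be >= 0")
        for label, dpv in self.displacement_per_volt.items():
            if dpv < 0:
                raise ValidationError(
                    f"displacement_per_volt[{label!r}] must be >= 0"
                )
        if "epoxy" not in self.displacement_per_volt:
            raise ValidationError("displacement map must define 'epoxy'")

    @property
    def footprint(self) -> float:
        """Lateral extent of the array (outer edge to outer edge), m."""
        n = max(self.array_shape)
        return (n - 1) * self.pitch + self.unit_size

    def unit_center(self, i: int, j: int) -> tuple[float, float]:
        rows, cols = self.array_shape
        cx = (j - (cols - 1) / 2) * self.pitch
        cy = (i - (rows - 1) / 2) * self.pitch
        return cx, cy

    def region_label(self, x: float, y: float) -> str:
        """Label of the region containing (x, y): a unit or 'epoxy'."""
        rows, cols = self.array_shape
        half = self.unit_size / 2
        for i in range(rows):
            for j in range(cols):
                cx, cy = self.unit_center(i, j)
                if abs(x - cx) <= half and abs(y - cy) <= half:
                    return f"unit({i},{j})"
        return "epoxy"

    def displacement_amplitude(self, x: float, y: float) -> float:
        """Displacement amplitude [m] at drive_voltage for point (x, y)."""
        label = self.region_label(x, y)
        dpv = self.displacement_per_volt.get(
            label, self.displacement_per_volt["epoxy"]
        )
        return dpv * 1e-9 * self.drive_voltage


@dataclass(frozen=True)
class ChamberConfig:
    """Fluid chamber: lateral box, fluid column height, wall impedances.

    "Rigid" walls are modelled with a large finite impedance
    (>= 1e12 Pa s/m).  ``symmetry`` flags mirror planes at x=0 and y=0
    used for quarter-domain solves.
    """

    lateral_size: tuple[float, float] = (10e-3, 10e-3)
    fluid_height: float = 1.1e-3
    fluid: Material = field(default_factory=water)
    top_impedance: float = 13e6
    side_impedance: float = 17e6
    symmetry: tuple[bool, bool] = (True, True)

    def __post_init__(self) -> None:
        if not self.fluid_height > 0:
            raise ValidationError("fluid_height must be > 0")
        if self.top_impedance <= 0 or self.side_impedance <= 0:
            raise ValidationError(
                "impedances must be > 0 (use >=1e12 for rigid walls)"
            )
        if self.lateral_size[0] <= 0 or self.lateral_size[1] <= 0:
            raise ValidationError("lateral_size must be > 0")

    def contains(self, x: float, y: float) -> bool:
        Lx, Ly = self.lateral_size
        return abs(x) <= Lx / 2 and abs(y) <= Ly / 2

    def validate_against(self, tmap: TransducerMap) -> None:
        Lx, Ly = self.lateral_size
        if min(Lx, Ly) < tmap.footprint:
            raise ValidationError(
                "chamber lateral size smaller than transducer array footprint"
            )


@dataclass(frozen=True)
class ParticleSpec:
    """Small compressible sphere (spheroid stand-in).

    Default density 1099 kg/m^3 and compressibility 4.0e-10 1/Pa are
    tissue-like values for fixed cell spheroids.
    """

    radius: float
    density: float = 1099.0
    compressibility: float = 4.0e-10

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValidationError("radius must be > 0")
        if not self.density > 0:
            raise ValidationError("density must be > 0")
        if not self.compressibility > 0:
            raise ValidationError("compressibility must be > 0")

    @property
    def volume(self) -> float:
        return (4.0 / 3.0) * math.pi * self.radius**3


def _grid_map(rows: int, cols: int, values: dict[str, float],
              epoxy: float) -> dict[str, float]:
    out = {"epoxy": epoxy}
    out.update(values)
    return out


def model_A_config() -> tuple[ChamberConfig, TransducerMap]:
    """Uniform-drive configuration: every PZT unit at 1.15 nm/V.

    60 V, 660 kHz, 1.1 mm fluid column, glass lid 13 MPa s/m,
    aluminium side walls 17 MPa s/m.
    """
    values = {f"unit({i},{j})": 1.15 for i in range(3) for j in range(3)}
    tmap = TransducerMap(
        array_shape=(3, 3),
        unit_size=2.0e-3,
        pitch=2.4e-3,
        displacement_per_volt=_grid_map(3, 3, values, epoxy=0.6),
        drive_voltage=60.0,
        frequency=660e3,
    )
    chamber = ChamberConfig()
    chamber.validate_against(tmap)
    return chamber, tmap


def model_B_config() -> tuple[ChamberConfig, TransducerMap]:
    """Position-dependent drive: center 1.7, edge 1.2, corner 1.0 nm/V.

    Mirrors the measured edge effect of the array; all other settings
    as in :func:`model_A_config`.
    """
    values = {}
    for i in range(3):
        for j in range(3):
            n_center = (i == 1) + (j == 1)
            dpv = {2: 1.7, 1: 1.2, 0: 1.0}[n_center]
            values[f"unit({i},{j})"] = dpv
    tmap = TransducerMap(
        array_shape=(3, 3),
        unit_size=2.0e-3,
        pitch=2.4e-3,
        displacement_per_volt=_grid_map(3, 3, values, epoxy=0.6),
        drive_voltage=60.0,
        frequency=660e3,
    )
    chamber = ChamberConfig()
    chamber.validate_against(tmap)
    return chamber, tmap


def displacement_at(tmap: TransducerMap, x: float, y: float,
                    chamber: ChamberConfig | None = None) -> float:
    """Bottom-boundary displacement amplitude [m] at (x, y).

    Piecewise constant: drive_voltage times the nm/V value of the
    containing region; points outside every unit footprint take the
    epoxy value.  If ``chamber`` is given, points outside its footprint
    raise :class:`DomainError`.
    """
    if chamber is not None and not chamber.contains(x, y):
        raise DomainError(f"point ({x}, {y}) outside chamber footprint")
    return tmap.displacement_amplitude(x, y)
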