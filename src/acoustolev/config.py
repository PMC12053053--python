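"""INI-style configuration files with mandatory units.

Sections: [chamber], [transducer], [drive], [particle].  Every
dimensional entry carries an explicit unit suffix ("1.1 mm",
"660 kHz", "13 MPa*s/m"); values are converted to SI on load.
"""

from __future__ import annotations

import configparser
from pathlib import Path

from .device import (ChamberConfig, Material, ParticleSpec, TransducerMap,
                     ValidationError, make_material)

__all__ = ["parse_quantity", "load_config", "example_config", "LoadedConfig"]

_UNITS = {
    # length
    "m": 1.0, "mm": 1e-3, "um": 1e-6, "µm": 1e-6, "μm": 1e-6, "nm": 1e-9,
    # frequency
    "Hz": 1.0, "kHz": 1e3, "MHz": 1e6,
    # electric / mechanical
    "V": 1.0, "Pa": 1.0, "MPa": 1e6,
    "kg/m^3": 1.0, "m/s": 1.0,
    "Pa*s": 1.0, "mPa*s": 1e-3,
    "Pa*s/m": 1.0, "MPa*s/m": 1e6,
    "nm/V": 1e-9, "1/Pa": 1.0,
    "1": 1.0,
}


def parse_quantity(text: str) -> float:
    """Parse "VALUE UNIT" into SI; the unit token is mandatory."""
    parts = text.strip().split()
    if len(parts) != 2:
        raise ValidationError(
            f"expected 'value unit', got {text!r} (units are mandatory)"
        )
    value, unit = parts
    if unit not in _UNITS:
        raise ValidationError(f"unknown unit {unit!r} in {text!r}")
    return float(value) * _UNITS[unit]


class LoadedConfig:
    """Bundle of the four configured objects plus free-form extras."""

    def __init__(self, chamber: ChamberConfig, tmap: TransducerMap,
                 particle: ParticleSpec, extras: dict):
        self.chamber = chamber
        self.tmap = tmap
        self.particle = particle
        self.extras = extras


def _get(cp, section, key, default=None):
    if cp.has_option(section, key):
        return parse_quantity(cp.get(section, key))
    if default is None:
        raise ValidationError(f"missing [{section}] {key}")
    return default


def load_config(path: str | Path) -> LoadedConfig:
    """Read a platform configuration file (see :func:`example_config`)."""
    cp = configparser.ConfigParser()
    read = cp.read(str(path))
    if not read:
        raise FileNotFoundError(path)

    fluid: Material = make_material(
        "fluid",
        _get(cp, "chamber", "fluid_density", 1000.0),
        _get(cp, "chamber", "fluid_sound_speed", 1480.0),
    )
    chamber = ChamberConfig(
        lateral_size=(_get(cp, "chamber", "lateral_size_x", 10e-3),
                      _get(cp, "chamber", "lateral_size_y", 10e-3)),
        fluid_height=_get(cp, "chamber", "fluid_height", 1.1e-3),
        fluid=fluid,
        top_impedance=_get(cp, "chamber", "top_impedance", 13e6),
        side_impedance=_get(cp, "chamber", "side_impedance", 17e6),
    )

    rows = cp.getint("transducer", "rows", fallback=3)
    cols = cp.getint("transducer", "cols", fallback=3)
    dpv = {"epoxy": _get(cp, "transducer", "epoxy_displacement", 0.6e-9) / 1e-9}
    if cp.has_option("transducer", "unit_displacement"):
        u = _get(cp, "transducer", "unit_displacement") / 1e-9
        for i in range(rows):
            for j in range(cols):
                dpv[f"unit({i},{j})"] = u
    else:
        center = _get(cp, "transducer", "center_displacement", 1.7e-9) / 1e-9
        edge = _get(cp, "transducer", "edge_displacement", 1.2e-9) / 1e-9
        corner = _get(cp, "transducer", "corner_displacement", 1.0e-9) / 1e-9
        for i in range(rows):
            for j in range(cols):
                n_center = (i == (rows - 1) // 2) + (j == (cols - 1) // 2)
                dpv[f"unit({i},{j})"] = {2: center, 1: edge, 0: corner}[n_center]
    tmap = TransducerMap(
        array_shape=(rows, cols),
        unit_size=_get(cp, "transducer", "unit_size", 2e-3),
        pitch=_get(cp, "transducer", "pitch", 2.4e-3),
        displacement_per_volt=dpv,
        drive_voltage=_get(cp, "drive", "voltage", 60.0),
        frequency=_get(cp, "drive", "frequency", 660e3),
    )
    chamber.validate_against(tmap)

    particle = ParticleSpec(
        radius=_get(cp, "particle", "diameter", 150e-6) / 2,
        density=_get(cp, "particle", "density", 1099.0),
        compressibility=_get(cp, "particle", "compressibility", 4.0e-10),
    )
    extras = {
        "viscosity": _get(cp, "particle", "viscosity", 1e-3),
    }
    return LoadedConfig(chamber, tmap, particle, extras)


def example_config(model: str = "A") -> str:
    """Text of a complete configuration file for stock model A or B."""
    if model.upper() == "A":
        trans = "unit_displacement = 1.15 nm/V"
    else:
        trans = ("center_displacement = 1.7 nm/V\n"
                 "edge_displacement = 1.2 nm/V\n"
                 "corner_displacement = 1.0 nm/V")
    return f"""[chamber]
lateral_size_x = 10 mm
lateral_size_y = 10 mm
fluid_height = 1.1 mm
fluid_density = 1000 kg/m^3
fluid_sound_speed = 1480 m/s
top_impedance = 13 MPa*s/m
side_impedance = 17 MPa*s/m

[transducer]
rows = 3
cols = 3
unit_size = 2 mm
pitch = 2.4 mm
{trans}
epoxy_displacement = 0.6 nm/V

[drive]
voltage = 60 V
frequency = 660 kHz

[particle]
diameter = 150 um
density = 1099 kg/m^3
compressibility = 4.0e-10 1/Pa
viscosity = 1 mPa*s
"""
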