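"""Synthetic spheroid populations and height measurements.

Emulates the statistical structure of cross-section height data from
the levitation platform so the analysis stage can be exercised without
wet-lab measurements:

* spheroid diameters: truncated Gaussian (+-3 sd);
* sedimented heights: spheroid radius plus floor-roughness offset,
  with occasional stacking (a second spheroid's diameter added) and
  wall adhesion (height uniform over the well depth), plus
  measurement noise — the three artifacts seen in sedimented wells;
* levitated heights: node height plus a per-block Gaussian offset
  (frame-height inhomogeneity between hydrogel blocks) plus
  per-spheroid jitter, independent of diameter.

Named presets reproduce the study populations: sedimented HepG2-140
(~150 +- 105 um), levitated HepG2-140 (510 +- 50), HepG2-340
(500 +- 80) and HCT-140 (475 +- 55).  All generators are
bit-reproducible given (seed, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .device import ParticleSpec, ValidationError

__all__ = [
    "HeightSample",
    "ArtifactParams",
    "gen_population",
    "gen_sedimented_heights",
    "gen_levitated_heights",
    "generate_preset",
    "samples_to_frame",
    "PRESETS",
    "CHAMBER_HEIGHT_UM",
]

CHAMBER_HEIGHT_UM = 1100.0


@dataclass(frozen=True)
class HeightSample:
    """One measured spheroid: center-of-mass height above the PZT plane."""

    height_um: float
    diameter_um: float
    group: str
    block: int = 0

    def __post_init__(self):
        if not 0 <= self.height_um <= CHAMBER_HEIGHT_UM:
            raise ValidationError("height outside chamber")
        if not self.diameter_um > 0:
            raise ValidationError("diameter must be > 0")


@dataclass(frozen=True)
class ArtifactParams:
    """Sedimentation artifact model (all length scales in um)."""

    floor_roughness_sd: float = 60.0
    stacking_probability: float = 0.15
    wall_adhesion_probability: float = 0.03
    measurement_noise_sd: float = 5.0
    block_offset_sd: float = 0.0

    def __post_init__(self):
        for name in ("floor_roughness_sd", "measurement_noise_sd",
                     "block_offset_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("stacking_probability", "wall_adhesion_probability"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")


def gen_population(n: int, mean_diameter_um: float, sd_diameter_um: float,
                   density: float = 1099.0, seed: int = 0,
                   compressibility: float = 4.0e-10) -> list[ParticleSpec]:
    """Draw n spheroids with truncated-Gaussian diameters (+-3 sd)."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    if sd_diameter_um < 0 or (sd_diameter_um > 0
                              and mean_diameter_um <= 3 * sd_diameter_um):
        raise ValidationError("need mean > 3*sd >= 0 to avoid negative draws")
    rng = np.random.default_rng(seed)
    if sd_diameter_um == 0:
        diam = np.full(n, mean_diameter_um)
    else:
        diam = truncnorm.rvs(-3, 3, loc=mean_diameter_um,
                             scale=sd_diameter_um, size=n, random_state=rng)
    return [ParticleSpec(radius=d / 2 * 1e-6, density=density,
                         compressibility=compressibility) for d in diam]


def gen_sedimented_heights(pop: list[ParticleSpec], params: ArtifactParams,
                           seed: int = 0, group: str = "sedimented",
                           chamber_height_um: float = CHAMBER_HEIGHT_UM,
                           ) -> list[HeightSample]:
    """Heights after passive sedimentation with floor/stacking/wall artifacts."""
    if not pop:
        raise ValidationError("population is empty")
    rng = np.random.default_rng(seed)
    n = len(pop)
    radii = np.array([p.radius for p in pop]) * 1e6
    diam = 2 * radii
    H = radii + np.abs(rng.normal(0.0, params.floor_roughness_sd, n)) \
        if params.floor_roughness_sd > 0 else radii.copy()
    stacked = rng.random(n) < params.stacking_probability
    H[stacked] += diam[rng.integers(0, n, size=int(stacked.sum()))]
    on_wall = rng.random(n) < params.wall_adhesion_probability
    H[on_wall] = rng.uniform(radii[on_wall], chamber_height_um - radii[on_wall])
    if params.measurement_noise_sd > 0:
        H += rng.normal(0.0, params.measurement_noise_sd, n)
    H = np.clip(H, 0.0, chamber_height_um)
    return [HeightSample(height_um=float(h), diameter_um=float(d),
                         group=group, block=0)
            for h, d in zip(H, diam)]


def gen_levitated_heights(pop: list[ParticleSpec], node_height_um: float,
                          block_offset_sd: float, spheroid_jitter_sd: float,
                          n_blocks: int = 1, seed: int = 0,
                          group: str = "levitated",
                          chamber_height_um: float = CHAMBER_HEIGHT_UM,
                          ) -> list[HeightSample]:
    """Heights after acoustic levitation to the node plane.

    Spheroids are assigned round-robin to ``n_blocks`` hydrogel blocks;
    each block carries one Gaussian height offset (sd
    ``block_offset_sd``) shared by its spheroids, on top of which each
    spheroid gets independent Gaussian jitter.  Heights do not depend
    on diameter: at force balance the levitation plane is
    size-independent.
    """
    if not pop:
        raise ValidationError("population is empty")
    if n_blocks < 1:
        raise ValidationError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    offsets = rng.normal(0.0, block_offset_sd, n_blocks)
    n = len(pop)
    blocks = np.arange(n) % n_blocks
    H = node_height_um + offsets[blocks] + rng.normal(0.0, spheroid_jitter_sd, n)
    H = np.clip(H, 0.0, chamber_height_um)
    return [HeightSample(height_um=float(h),
                         diameter_um=float(2e6 * p.radius),
                         group=group, block=int(b))
            for h, p, b in zip(H, pop, blocks)]


@dataclass(frozen=True)
class _Preset:
    group: str
    n: int
    mean_diameter_um: float
    sd_diameter_um: float
    mode: str                       # "sedimented" | "levitated"
    artifacts: ArtifactParams | None = None
    node_height_um: float = 0.0
    block_offset_sd: float = 0.0
    spheroid_jitter_sd: float = 0.0
    n_blocks: int = 1


#: Study populations: group sizes and dispersion as measured on the platform.
PRESETS: dict[str, _Preset] = {
    "HepG2-140-sedimented": _Preset(
        group="HepG2-140-sedimented", n=220, mean_diameter_um=140,
        sd_diameter_um=10, mode="sedimented",
        artifacts=ArtifactParams(floor_roughness_sd=60.0,
                                 stacking_probability=0.15,
                                 wall_adhesion_probability=0.03,
                                 measurement_noise_sd=5.0)),
    "HepG2-340-sedimented": _Preset(
        group="HepG2-340-sedimented", n=76, mean_diameter_um=340,
        sd_diameter_um=40, mode="sedimented",
        artifacts=ArtifactParams(floor_roughness_sd=50.0,
                                 stacking_probability=0.07,
                                 wall_adhesion_probability=0.01,
                                 measurement_noise_sd=5.0)),
    "HepG2-140-levitated": _Preset(
        group="HepG2-140-levitated", n=285, mean_diameter_um=140,
        sd_diameter_um=10, mode="levitated", node_height_um=510,
        block_offset_sd=30.0, spheroid_jitter_sd=40.0, n_blocks=4),
    "HepG2-340-levitated": _Preset(
        group="HepG2-340-levitated", n=45, mean_diameter_um=340,
        sd_diameter_um=40, mode="levitated", node_height_um=500,
        block_offset_sd=30.0, spheroid_jitter_sd=74.0, n_blocks=3),
    "HCT-140-levitated": _Preset(
        group="HCT-140-levitated", n=155, mean_diameter_um=140,
        sd_diameter_um=15, mode="levitated", node_height_um=475,
        block_offset_sd=30.0, spheroid_jitter_sd=46.0, n_blocks=3),
}


def generate_preset(name: str, seed: int = 0, n: int | None = None,
                    node_height_um: float | None = None) -> list[HeightSample]:
    """Generate one named study population (optionally resized/recentered)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    p = PRESETS[name]
    if n is not None:
        p = replace(p, n=n)
    if node_height_um is not None:
        p = replace(p, node_height_um=node_height_um)
    pop = gen_population(p.n, p.mean_diameter_um, p.sd_diameter_um, seed=seed)
    if p.mode == "sedimented":
        return gen_sedimented_heights(pop, p.artifacts, seed=seed + 1,
                                      group=p.group)
    return gen_levitated_heights(pop, p.node_height_um, p.block_offset_sd,
                                 p.spheroid_jitter_sd, p.n_blocks,
                                 seed=seed + 1, group=p.group)


def samples_to_frame(samples: list[HeightSample]) -> pd.DataFrame:
    """CSV-ready table: group, block, diameter_um, height_um."""
    return pd.DataFrame({
        "group": [s.group for s in samples],
        "block": [s.block for s in samples],
        "diameter_um": [s.diameter_um for s in samples],
        "height_um": [s.height_um for s in samples],
    })
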