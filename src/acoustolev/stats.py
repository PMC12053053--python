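"""Alignment statistics for spheroid height distributions.

The primary readout of the platform is the height H of each spheroid's
center of mass above the transducer plane.  This module fits Gaussians
to per-group height samples, derives slab-coverage metrics (the
thickness of the central slab holding a given fraction of a Gaussian
population), compares groups with the two-sample Kolmogorov-Smirnov
test on cumulative frequencies, and provides the circularity shape
metric 4 pi A / P^2 used on segmented cross-sections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .device import ValidationError
from .synth import HeightSample

__all__ = [
    "GaussianFit",
    "PopulationStats",
    "fit_gaussian",
    "central_interval_width",
    "fraction_within_slab",
    "empirical_fraction_within_slab",
    "ks_two_sample",
    "misalignment",
    "circularity",
    "group_report",
    "DegenerateFitError",
]

#: combined-size threshold below which the exact KS null distribution is used
_KS_EXACT_LIMIT = 25


class DegenerateFitError(ValueError):
    """Sample is constant; a Gaussian fit is undefined."""


class GaussianFit(NamedTuple):
    mean: float
    sd: float
    goodness: float   # one-sample KS distance of data to the fitted Gaussian


@dataclass(frozen=True)
class PopulationStats:
    group: str
    n: int
    mean: float
    sd: float
    thickness_70: float
    goodness: float


def fit_gaussian(heights: Sequence[float], min_n: int = 8) -> GaussianFit:
    """Maximum-likelihood Gaussian fit (sample mean, n-1 SD) + KS goodness."""
    x = np.asarray(heights, dtype=float)
    if len(x) < min_n:
        raise ValidationError(f"need at least {min_n} samples, got {len(x)}")
    mu = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise DegenerateFitError("constant data: Gaussian fit is degenerate")
    d = float(sps.kstest(x, "norm", args=(mu, sd)).statistic)
    return GaussianFit(mean=mu, sd=sd, goodness=d)


def central_interval_width(sd: float, coverage: float = 0.70) -> float:
    """Width of the central interval of N(mu, sd) holding ``coverage``.

    2 * sd * Phi^-1((1 + coverage) / 2); for coverage 0.70 this is
    2 * 1.0364 * sd — the "thickness containing 70% of the spheroids".
    """
    if not 0 < coverage < 1:
        raise ValidationError("coverage must lie in (0, 1)")
    if sd < 0:
        raise ValidationError("sd must be >= 0")
    return 2.0 * sd * float(sps.norm.ppf((1 + coverage) / 2))


def fraction_within_slab(mean: float, sd: float, thickness: float) -> float:
    """Gaussian probability mass inside the slab of ``thickness`` centered at mean."""
    if thickness < 0:
        raise ValidationError("thickness must be >= 0")
    if sd == 0:
        return 1.0 if thickness > 0 else 0.0
    return float(2 * sps.norm.cdf(thickness / (2 * sd)) - 1)


def empirical_fraction_within_slab(heights: Sequence[float],
                                   thickness: float) -> float:
    """Largest fraction of samples covered by any slab of ``thickness``."""
    x = np.sort(np.asarray(heights, dtype=float))
    if len(x) == 0:
        raise ValidationError("empty sample")
    j = np.searchsorted(x, x + thickness, side="right")
    return float((j - np.arange(len(x))).max() / len(x))


class KSResult(NamedTuple):
    statistic: float
    pvalue: float


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test.

    D = sup |ECDF_x - ECDF_y|; the p-value uses the asymptotic
    Kolmogorov distribution with effective size n1 n2/(n1+n2), or the
    exact null distribution when the combined size is below 25.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    method = "exact" if len(x) + len(y) < _KS_EXACT_LIMIT else "asymp"
    r = sps.ks_2samp(x, y, method=method)
    return KSResult(statistic=float(r.statistic), pvalue=float(r.pvalue))


def misalignment(stats_a: PopulationStats, stats_b: PopulationStats) -> float:
    """Absolute offset of the fitted population centers, |mu_A - mu_B|."""
    return abs(stats_a.mean - stats_b.mean)


def circularity(area: float, perimeter: float) -> float:
    """4 pi A / P^2; 1 for a circle, < 1 for any other planar shape."""
    if area <= 0 or perimeter <= 0:
        raise ValidationError("area and perimeter must be > 0")
    return 4 * np.pi * area / perimeter**2


def group_report(samples: Sequence[HeightSample], coverage: float = 0.70,
                 min_n: int = 8) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group Gaussian fits + pairwise KS comparison matrix.

    Groups with fewer than ``min_n`` samples are flagged
    (``fitted = False``) and excluded from fits and comparisons.
    Returns (stats table, long-format pairwise table of D and p).
    """
    by_group: dict[str, list[float]] = {}
    for s in samples:
        by_group.setdefault(s.group, []).append(s.height_um)
    if not by_group:
        raise ValidationError("no samples")
    rows = []
    fitted: dict[str, np.ndarray] = {}
    for g, hs in by_group.items():
        if len(hs) < min_n:
            rows.append({"group": g, "n": len(hs), "mean": np.nan,
                         "sd": np.nan, "thickness_70": np.nan,
                         "goodness": np.nan, "fitted": False})
            continue
        fit = fit_gaussian(hs, min_n=min_n)
        rows.append({
            "group": g, "n": len(hs), "mean": fit.mean, "sd": fit.sd,
            "thickness_70": central_interval_width(fit.sd, coverage),
            "goodness": fit.goodness, "fitted": True,
        })
        fitted[g] = np.asarray(hs)
    stats_df = pd.DataFrame(rows)
    pairs = []
    names = list(fitted)
    for i, ga in enumerate(names):
        for gb in names[i:]:
            if ga == gb:
                d, p = 0.0, 1.0
            else:
                d, p = ks_two_sample(fitted[ga], fitted[gb])
            pairs.append({"group_a": ga, "group_b": gb,
                          "ks_statistic": d, "ks_pvalue": p})
    return stats_df, pd.DataFrame(pairs)
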