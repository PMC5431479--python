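"""Population descriptors of a microglia point pattern.

Covers nearest-neighbour distances with the regularity index
RI = mean(NND)/sd(NND), global density, eccentricity profiles relative to
the optic nerve head, the Bland–Altman percentage agreement statistic used
to validate automated counts, and the red→blue NND pseudocolour map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .patterns import PointPattern

#: Clark–Evans expected regularity index of a Poisson process,
#: (1/2)·sqrt(4π/(4−π)) ≈ 1.9131
CLARK_EVANS_POISSON_RI = 0.5 * np.sqrt(4 * np.pi / (4 - np.pi))


@dataclass
class NNDSummary:
    """Per-point nearest-neighbour distances and their regularity index."""

    nnds: np.ndarray  # μm
    mean_um: float
    sd_um: float
    ri: float  # mean/sd; NaN when sd == 0 (flagged by warning)

    @property
    def ri_defined(self) -> bool:
        return np.isfinite(self.ri)


def nearest_neighbour_distances(
    pattern: PointPattern, ddof: int = 1
) -> NNDSummary:
    """Each point's Euclidean distance to its nearest other point, with the
    population mean, standard deviation (sample, ddof=1 by default) and
    regularity index."""
    if pattern.n < 2:
        raise ValueError("need at least 2 points for NND")
    d, _ = cKDTree(pattern.points).query(pattern.points, k=2)
    nnds = d[:, 1]
    mean = float(nnds.mean())
    sd = float(nnds.std(ddof=ddof))
    if sd == 0.0:
        warnings.warn("NND standard deviation is zero: RI undefined",
                      stacklevel=2)
        ri = np.nan
    else:
        ri = mean / sd
    return NNDSummary(nnds=nnds, mean_um=mean, sd_um=sd, ri=ri)


def global_density(pattern: PointPattern, area_mm2: float | None = None) -> float:
    """Total count divided by retinal area, in cells/mm².

    ``area_mm2`` defaults to the window polygon area.
    """
    if area_mm2 is None:
        area_mm2 = pattern.area_mm2
    if area_mm2 <= 0:
        raise ValueError("area must be positive")
    return pattern.n / area_mm2


@dataclass
class EccentricityProfile:
    """Binned percentage frequency of distance-to-ONH, d = √((x−a)²+(y−b)²)."""

    onh_um: tuple[float, float]
    bin_width_um: float
    bin_edges_um: np.ndarray  # len nbins+1
    counts: np.ndarray
    pct: np.ndarray  # sums to 100
    cum_pct: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start_um": self.bin_edges_um[:-1],
                "bin_end_um": self.bin_edges_um[1:],
                "count": self.counts,
                "pct": self.pct,
                "cum_pct": self.cum_pct,
            }
        )


def eccentricity_profile(
    pattern: PointPattern,
    onh_um: tuple[float, float],
    bin_width_um: float = 50.0,
) -> EccentricityProfile:
    """Percentage frequency distribution of each cell's distance to the
    optic nerve head centre (a, b), binned at ``bin_width_um`` (default
    50 μm), with its cumulative curve. Percentages use the retina's total
    cell count as denominator."""
    if pattern.n == 0:
        raise ValueError("empty pattern")
    a, b = onh_um
    import shapely

    if not shapely.intersects_xy(pattern.window, a, b):
        warnings.warn("ONH centre lies outside the window", stacklevel=2)
    d = np.hypot(pattern.points[:, 0] - a, pattern.points[:, 1] - b)
    nbins = max(1, int(np.ceil(d.max() / bin_width_um)) or 1)
    edges = np.arange(nbins + 1) * bin_width_um
    counts, _ = np.histogram(d, bins=edges)
    pct = 100.0 * counts / pattern.n
    return EccentricityProfile(
        onh_um=(a, b),
        bin_width_um=bin_width_um,
        bin_edges_um=edges,
        counts=counts,
        pct=pct,
        cum_pct=np.cumsum(pct),
    )


def bland_altman_percent(
    counts_a, counts_b
) -> tuple[float, float, float]:
    """Bland–Altman agreement of two paired count series, on the percentage
    scale: per pair 100·(a−b)/mean(a,b); bias is the mean difference and the
    limits of agreement are bias ± 1.96·sd.

    Returns ``(bias, loa_upper, loa_lower)``; with a single pair the limits
    are NaN (flagged by warning).
    """
    a = np.asarray(counts_a, float)
    b = np.asarray(counts_b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("need equal-length 1-D paired counts")
    means = (a + b) / 2.0
    if np.any(means <= 0):
        raise ValueError("pair mean must be positive")
    diffs = 100.0 * (a - b) / means
    bias = float(diffs.mean())
    if len(a) < 2:
        warnings.warn("single pair: limits of agreement undefined",
                      stacklevel=2)
        return bias, np.nan, np.nan
    sd = float(diffs.std(ddof=1))
    return bias, bias + 1.96 * sd, bias - 1.96 * sd


def nnd_to_colour(
    nnds: np.ndarray, vrange: tuple[float, float] = (15.0, 70.0)
) -> np.ndarray:
    """Map NND values (μm) onto the red→blue pseudocolour scale, clipped to
    ``vrange`` (defaults 15 μm = extreme red, 70 μm = extreme blue)."""
    from matplotlib import colormaps, colors

    lo, hi = vrange
    norm = colors.Normalize(vmin=lo, vmax=hi, clip=True)
    return colormaps["RdBu"](norm(np.asarray(nnds, float)))


def nnd_colour_map(
    pattern: PointPattern,
    vrange: tuple[float, float] = (15.0, 70.0),
    ax=None,
    point_size: float = 8.0,
):
    """Scatter of cell centroids pseudocoloured by NND inside the window
    boundary; red tones mark tightly packed cells, blue tones sparse ones."""
    import matplotlib.pyplot as plt

    summary = nearest_neighbour_distances(pattern)
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    colours = nnd_to_colour(summary.nnds, vrange)
    ax.scatter(pattern.points[:, 0], pattern.points[:, 1],
               c=colours, s=point_size, linewidths=0)
    bx, by = pattern.window.exterior.xy
    ax.plot(bx, by, color="k", lw=0.8)
    ax.set_aspect("equal")
    ax.invert_yaxis()  # image convention: y downward
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_title(f"NND map — {pattern.retina_id}")
    return ax
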