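"""Soma segmentation from 8-bit fluorescence whole-mount images.

The pipeline mirrors the original Fiji/MorphoLibJ recipe and runs in a
fixed order:

1. grey-scale attribute (area) opening — removes bright structures smaller
   than ``attribute_area_min`` connected pixels at every grey level;
2. grey-scale morphological opening with a small octagonal element —
   detaches thin processes from somata;
3. maximum-entropy (Kapur) threshold — separates somata from background;
4. connected-component particle extraction with a minimum pixel-count gate,
   measuring area, centroid and roundness 4A/(πM²) per particle;
5. a nearest-neighbour-distance gate on particle centroids.

Tissue area and its boundary polygon come from a low-intensity background
selection on the raw image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from skimage import measure, morphology

# 3×3 cross-with-corners footprint approximating a radius-1 octagon
OCTAGON_R1 = np.ones((3, 3), dtype=bool)


@dataclass
class RasterImage:
    """A single-channel 8-bit image with a physical pixel size (μm/px)."""

    intensities: np.ndarray
    pixel_size_um: float = 1.24

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 2:
            raise ValueError("expected a 2-D single-channel image")
        if self.intensities.dtype != np.uint8:
            if self.intensities.min() < 0 or self.intensities.max() > 255:
                raise ValueError("intensities outside [0, 255]")
            self.intensities = self.intensities.astype(np.uint8)
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape


@dataclass
class SegmentationParams:
    """Tunable knobs of the segmentation pipeline (defaults are the
    published recipe at 1.24 μm/px)."""

    attribute_area_min: int = 25  # px
    attribute_connectivity: int = 8  # {4, 8}
    opening_radius: int = 1  # px, octagon
    particle_area_min: int = 10  # px
    nnd_gate_px: float = 14.0  # px, gate on centroid NND
    nnd_keep_below: bool = True  # printed rule: keep NND < gate
    low_intensity_range: tuple[int, int] = (0, 5)  # background selection
    tissue_is_complement: bool = True

    def __post_init__(self) -> None:
        if self.attribute_connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        for v in (self.attribute_area_min, self.particle_area_min,
                  self.opening_radius, self.nnd_gate_px):
            if v < 0:
                raise ValueError("thresholds must be non-negative")


@dataclass
class Particle:
    """One segmented soma."""

    area_um2: float
    x_um: float
    y_um: float
    major_axis_um: float
    roundness: float  # 4A/(πM²); 1 for a circle, → 0 when elongated

    def __post_init__(self) -> None:
        if self.area_um2 <= 0 or self.major_axis_um <= 0:
            raise ValueError("area and major axis must be positive")


def _skimage_connectivity(conn: int) -> int:
    return {4: 1, 8: 2}[conn]


def attribute_open(
    image: RasterImage, area_min: int = 25, connectivity: int = 8
) -> RasterImage:
    """Grey-scale area opening: flatten every bright grain smaller than
    ``area_min`` connected pixels (at any grey level) into its surround."""
    out = morphology.area_opening(
        image.intensities,
        area_threshold=area_min,
        connectivity=_skimage_connectivity(connectivity),
    )
    return RasterImage(out, image.pixel_size_um)


def octagon_footprint(radius: int = 1) -> np.ndarray:
    if radius == 1:
        return OCTAGON_R1.copy()
    return morphology.octagon(radius, max(1, radius // 2))


def morphological_open(image: RasterImage, radius: int = 1) -> RasterImage:
    """Grey-scale opening with an octagonal structuring element; removes
    structures (e.g. 1-px processes) thinner than the element."""
    out = morphology.opening(image.intensities, octagon_footprint(radius))
    return RasterImage(out, image.pixel_size_um)


def max_entropy_threshold(image: RasterImage | np.ndarray) -> int:
    """Kapur–Sahoo–Wong maximum-entropy threshold on the 256-bin histogram.

    Returns the level t maximizing the summed Shannon entropies of the
    normalized sub-histograms [0..t] and [t+1..255]; foreground is > t.
    Ties break toward the lower threshold. Raises on a constant image.
    """
    arr = image.intensities if isinstance(image, RasterImage) else np.asarray(image)
    hist = np.bincount(arr.ravel().astype(np.uint8), minlength=256).astype(float)
    p = hist / hist.sum()
    if np.count_nonzero(p) < 2:
        raise ValueError("degenerate histogram: image has < 2 grey levels")
    P = np.cumsum(p)  # P[t] = mass of [0..t]
    # entropy of the low side, accumulated: -sum p log p over [0..t]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    S = np.cumsum(plogp)
    total = S[-1]
    best_t, best_val = -1, -np.inf
    for t in range(256):
        w0, w1 = P[t], 1.0 - P[t]
        if w0 <= 0 or w1 <= 0:
            continue
        h0 = np.log(w0) - S[t] / w0
        h1 = np.log(w1) - (total - S[t]) / w1
        val = h0 + h1
        if val > best_val + 1e-12:  # strict: ties keep the lower t
            best_val, best_t = val, t
    return int(best_t)


def extract_particles(
    mask: np.ndarray, pixel_size_um: float, particle_area_min: int = 10
) -> list[Particle]:
    """One Particle per 8-connected foreground component with at least
    ``particle_area_min`` pixels.

    Area is pixel count × pixel_size²; the centroid is the component's
    centre of mass; M is the major axis of the normalized-second-moment
    ellipse fit; roundness = 4A/(πM²).
    """
    lab = measure.label(np.asarray(mask, bool), connectivity=2)
    out: list[Particle] = []
    for rp in measure.regionprops(lab):
        if rp.area < particle_area_min:
            continue
        a_um2 = rp.area * pixel_size_um**2
        m_um = rp.axis_major_length * pixel_size_um
        if m_um <= 0:  # degenerate single-row fit; skip defensively
            continue
        r, c = rp.centroid
        out.append(
            Particle(
                area_um2=a_um2,
                x_um=c * pixel_size_um,
                y_um=r * pixel_size_um,
                major_axis_um=m_um,
                roundness=4.0 * a_um2 / (np.pi * m_um**2),
            )
        )
    return out


def nnd_gate(
    particles: list[Particle], gate_um: float, keep_below: bool = True
) -> list[Particle]:
    """Filter particles by centroid nearest-neighbour distance.

    The published rule keeps particles with NND < 14 px (× pixel size); the
    direction is configurable. A single particle has no NND and is returned
    unfiltered with a warning.
    """
    if not particles:
        return []
    if len(particles) == 1:
        warnings.warn("single particle: NND undefined, returned unfiltered",
                      stacklevel=2)
        return list(particles)
    xy = np.array([[p.x_um, p.y_um] for p in particles])
    d, _ = cKDTree(xy).query(xy, k=2)
    nnd = d[:, 1]
    keep = nnd < gate_um if keep_below else nnd >= gate_um
    return [p for p, k in zip(particles, keep) if k]


def retina_area_and_boundary(
    image: RasterImage,
    low_range: tuple[int, int] = (0, 5),
    tissue_is_complement: bool = True,
) -> tuple[float, Polygon]:
    """Tissue area (mm²) and outer boundary polygon (μm) from a
    low-intensity background selection.

    Pixels inside ``low_range`` are background; tissue is the complement
    (flip with ``tissue_is_complement=False``). The boundary is the longest
    outer contour of the largest tissue component.
    """
    arr = image.intensities
    lo, hi = low_range
    background = (arr >= lo) & (arr <= hi)
    tissue = ~background if tissue_is_complement else background
    if not tissue.any():
        raise ValueError("empty tissue mask")
    ps = image.pixel_size_um
    area_mm2 = tissue.sum() * ps**2 / 1e6

    lab = measure.label(tissue, connectivity=2)
    largest = lab == np.argmax(np.bincount(lab.ravel())[1:]) + 1
    padded = np.pad(largest, 1)  # guarantee a closed outer contour
    contours = measure.find_contours(padded.astype(float), 0.5)
    if not contours:
        raise ValueError("no boundary contour found")
    contour = max(contours, key=len) - 1.0  # (row, col), undo padding
    poly = Polygon(np.column_stack([contour[:, 1] * ps, contour[:, 0] * ps]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    # one-pixel simplification removes the staircase artefact so the
    # perimeter approximates the true tissue outline
    poly = poly.simplify(ps)
    return area_mm2, poly


def segment_image(
    image: RasterImage, params: SegmentationParams | None = None
) -> list[Particle]:
    """Full pipeline (steps 1–5 in fixed order) on one image."""
    params = params or SegmentationParams()
    filtered = attribute_open(
        image, params.attribute_area_min, params.attribute_connectivity
    )
    opened = morphological_open(filtered, params.opening_radius)
    t = max_entropy_threshold(opened)
    mask = opened.intensities > t
    particles = extract_particles(
        mask, image.pixel_size_um, params.particle_area_min
    )
    gate_um = params.nnd_gate_px * image.pixel_size_um
    return nnd_gate(particles, gate_um, params.nnd_keep_below)
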