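"""File contracts: point-table CSV, boundary-polygon CSV, 8-bit TIFF.

The canonical point table has columns
``retina_id, group, x_um, y_um, area_um2, roundness`` and optionally
``activity_label``; one row per cell. Boundary polygons are ordered
``x_um, y_um`` vertex lists. Images are single-channel 8-bit TIFFs; when
pixel-size metadata is missing the configured default (1.24 μm/px) is used
with a warning.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import Polygon

from .patterns import PointPattern
from .segmentation import Particle, RasterImage

POINT_TABLE_COLUMNS = ("retina_id", "group", "x_um", "y_um",
                       "area_um2", "roundness")
DEFAULT_PIXEL_SIZE_UM = 1.24


def particles_to_frame(
    particles: list[Particle], retina_id: str, group: str
) -> pd.DataFrame:
    """Particle list → canonical point-table rows."""
    return pd.DataFrame(
        {
            "retina_id": retina_id,
            "group": group,
            "x_um": [p.x_um for p in particles],
            "y_um": [p.y_um for p in particles],
            "area_um2": [p.area_um2 for p in particles],
            "roundness": [p.roundness for p in particles],
        }
    )


def write_point_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    missing = [c for c in POINT_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"point table missing columns {missing}")
    frame.to_csv(path, index=False)
    return path


def read_point_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a point-table CSV; malformed rows are reported
    with their line number."""
    path = Path(path)
    frame = pd.read_csv(path)
    missing = [c for c in POINT_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    numeric = ["x_um", "y_um", "area_um2", "roundness"]
    for col in numeric:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = np.where(~np.isfinite(vals.to_numpy(dtype=float)))[0]
        if len(bad):
            # +2: header line and 1-based numbering
            raise ValueError(
                f"{path}: non-finite value in column {col!r} at line {bad[0] + 2}"
            )
        frame[col] = vals
    return frame


def pattern_from_table(
    frame: pd.DataFrame, window: Polygon, retina_id: str
) -> PointPattern:
    """Rows of one retina → a PointPattern (marks from activity_label when
    present)."""
    sub = frame[frame["retina_id"] == retina_id]
    if sub.empty:
        raise ValueError(f"no rows for retina {retina_id!r}")
    group = str(sub["group"].iloc[0])
    marks = None
    if "activity_label" in sub.columns and sub["activity_label"].notna().all():
        marks = sub["activity_label"].to_numpy(dtype=object)
    return PointPattern(
        sub[["x_um", "y_um"]].to_numpy(float), window, marks, retina_id, group
    )


def write_boundary_csv(polygon: Polygon, path: str | Path) -> Path:
    path = Path(path)
    x, y = polygon.exterior.coords.xy
    pd.DataFrame({"x_um": x, "y_um": y}).to_csv(path, index=False)
    return path


def read_boundary_csv(path: str | Path) -> Polygon:
    path = Path(path)
    frame = pd.read_csv(path)
    for col in ("x_um", "y_um"):
        if col not in frame.columns:
            raise ValueError(f"{path}: missing column {col!r}")
        vals = pd.to_numeric(frame[col], errors="coerce").to_numpy(float)
        bad = np.where(~np.isfinite(vals))[0]
        if len(bad):
            raise ValueError(
                f"{path}: non-finite value in column {col!r} at line {bad[0] + 2}"
            )
    coords = frame[["x_um", "y_um"]].to_numpy(float)
    # drop an explicit closing vertex before counting
    if len(coords) > 1 and np.allclose(coords[0], coords[-1]):
        coords = coords[:-1]
    if len(coords) < 3:
        raise ValueError(f"{path}: boundary needs at least 3 vertices")
    poly = Polygon(coords)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def write_tiff(image: RasterImage, path: str | Path) -> Path:
    """Write a single-channel 8-bit TIFF carrying the pixel size as
    resolution metadata (pixels per centimetre)."""
    path = Path(path)
    px_per_cm = 1e4 / image.pixel_size_um
    tifffile.imwrite(
        path,
        image.intensities,
        resolution=(px_per_cm, px_per_cm),
        resolutionunit="CENTIMETER",
    )
    return path


def read_tiff(
    path: str | Path, pixel_size_fallback_um: float = DEFAULT_PIXEL_SIZE_UM
) -> RasterImage:
    """Read a single-channel 8-bit TIFF; pixel size from resolution tags,
    else the fallback (with a warning)."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        arr = page.asarray()
        pixel_size = None
        tags = page.tags
        if "XResolution" in tags and "ResolutionUnit" in tags:
            num, den = tags["XResolution"].value
            unit = getattr(tags["ResolutionUnit"].value, "value",
                           tags["ResolutionUnit"].value)
            if num > 0 and den > 0:
                px_per_unit = num / den
                if unit == 3:  # centimetre
                    pixel_size = 1e4 / px_per_unit
                elif unit == 2:  # inch
                    pixel_size = 25.4e3 / px_per_unit
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if pixel_size is None:
        warnings.warn(
            f"{path}: no pixel-size metadata, using "
            f"{pixel_size_fallback_um} μm/px",
            stacklevel=2,
        )
        pixel_size = pixel_size_fallback_um
    return RasterImage(arr, pixel_size)
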