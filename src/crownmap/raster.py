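"""Raster containers, GeoTIFF I/O, slope derivation and layer stacking.

Rasters are kept as ``(bands, rows, cols)`` float or integer arrays with a
north-up square-pixel geotransform (pixel-centre registration internally,
GeoTIFF corner-anchored tie point on disk).  The slope model is derived from
the digital surface model (DSM) with Horn's 3x3 weighted finite differences,
the default of mainstream GIS slope tools: it measures the maximum rate of
elevation change between a cell and its neighbours, which makes tree crown
rims stand out as high-slope rings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile
from scipy import ndimage

__all__ = [
    "GeoTransform",
    "RasterGrid",
    "SurfaceModel",
    "SlopeModel",
    "RasterFormatError",
    "read_raster",
    "write_raster",
    "compute_slope",
    "resample_to",
    "stack_layers",
]

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterFormatError(ValueError):
    """Raised for unreadable or ungeoreferenced raster files."""


@dataclass(frozen=True)
class GeoTransform:
    """North-up affine geotransform: ``x = ox + col*px`` , ``y = oy - row*px``.

    ``origin_x``/``origin_y`` anchor the outer corner of the top-left pixel;
    ``cell_size`` is the square pixel size in metres.
    """

    origin_x: float
    origin_y: float
    cell_size: float

    def __post_init__(self) -> None:
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    def pixel_center(self, row, col):
        """Geographic coordinates of pixel centres (vectorised)."""
        x = self.origin_x + (np.asarray(col) + 0.5) * self.cell_size
        y = self.origin_y - (np.asarray(row) + 0.5) * self.cell_size
        return x, y

    def almost_equal(self, other: "GeoTransform", tol: float = 1e-9) -> bool:
        return (
            abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )


@dataclass
class RasterGrid:
    """Aligned multi-band grid: the common currency of all raster stages."""

    values: np.ndarray  # (bands, rows, cols)
    transform: GeoTransform
    nodata: float | None = None
    band_names: tuple[str, ...] = ()
    layer_weights: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim == 2:
            v = v[None]
        if v.ndim != 3:
            raise ValueError(f"expected 2-D or 3-D values, got ndim={v.ndim}")
        self.values = v
        if not self.band_names:
            self.band_names = tuple(f"band{i + 1}" for i in range(v.shape[0]))
        if len(self.band_names) != v.shape[0]:
            raise ValueError("band_names length must match band count")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    def valid_mask(self) -> np.ndarray:
        """True where no band holds the nodata sentinel (or NaN)."""
        v = self.values.astype(float)
        mask = ~np.isnan(v).any(axis=0)
        if self.nodata is not None:
            mask &= ~(self.values == self.nodata).any(axis=0)
        return mask

    def band_statistics(self) -> dict[str, tuple[float, float]]:
        """Per-band (mean, population SD) over valid cells only."""
        mask = self.valid_mask()
        out = {}
        for name, band in zip(self.band_names, self.values):
            vals = band[mask].astype(float)
            out[name] = (float(vals.mean()), float(vals.std()))
        return out


@dataclass
class SurfaceModel:
    """Digital surface model: canopy-top elevation in metres."""

    elevation: np.ndarray  # (rows, cols)
    transform: GeoTransform
    nodata: float | None = None

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=float)
        if self.elevation.ndim != 2:
            raise ValueError("elevation must be 2-D")

    @property
    def cell_size(self) -> float:
        return self.transform.cell_size

    def valid_mask(self) -> np.ndarray:
        mask = ~np.isnan(self.elevation)
        if self.nodata is not None:
            mask &= self.elevation != self.nodata
        return mask

    def as_grid(self) -> RasterGrid:
        return RasterGrid(self.elevation[None], self.transform,
                          nodata=self.nodata, band_names=("DSM",))


@dataclass
class SlopeModel:
    """Per-cell slope in degrees, in [0, 90)."""

    slope: np.ndarray  # (rows, cols); NaN where undefined
    transform: GeoTransform

    def as_grid(self) -> RasterGrid:
        return RasterGrid(self.slope[None], self.transform,
                          nodata=float("nan"), band_names=("slope",))


# ---------------------------------------------------------------------------
# GeoTIFF I/O (tifffile + GeoTIFF tags)
# ---------------------------------------------------------------------------

def write_raster(path: str | Path, grid: RasterGrid) -> None:
    """Write a RasterGrid to GeoTIFF, preserving geotransform and nodata."""
    t = grid.transform
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (t.cell_size, t.cell_size, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.origin_x, t.origin_y, 0.0)),
    ]
    if grid.nodata is not None:
        extratags.append((_TAG_GDAL_NODATA, "s", 0, str(grid.nodata)))
    data = grid.values
    if data.shape[0] == 1:
        tifffile.imwrite(path, data[0], extratags=extratags)
    else:
        tifffile.imwrite(path, data, planarconfig="separate",
                         photometric="minisblack", extratags=extratags)


def read_raster(path: str | Path) -> RasterGrid:
    """Read a georeferenced single- or multi-band GeoTIFF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = tif.asarray()
            tags = page.tags
            scale_tag = tags.get(_TAG_PIXEL_SCALE)
            tiepoint_tag = tags.get(_TAG_TIEPOINT)
            nodata_raw = tags.get(_TAG_GDAL_NODATA)
            scale = None if scale_tag is None else tuple(scale_tag.value)
            tp = None if tiepoint_tag is None else tuple(tiepoint_tag.value)
            nodata_tag = None if nodata_raw is None else str(nodata_raw.value)
            planar = page.planarconfig
    except (tifffile.TiffFileError, ValueError) as exc:
        raise RasterFormatError(f"unreadable raster: {path}: {exc}") from exc
    if scale is None or tp is None:
        raise RasterFormatError(f"raster is not georeferenced: {path}")
    sx, sy = float(scale[0]), float(scale[1])
    if not math.isclose(sx, sy, rel_tol=1e-6):
        raise RasterFormatError("non-square pixels are not supported")
    transform = GeoTransform(float(tp[3]) - float(tp[0]) * sx,
                             float(tp[4]) + float(tp[1]) * sy, sx)
    nodata = None
    if nodata_tag is not None:
        nodata = float(nodata_tag.strip("\x00 "))
    if data.ndim == 2:
        data = data[None]
    elif data.ndim == 3 and planar != 2:
        # contiguous (rows, cols, bands) -> (bands, rows, cols)
        data = np.moveaxis(data, -1, 0)
    names = ("R", "G", "B") if data.shape[0] == 3 else ()
    return RasterGrid(data, transform, nodata=nodata, band_names=names)


# ---------------------------------------------------------------------------
# Slope (Horn 3x3)
# ---------------------------------------------------------------------------

def compute_slope(dsm: SurfaceModel) -> SlopeModel:
    """Slope in degrees from Horn's 3x3 weighted finite differences.

    Edge cells use clamp-to-edge padding so the output keeps the DSM shape.
    Cells whose 3x3 neighbourhood touches nodata are NaN in the output.
    """
    z = dsm.elevation
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("DSM must be at least 3x3 to compute slope")
    valid = dsm.valid_mask()
    if not valid.any():
        raise ValueError("DSM holds no valid cells")
    zf = np.where(valid, z, np.nan)
    zp = np.pad(zf, 1, mode="edge")
    cs = dsm.cell_size
    # neighbourhood letters:  a b c / d e f / g h i
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    slope[~valid] = np.nan
    return SlopeModel(slope, dsm.transform)


# ---------------------------------------------------------------------------
# Resampling and stacking
# ---------------------------------------------------------------------------

def resample_to(band: np.ndarray, src: GeoTransform, dst: GeoTransform,
                dst_shape: tuple[int, int]) -> np.ndarray:
    """Bilinearly resample one band from the ``src`` grid onto ``dst``."""
    rows, cols = np.mgrid[0:dst_shape[0], 0:dst_shape[1]]
    x, y = dst.pixel_center(rows, cols)
    # fractional indices into the source grid (pixel-centre registration)
    src_col = (x - src.origin_x) / src.cell_size - 0.5
    src_row = (src.origin_y - y) / src.cell_size - 0.5
    return ndimage.map_coordinates(np.asarray(band, dtype=float),
                                   [src_row, src_col], order=1, mode="nearest")


def _scaled_to_byte_range(band: np.ndarray) -> np.ndarray:
    """Min-max scale a layer to 0..255 so layer weights are commensurate."""
    finite = np.isfinite(band)
    if not finite.any():
        return np.zeros_like(band)
    lo, hi = band[finite].min(), band[finite].max()
    if hi <= lo:
        return np.zeros_like(band)
    out = (band - lo) / (hi - lo) * 255.0
    return np.where(finite, out, 0.0)


def stack_layers(ortho: RasterGrid, dsm: SurfaceModel, slope: SlopeModel,
                 weights: Sequence[float] = (1.0, 1.0, 1.0, 1.0, 1.0)) -> RasterGrid:
    """Stack [R, G, B, DSM, slope] on the ortho grid for segmentation.

    DSM-resolution layers are bilinearly resampled to the orthomosaic grid
    first, then min-max scaled to the 0-255 byte range so that the per-layer
    ``weights`` act on commensurate units in the merge cost.
    """
    if ortho.n_bands != 3:
        raise ValueError("orthomosaic must have exactly 3 bands (R, G, B)")
    if len(weights) != 5:
        raise ValueError("expected 5 layer weights for [R, G, B, DSM, slope]")
    shape = ortho.shape
    t = ortho.transform
    dsm_band = resample_to(dsm.elevation, dsm.transform, t, shape)
    slope_band = resample_to(slope.slope, slope.transform, t, shape)
    layers = np.stack([
        ortho.values[0].astype(float),
        ortho.values[1].astype(float),
        ortho.values[2].astype(float),
        _scaled_to_byte_range(dsm_band),
        _scaled_to_byte_range(slope_band),
    ])
    return RasterGrid(layers, t, nodata=ortho.nodata,
                      band_names=("R", "G", "B", "DSM", "slope"),
                      layer_weights=tuple(float(w) for w in weights))
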