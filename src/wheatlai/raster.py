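"""Georeferenced raster container, GeoTIFF I/O and point extraction.

Rasters are held as numpy arrays (2-D single band, or 3-D ``(band, row, col)``)
with NaN as the in-memory nodata sentinel, a north-up affine transform mapping
pixel to map coordinates, and an optional CRS identifier string.  Files are
plain GeoTIFFs written through :mod:`tifffile` with the standard
ModelPixelScale / ModelTiepoint georeferencing tags.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import tifffile

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class Affine(NamedTuple):
    """Affine pixel->map transform, GDAL ordering.

    ``x = a*col + b*row + c`` and ``y = d*col + e*row + f`` where (col, row)
    are *pixel-center* indices offset by 0.5 (i.e. pixel (0,0) has its center
    at (c + a/2, f + e/2) for an axis-aligned grid).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    @classmethod
    def from_origin(cls, west: float, north: float, xres: float, yres: float) -> "Affine":
        """North-up grid: row 0 at the northern edge, y decreasing with row."""
        return cls(xres, 0.0, west, 0.0, -yres, north)

    def xy(self, row, col):
        """Map coordinates of the center of pixel (row, col)."""
        fc = np.asarray(col) + 0.5
        fr = np.asarray(row) + 0.5
        return self.a * fc + self.b * fr + self.c, self.d * fc + self.e * fr + self.f

    def rowcol(self, x, y):
        """Pixel (row, col) containing map point (x, y); pixel-center convention."""
        det = self.a * self.e - self.b * self.d
        if det == 0:
            raise ValueError("transform is singular")
        dx = np.asarray(x) - self.c
        dy = np.asarray(y) - self.f
        fc = (self.e * dx - self.b * dy) / det
        fr = (self.a * dy - self.d * dx) / det
        return np.floor(fr).astype(int), np.floor(fc).astype(int)


@dataclass
class Raster:
    """A nodata-aware georeferenced grid."""

    values: np.ndarray
    transform: Affine = Affine.from_origin(0.0, 0.0, 1.0, 1.0)
    crs: str | None = None
    band_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim not in (2, 3):
            raise ValueError("raster values must be 2-D or 3-D (band, row, col)")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[-2:]

    @property
    def height(self) -> int:
        return self.values.shape[-2]

    @property
    def width(self) -> int:
        return self.values.shape[-1]

    @property
    def count(self) -> int:
        return 1 if self.values.ndim == 2 else self.values.shape[0]

    @property
    def res(self) -> tuple[float, float]:
        return abs(self.transform.a), abs(self.transform.e)

    def band(self, key: int | str) -> "Raster":
        """Single band as a 2-D raster; ``key`` is an index or a band name."""
        if self.values.ndim == 2:
            if key in (0, None) or key == (self.band_names or ("",))[0]:
                return self
            raise KeyError(f"single-band raster has no band {key!r}")
        if isinstance(key, str):
            if not self.band_names or key not in self.band_names:
                raise KeyError(f"unknown band {key!r}; have {self.band_names}")
            key = self.band_names.index(key)
        return Raster(self.values[key], self.transform, self.crs)

    def like(self, values: np.ndarray, band_names=None) -> "Raster":
        """New raster on this grid with different values."""
        return Raster(np.asarray(values, dtype=np.float64), self.transform,
                      self.crs, band_names)

    def same_grid(self, other: "Raster") -> bool:
        return self.shape == other.shape and all(
            math.isclose(u, v, rel_tol=0, abs_tol=1e-9)
            for u, v in zip(self.transform, other.transform)
        )


@dataclass
class SamplePoint:
    """A ground observation: location plus measured LAI and plant height."""

    id: int
    x: float
    y: float
    lai: float
    ph_cm: float


# ---------------------------------------------------------------------------
# GeoTIFF I/O
# ---------------------------------------------------------------------------

def write_geotiff(path: str | Path, raster: Raster) -> None:
    """Write a raster as a tiled GeoTIFF (float64, NaN nodata)."""
    t = raster.transform
    if t.b != 0 or t.d != 0:
        raise ValueError("only axis-aligned transforms are written")
    desc = json.dumps({"crs": raster.crs, "band_names": raster.band_names})
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(t.a), abs(t.e), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, t.c, t.f, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, "nan"),
    ]
    data = raster.values
    kwargs = {}
    if data.ndim == 3:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(path, data, photometric="minisblack",
                     description=desc, extratags=extratags, **kwargs)


def read_geotiff(path: str | Path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        scale = page.tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = page.tags[_TAG_MODEL_TIEPOINT].value
        meta = {}
        if page.description:
            try:
                meta = json.loads(page.description)
            except (ValueError, TypeError):
                meta = {}
    transform = Affine.from_origin(tie[3], tie[4], scale[0], scale[1])
    names = meta.get("band_names")
    return Raster(np.asarray(data, dtype=np.float64), transform,
                  meta.get("crs"), tuple(names) if names else None)


def write_points_csv(path: str | Path, points: Sequence[SamplePoint]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["id", "x", "y", "lai", "ph_cm"])
        for p in points:
            w.writerow([p.id, repr(p.x), repr(p.y), repr(p.lai), repr(p.ph_cm)])


def read_points_csv(path: str | Path) -> list[SamplePoint]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(SamplePoint(int(row["id"]), float(row["x"]), float(row["y"]),
                                   float(row["lai"]), float(row["ph_cm"])))
    return out


# ---------------------------------------------------------------------------
# Cubic-convolution resampling (Keys kernel, a = -0.5)
# ---------------------------------------------------------------------------

def _keys_kernel(s: np.ndarray, a: float = -0.5) -> np.ndarray:
    s = np.abs(s)
    w = np.zeros_like(s)
    near = s <= 1
    far = (s > 1) & (s < 2)
    w[near] = (a + 2) * s[near] ** 3 - (a + 3) * s[near] ** 2 + 1
    w[far] = a * s[far] ** 3 - 5 * a * s[far] ** 2 + 8 * a * s[far] - 4 * a
    return w


def _resample_axis(values: np.ndarray, pos: np.ndarray, axis: int) -> np.ndarray:
    """Cubic-convolution interpolation of `values` at fractional indices `pos`
    along `axis`, clamping the 4-tap neighborhood at the edges."""
    n = values.shape[axis]
    base = np.floor(pos).astype(int)
    out = None
    for k in range(-1, 3):
        idx = np.clip(base + k, 0, n - 1)
        w = _keys_kernel(pos - (base + k))
        taken = np.take(values, idx, axis=axis)
        shape = [1] * taken.ndim
        shape[axis] = len(pos)
        term = taken * w.reshape(shape)
        out = term if out is None else out + term
    return out


def resample_cubic(raster: Raster, target_resolution: float) -> Raster:
    """Resample to ``target_resolution`` (m/pixel) by cubic convolution.

    The output grid shares the raster's origin and covers (at least) the same
    extent.  NaN nodata propagates through the 4x4 interpolation footprint.
    """
    if target_resolution <= 0:
        raise ValueError("target_resolution must be > 0")
    if raster.values.size == 0:
        raise ValueError("cannot resample an empty raster")
    xres, yres = raster.res
    new_w = max(1, round(raster.width * xres / target_resolution))
    new_h = max(1, round(raster.height * yres / target_resolution))
    # output pixel centers expressed in source fractional pixel indices
    cols = (np.arange(new_w) + 0.5) * target_resolution / xres - 0.5
    rows = (np.arange(new_h) + 0.5) * target_resolution / yres - 0.5
    out = _resample_axis(raster.values, cols, axis=-1)
    out = _resample_axis(out, rows, axis=-2)
    t = raster.transform
    new_t = Affine.from_origin(t.c, t.f, target_resolution, target_resolution)
    return Raster(out, new_t, raster.crs, raster.band_names)


# ---------------------------------------------------------------------------
# Point extraction
# ---------------------------------------------------------------------------

def extract_at_points(raster: Raster, points: Sequence[SamplePoint],
                      radius: float = 0.0) -> np.ndarray:
    """Raster values at sample points.

    radius 0 reads the single pixel containing each point (pixel-center
    convention); radius > 0 averages the valid pixels whose centers fall
    within ``radius`` meters of the point.
    """
    if raster.values.ndim != 2:
        raise ValueError("extract_at_points expects a single-band raster")
    vals = raster.values
    h, w = vals.shape
    xres, yres = raster.res
    out = np.empty(len(points))
    for i, p in enumerate(points):
        row, col = raster.transform.rowcol(p.x, p.y)
        if not (0 <= row < h and 0 <= col < w):
            raise ValueError(f"point id={p.id} at ({p.x}, {p.y}) outside raster extent")
        if radius <= 0:
            out[i] = vals[row, col]
            continue
        rr = int(math.ceil(radius / yres)) + 1
        rc = int(math.ceil(radius / xres)) + 1
        r0, r1 = max(0, row - rr), min(h, row + rr + 1)
        c0, c1 = max(0, col - rc), min(w, col + rc + 1)
        rows = np.arange(r0, r1)
        cols = np.arange(c0, c1)
        cx, cy = raster.transform.xy(rows[:, None], cols[None, :])
        inside = (cx - p.x) ** 2 + (cy - p.y) ** 2 <= radius**2
        window = vals[r0:r1, c0:c1]
        sel = window[inside & np.isfinite(window)]
        out[i] = sel.mean() if sel.size else np.nan
    return out
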