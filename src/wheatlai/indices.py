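"""Vegetation indices for the four-band (G/R/RE/NIR) multispectral mosaic.

The registry holds the 17 indices used as LAI predictors plus OSAVI, which
serves only as an input to the wheat/soil mask classifier.  Formulas are the
standard literature forms for each index; pixels where a denominator vanishes
or a radicand goes negative become NaN (nodata).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np

from .raster import Raster

WAVELENGTHS_NM = {"G": 550, "R": 660, "RE": 735, "NIR": 790}
BAND_ORDER = ("G", "R", "RE", "NIR")


@dataclass
class BandSet:
    """Co-registered reflectance bands: green, red, red edge, near infrared."""

    G: Raster
    R: Raster
    RE: Raster
    NIR: Raster

    def __post_init__(self) -> None:
        for name in ("R", "RE", "NIR"):
            if not self.G.same_grid(getattr(self, name)):
                raise ValueError(f"band {name} is not on the G band's grid")

    @classmethod
    def from_scene(cls, scene: Raster) -> "BandSet":
        """Split a 4-band reflectance raster (band order G, R, RE, NIR)."""
        if scene.count != 4:
            raise ValueError("scene must have exactly 4 bands")
        order = scene.band_names or BAND_ORDER
        return cls(**{n: scene.band(n if scene.band_names else i)
                      for i, n in enumerate(order)})

    def arrays(self) -> tuple[np.ndarray, ...]:
        return self.G.values, self.R.values, self.RE.values, self.NIR.values

    @property
    def grid(self) -> Raster:
        return self.G


def _safe_div(num, den):
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.asarray(num, dtype=float) / den
    return np.where(den == 0, np.nan, out)


def _safe_sqrt(x):
    x = np.asarray(x, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(x < 0, np.nan, np.sqrt(np.clip(x, 0, None)))


# Each formula maps (G, R, RE, NIR) reflectance arrays to an index array.
_FORMULAS: dict[str, Callable] = {
    "RVI": lambda G, R, RE, NIR: _safe_div(NIR, R),
    "DVI": lambda G, R, RE, NIR: NIR - R,
    "NDVI": lambda G, R, RE, NIR: _safe_div(NIR - R, NIR + R),
    "GNDVI": lambda G, R, RE, NIR: _safe_div(NIR - G, NIR + G),
    "EVI2": lambda G, R, RE, NIR: _safe_div(2.5 * (NIR - R), NIR + 2.4 * R + 1),
    "CLgreen": lambda G, R, RE, NIR: _safe_div(NIR, G) - 1,
    "MSR": lambda G, R, RE, NIR: _safe_div(
        _safe_div(NIR, R) - 1, _safe_sqrt(_safe_div(NIR, R) + 1)),
    "MSAVI": lambda G, R, RE, NIR: 0.5 * (
        (2 * NIR + 1) - _safe_sqrt((2 * NIR + 1) ** 2 - 8 * (NIR - R))),
    "GOSAVI": lambda G, R, RE, NIR: _safe_div(1.16 * (NIR - G), NIR + G + 0.16),
    "REOSAVI": lambda G, R, RE, NIR: _safe_div(1.16 * (NIR - RE), NIR + RE + 0.16),
    "RERDVI": lambda G, R, RE, NIR: _safe_div(NIR - RE, NIR + RE),
    "CLre": lambda G, R, RE, NIR: _safe_div(NIR, RE) - 1,
    "CARI": lambda G, R, RE, NIR: (RE - R) - 0.2 * (RE + R),
    "NGRDI": lambda G, R, RE, NIR: _safe_div(G - R, G + R),
    "TVI": lambda G, R, RE, NIR: 60 * (NIR - G) - 100 * (R - G),
    "MTVI2": lambda G, R, RE, NIR: _safe_div(
        1.5 * (1.2 * (NIR - G) - 2.5 * (R - G)),
        _safe_sqrt((2 * NIR + 1) ** 2 - (6 * NIR - 5 * _safe_sqrt(R)) - 0.5)),
    "MTCI": lambda G, R, RE, NIR: _safe_div(NIR - RE, RE - R),
    # red-band OSAVI: mask-classifier input only, not an LAI predictor
    "OSAVI": lambda G, R, RE, NIR: _safe_div(1.16 * (NIR - R), NIR + R + 0.16),
}

#: The 17 LAI-predictor indices, in registry order.
VI_NAMES: tuple[str, ...] = (
    "RVI", "DVI", "NDVI", "GNDVI", "EVI2", "CLgreen", "MSR", "MSAVI",
    "GOSAVI", "REOSAVI", "RERDVI", "CLre", "CARI", "NGRDI", "TVI",
    "MTVI2", "MTCI",
)

#: Indices feeding the wheat-pixel mask classifier alongside the raw bands.
MASK_VI_NAMES: tuple[str, ...] = ("NDVI", "EVI2", "REOSAVI", "OSAVI")


def compute_vi(bands: BandSet, name: str) -> Raster:
    """Evaluate a registered vegetation index over the scene.

    NaN in any input band propagates; singular pixels become NaN.
    """
    if name not in _FORMULAS:
        raise KeyError(
            f"unknown vegetation index {name!r}; registered: {sorted(_FORMULAS)}")
    out = _FORMULAS[name](*bands.arrays())
    invalid = ~np.isfinite(sum(bands.arrays()))
    out = np.where(invalid, np.nan, out)
    return bands.grid.like(out)


def compute_all_vi(bands: BandSet) -> Mapping[str, Raster]:
    """All 17 LAI-predictor indices, keyed by name."""
    return {name: compute_vi(bands, name) for name in VI_NAMES}
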