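"""Plant height from surface-model differencing.

The canopy height model is the jointing-stage DSM minus the bare-soil DSM
(both in metres), delivered in centimetres with negative differences —
terrain/photogrammetric noise artifacts — clipped to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .raster import Raster, SamplePoint, extract_at_points

#: Field protocol averaged plants within a 50 cm radius of each point.
DEFAULT_PH_RADIUS_M = 0.5


@dataclass
class SurfaceModelPair:
    """Co-registered bare-soil (dsm0) and crop-stage (dsm1) elevation rasters."""

    dsm0: Raster
    dsm1: Raster

    def __post_init__(self) -> None:
        if not self.dsm0.same_grid(self.dsm1):
            raise ValueError("DSM0 and DSM1 are not on the same grid")


def compute_ph(pair: SurfaceModelPair) -> Raster:
    """Plant-height raster in cm: (DSM1 - DSM0) * 100, clipped at 0, NaN-aware."""
    diff = (pair.dsm1.values - pair.dsm0.values) * 100.0
    with np.errstate(invalid="ignore"):
        ph = np.where(np.isfinite(diff), np.clip(diff, 0.0, None), np.nan)
    return pair.dsm0.like(ph)


def ph_at_points(ph: Raster, points: Sequence[SamplePoint],
                 radius: float = DEFAULT_PH_RADIUS_M) -> np.ndarray:
    """Mean plant height (cm) within ``radius`` metres of each sample point."""
    return extract_at_points(ph, points, radius=radius)
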