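"""Synthetic UAV scenes with the statistical structure of a winter-wheat field.

The generator replaces a field campaign: it produces a 4-band reflectance
orthomosaic, a bare-soil and a jointing-stage surface model, ground-truth LAI
and wheat-mask rasters, and a table of ground sample points.

Construction, in order:

* LAI is a smooth Gaussian random field, rank-mapped through the quantile
  function of a truncated normal so the marginal hits the configured range
  and approximately the configured mean/SD.
* Plant height is linear in LAI (cm) plus noise, zero on bare soil.
* DSM0 is gentle smooth terrain; DSM1 adds plant height (m) and survey noise.
* Reflectance mixes pure-canopy and bare-soil spectra through a Beer-Lambert
  cover fraction f = 1 - exp(-k LAI), so high-LAI canopies saturate
  spectrally; a periodic seeding-row pattern modulates cover on wheat pixels.
* Bare-soil strips (tramlines) give the mask classifier both classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage, stats

from .raster import Affine, Raster, SamplePoint, write_geotiff, write_points_csv

BAND_NAMES = ("G", "R", "RE", "NIR")


@dataclass
class SceneConfig:
    """Parameters of the synthetic scene.

    Reflectance spectra are (G, R, RE, NIR) tuples in [0, 1]; heights in cm,
    elevations in m, resolution in m/pixel.
    """

    width: int = 256
    height: int = 256
    resolution: float = 0.1
    seed: int = 0
    lai_range: tuple[float, float] = (0.61, 8.57)
    lai_mean_sd: tuple[float, float] = (3.89, 1.93)
    ph_slope: float = 5.0          # cm per LAI unit
    ph_intercept: float = 15.0     # cm
    ph_noise_sd: float = 1.0       # cm, canopy-surface roughness
    extinction_k: float = 0.5
    veg_reflectance: tuple[float, float, float, float] = (0.12, 0.05, 0.30, 0.50)
    soil_reflectance: tuple[float, float, float, float] = (0.18, 0.22, 0.26, 0.30)
    row_spacing: float = 0.15      # m between seeding rows
    row_amplitude: float = 0.08    # relative cover modulation of the rows
    re_absorption_floor: float = 0.20  # asymptotic canopy red-edge reflectance
    re_absorption_rate: float = 0.15   # per-LAI decay of red-edge reflectance
    noise_sd: float = 0.004        # reflectance noise
    n_points: int = 79
    lai_noise_sd: float = 0.15     # LAI measurement noise at sample points
    ph_meas_noise_sd: float = 0.5  # cm, tape-measure noise at sample points
    smooth_sigma_px: float = 15.0  # correlation length of the LAI field
    base_elevation: float = 25.0   # m
    terrain_amplitude: float = 0.2  # m
    dsm_noise_sd: float = 0.005    # m, photogrammetric surface noise
    soil_strip_period_px: int = 48
    soil_strip_width_px: int = 8
    sample_margin_px: int = 6      # keep samples away from scene borders

    def __post_init__(self) -> None:
        numeric = [self.resolution, self.ph_slope, self.ph_intercept,
                   self.ph_noise_sd, self.extinction_k, self.row_spacing,
                   self.noise_sd, *self.lai_range, *self.lai_mean_sd,
                   *self.veg_reflectance, *self.soil_reflectance]
        if not all(math.isfinite(v) for v in numeric):
            raise ValueError("scene config contains non-finite values")
        if self.lai_range[0] > self.lai_range[1]:
            raise ValueError("lai_range min must not exceed max")
        for refl in (self.veg_reflectance, self.soil_reflectance):
            if not all(0 <= v <= 1 for v in refl):
                raise ValueError("reflectances must lie in [0, 1]")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_points < 4:
            raise ValueError("n_points must be >= 4")


@dataclass
class SceneBundle:
    """A generated scene: rasters on one grid plus ground sample points."""

    scene: Raster           # 4-band reflectance, bands G, R, RE, NIR
    dsm0: Raster            # bare-soil surface model (m)
    dsm1: Raster            # jointing-stage surface model (m)
    truth_lai: Raster       # m2/m2, zero off the wheat mask
    truth_mask: Raster      # 1 = wheat, 0 = soil
    truth_ph: Raster        # cm, zero off the wheat mask
    points: list[SamplePoint]
    config: SceneConfig

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_geotiff(directory / "reflectance.tif", self.scene)
        write_geotiff(directory / "dsm0.tif", self.dsm0)
        write_geotiff(directory / "dsm1.tif", self.dsm1)
        write_geotiff(directory / "truth_lai.tif", self.truth_lai)
        write_geotiff(directory / "truth_mask.tif", self.truth_mask)
        write_geotiff(directory / "truth_ph.tif", self.truth_ph)
        write_points_csv(directory / "points.csv", self.points)
        import dataclasses
        import yaml
        (directory / "scene_config.yaml").write_text(
            yaml.safe_dump(dataclasses.asdict(self.config)))


def _lai_field(cfg: SceneConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth random field rank-mapped onto a truncated-normal LAI marginal."""
    lo, hi = cfg.lai_range
    shape = (cfg.height, cfg.width)
    if lo == hi:
        return np.full(shape, float(lo))
    base = ndimage.gaussian_filter(rng.standard_normal(shape),
                                   cfg.smooth_sigma_px, mode="reflect")
    ranks = stats.rankdata(base.ravel(), method="average")
    u = ranks / (base.size + 1)
    mean, sd = cfg.lai_mean_sd
    if sd <= 0:
        lai = np.full(base.size, float(np.clip(mean, lo, hi)))
    else:
        loc, scale = _moment_matched_truncnorm(lo, hi, mean, sd)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        lai = stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)
    return lai.reshape(shape)


def _moment_matched_truncnorm(lo: float, hi: float, mean: float, sd: float
                              ) -> tuple[float, float]:
    """(loc, scale) of a normal whose truncation to [lo, hi] has the target
    mean and SD; falls back to (mean, sd) when no solution exists (the SD of
    a truncated normal is bounded by the uniform limit)."""
    from scipy.optimize import fsolve

    def moments(params):
        loc, scale = params
        scale = abs(scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, float(np.sqrt(v)) - sd]

    try:
        sol, info, ier, _ = fsolve(moments, x0=[mean, sd], full_output=True)
        if ier == 1:
            return float(sol[0]), float(abs(sol[1]))
    except Exception:
        pass
    return mean, sd


def _wheat_mask(cfg: SceneConfig) -> np.ndarray:
    cols = np.arange(cfg.width)
    soil = (cols % cfg.soil_strip_period_px) < cfg.soil_strip_width_px
    return ~np.broadcast_to(soil, (cfg.height, cfg.width))


def generate_scene(config: SceneConfig) -> SceneBundle:
    """Generate a scene bundle; identical config (incl. seed) => identical bundle."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    transform = Affine.from_origin(0.0, cfg.height * cfg.resolution,
                                   cfg.resolution, cfg.resolution)
    grid = Raster(np.zeros((cfg.height, cfg.width)), transform, "local-metres")

    mask = _wheat_mask(cfg)
    lai = np.where(mask, _lai_field(cfg, rng), 0.0)

    ph = cfg.ph_slope * lai + cfg.ph_intercept
    if cfg.ph_noise_sd > 0:
        ph = ph + rng.normal(0.0, cfg.ph_noise_sd, lai.shape)
    ph = np.where(mask, np.clip(ph, 0.0, None), 0.0)

    yy, xx = np.mgrid[0:cfg.height, 0:cfg.width]
    terrain = cfg.base_elevation + 0.001 * xx * cfg.resolution
    smooth = ndimage.gaussian_filter(rng.standard_normal(lai.shape), 30.0,
                                     mode="reflect")
    scale = smooth.std()
    if scale > 0:
        terrain = terrain + cfg.terrain_amplitude * smooth / scale
    dsm0 = terrain
    dsm1 = dsm0 + ph / 100.0
    if cfg.dsm_noise_sd > 0:
        dsm1 = dsm1 + rng.normal(0.0, cfg.dsm_noise_sd, lai.shape)

    # Beer-Lambert canopy cover, modulated by the periodic seeding rows
    cover = 1.0 - np.exp(-cfg.extinction_k * lai)
    y_m = (yy + 0.5) * cfg.resolution
    rows_mod = 1.0 + cfg.row_amplitude * np.sin(2 * np.pi * y_m / cfg.row_spacing)
    cover = np.clip(cover * np.where(mask, rows_mod, 1.0), 0.0, 0.999)
    cover = np.where(mask, cover, 0.0)

    bands = []
    for b, name in enumerate(BAND_NAMES):
        veg = np.full(lai.shape, cfg.veg_reflectance[b])
        if name == "RE":
            # canopy red-edge reflectance declines as chlorophyll absorption
            # deepens with LAI; this is what gives red-edge indices (MTCI,
            # CLre, RERDVI) their LAI sensitivity
            floor = cfg.re_absorption_floor
            veg = floor + (cfg.veg_reflectance[b] - floor) * np.exp(
                -cfg.re_absorption_rate * lai)
        refl = cover * veg + (1.0 - cover) * cfg.soil_reflectance[b]
        if cfg.noise_sd > 0:
            refl = refl + rng.normal(0.0, cfg.noise_sd, lai.shape)
        bands.append(np.clip(refl, 0.0, 1.0))

    scene = Raster(np.stack(bands), transform, grid.crs, BAND_NAMES)
    bundle = SceneBundle(
        scene=scene,
        dsm0=grid.like(dsm0),
        dsm1=grid.like(dsm1),
        truth_lai=grid.like(lai),
        truth_mask=grid.like(mask.astype(float)),
        truth_ph=grid.like(ph),
        points=[],
        config=cfg,
    )
    bundle.points = sample_ground_truth(
        bundle, cfg.n_points, seed=int(rng.integers(2**31)),
        lai_noise_sd=cfg.lai_noise_sd, ph_noise_sd=cfg.ph_meas_noise_sd)
    return bundle


def sample_ground_truth(bundle: SceneBundle, n: int, seed: int,
                        lai_noise_sd: float | None = None,
                        ph_noise_sd: float | None = None) -> list[SamplePoint]:
    """Quasi-uniform ground samples over the wheat mask (stratified grid jitter).

    The scene is divided into a near-square grid of cells; one random wheat
    pixel is drawn per cell, cycling until ``n`` distinct pixels are chosen.
    Measured LAI/PH are the truth rasters at the pixel plus Gaussian
    measurement noise (defaults from the scene config).
    """
    cfg = bundle.config
    if lai_noise_sd is None:
        lai_noise_sd = cfg.lai_noise_sd
    if ph_noise_sd is None:
        ph_noise_sd = cfg.ph_meas_noise_sd
    mask = bundle.truth_mask.values > 0.5
    m = cfg.sample_margin_px
    inner = np.zeros_like(mask)
    if mask.shape[0] > 2 * m and mask.shape[1] > 2 * m:
        inner[m:mask.shape[0] - m, m:mask.shape[1] - m] = True
    # points sit inside the crop: the whole 50 cm measurement neighborhood
    # must be wheat, so erode the mask by the sampling margin
    if m > 0:
        yy, xx = np.mgrid[-m:m + 1, -m:m + 1]
        disk = (xx**2 + yy**2) <= m**2
        eroded = ndimage.binary_erosion(mask, structure=disk)
    else:
        eroded = mask
    candidates = eroded & inner
    if not candidates.any():
        candidates = mask & inner
    if not candidates.any():
        raise ValueError("wheat mask is empty; cannot place sample points")
    total = int(candidates.sum())
    if n > total:
        raise ValueError(f"requested {n} points but only {total} wheat pixels")

    rng = np.random.default_rng(seed)
    g = math.ceil(math.sqrt(n))
    rows_edges = np.linspace(0, mask.shape[0], g + 1).astype(int)
    cols_edges = np.linspace(0, mask.shape[1], g + 1).astype(int)
    cells = []
    for i in range(g):
        for j in range(g):
            rr, cc = np.nonzero(candidates[rows_edges[i]:rows_edges[i + 1],
                                           cols_edges[j]:cols_edges[j + 1]])
            if rr.size:
                cells.append((rows_edges[i] + rr, cols_edges[j] + cc))
    chosen: list[tuple[int, int]] = []
    seen: set[tuple[int, int]] = set()
    k = 0
    while len(chosen) < n:
        rr, cc = cells[k % len(cells)]
        for _ in range(10):
            idx = int(rng.integers(rr.size))
            px = (int(rr[idx]), int(cc[idx]))
            if px not in seen:
                seen.add(px)
                chosen.append(px)
                break
        k += 1

    lai_vals = bundle.truth_lai.values
    ph_vals = bundle.truth_ph.values
    points = []
    for pid, (r, c) in enumerate(chosen, start=1):
        x, y = bundle.truth_lai.transform.xy(r, c)
        lai = float(lai_vals[r, c])
        ph = float(ph_vals[r, c])
        if lai_noise_sd > 0:
            lai = max(0.0, lai + float(rng.normal(0, lai_noise_sd)))
        if ph_noise_sd > 0:
            ph = max(0.0, ph + float(rng.normal(0, ph_noise_sd)))
        points.append(SamplePoint(pid, float(x), float(y), lai, ph))
    return points
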