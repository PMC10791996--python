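"""GLCM texture rasters and texture indices.

Eight Haralick statistics (MEA, VAR, HOM, CON, DIS, ENT, SEC, COR) are
computed from a symmetric, normalized gray-level co-occurrence matrix inside a
moving window on each of the four bands, giving a 32-layer texture stack.
Pairs of layers combine into normalized-difference (NDTI), difference (DTI)
and ratio (RTI) texture indices:

    NDTI = (T1 - T2)/(T1 + T2),   DTI = T1 - T2,   RTI = T1/T2.

The raster path (:func:`texture_stack`) is a vectorized re-expression of the
per-window statistics over co-occurring pixel pairs; :func:`glcm_statistics`
is the direct single-window form that builds the co-occurrence matrix
explicitly, and the two are interchangeable on valid data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .indices import BAND_ORDER, BandSet
from .raster import Raster

STAT_NAMES: tuple[str, ...] = ("MEA", "VAR", "HOM", "CON", "DIS", "ENT", "SEC", "COR")
TI_KINDS: tuple[str, ...] = ("NDTI", "DTI", "RTI")


@dataclass(frozen=True)
class GLCMConfig:
    """Co-occurrence settings: window size, gray levels, pixel offset.

    Defaults follow common practice for fine-resolution canopy imagery:
    3x3 window, 64 gray levels, a one-pixel diagonal offset, symmetric
    counting.
    """

    window: int = 3
    levels: int = 64
    offset: tuple[int, int] = (1, 1)  # (dx, dy) = (column, row) shift
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.offset == (0, 0):
            raise ValueError("offset must be non-zero")
        if max(abs(self.offset[0]), abs(self.offset[1])) >= self.window:
            raise ValueError("offset must fit inside the window")


def quantize_band(raster: Raster, levels: int = 64) -> Raster:
    """Linear min-max quantization of valid values onto {0, ..., levels-1}.

    Values map to the nearest level index, ties rounding down; NaN is
    preserved.  A constant raster has no defined scaling and is rejected.
    """
    vals = raster.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("raster has no valid values")
    lo, hi = vals[finite].min(), vals[finite].max()
    if lo == hi:
        raise ValueError("quantization undefined for a constant raster")
    t = (vals - lo) / (hi - lo)
    with np.errstate(invalid="ignore"):
        q = np.ceil((levels - 1) * t - 0.5)
    q = np.clip(q, 0, levels - 1)
    return raster.like(np.where(finite, q, np.nan))


# ---------------------------------------------------------------------------
# Single-window statistics via the explicit co-occurrence matrix
# ---------------------------------------------------------------------------

def _pair_views(win: np.ndarray, dx: int, dy: int):
    """The two co-occurring sub-grids of a window under offset (dx, dy)."""
    h, w = win.shape[-2:]
    rows_a = slice(max(0, -dy), h - max(0, dy))
    rows_b = slice(max(0, dy), h - max(0, -dy))
    cols_a = slice(max(0, -dx), w - max(0, dx))
    cols_b = slice(max(0, dx), w - max(0, -dx))
    return win[..., rows_a, cols_a], win[..., rows_b, cols_b]


def glcm_statistics(window: np.ndarray, config: GLCMConfig) -> dict[str, float]:
    """The eight Haralick statistics of one quantized window.

    Builds the (symmetric, normalized) co-occurrence matrix p(i, j) for the
    configured offset and evaluates:
    MEA = sum i p, VAR = sum (i-mu)^2 p, HOM = sum p/(1+(i-j)^2),
    CON = sum (i-j)^2 p, DIS = sum |i-j| p, ENT = -sum p ln p,
    SEC = sum p^2, COR = sum (i-mu_i)(j-mu_j) p / (sigma_i sigma_j);
    a zero-variance window reports COR = 0.  NaN pixels contribute no pairs;
    a window with no valid pair returns all-NaN.
    """
    window = np.asarray(window, dtype=float)
    dx, dy = config.offset
    a, b = _pair_views(window, dx, dy)
    valid = np.isfinite(a) & np.isfinite(b)
    if not valid.any():
        return {s: np.nan for s in STAT_NAMES}
    i = a[valid].astype(int)
    j = b[valid].astype(int)
    L = config.levels
    p = np.zeros((L, L))
    np.add.at(p, (i, j), 1.0)
    if config.symmetric:
        np.add.at(p, (j, i), 1.0)
    p /= p.sum()
    lev = np.arange(L, dtype=float)
    ii = lev[:, None] * np.ones((1, L))
    jj = ii.T
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(lev @ pi)
    mu_j = float(lev @ pj)
    var_i = float(((lev - mu_i) ** 2) @ pi)
    var_j = float(((lev - mu_j) ** 2) @ pj)
    diff = ii - jj
    nz = p > 0
    cov = float((((ii - mu_i) * (jj - mu_j)) * p).sum())
    sigma = np.sqrt(var_i * var_j)
    return {
        "MEA": float((ii * p).sum()),
        "VAR": float((((ii - mu_i) ** 2) * p).sum()),
        "HOM": float((p / (1 + diff**2)).sum()),
        "CON": float(((diff**2) * p).sum()),
        "DIS": float((np.abs(diff) * p).sum()),
        "ENT": float(-(p[nz] * np.log(p[nz])).sum()),
        "SEC": float((p**2).sum()),
        "COR": cov / sigma if sigma > 0 else 0.0,
    }


# ---------------------------------------------------------------------------
# Moving-window texture stack (vectorized over windows)
# ---------------------------------------------------------------------------

def _window_stats_block(win: np.ndarray, config: GLCMConfig) -> dict[str, np.ndarray]:
    """Statistics of a block of windows, shape (..., w, w), NaN -> -1 sentinel."""
    dx, dy = config.offset
    a, b = _pair_views(win, dx, dy)
    a = a.reshape(a.shape[:-2] + (-1,))
    b = b.reshape(b.shape[:-2] + (-1,))
    if config.symmetric:
        # symmetric counting = every directed pair in both orders, equal weight
        x = np.concatenate([a, b], axis=-1)
        y = np.concatenate([b, a], axis=-1)
    else:
        x, y = a, b
    valid = (x >= 0) & (y >= 0)
    m = valid.sum(axis=-1).astype(float)  # valid directed pairs per window
    with np.errstate(invalid="ignore", divide="ignore"):
        def vmean(arr):
            return np.where(m > 0, (arr * valid).sum(axis=-1) / m, np.nan)

        mea = vmean(x)
        mea_y = vmean(y)
        var = vmean((x - mea[..., None]) ** 2)
        var_y = vmean((y - mea_y[..., None]) ** 2)
        diff = x - y
        con = vmean(diff**2)
        dis = vmean(np.abs(diff))
        hom = vmean(1.0 / (1.0 + diff**2))
        cov = vmean((x - mea[..., None]) * (y - mea_y[..., None]))
        sig = np.sqrt(var * var_y)
        cor = np.where(sig > 0, cov / np.where(sig > 0, sig, 1.0), 0.0)
        cor = np.where(m > 0, cor, np.nan)
        # cell probabilities via pairwise-equality counts of directed pairs
        code = np.where(valid, x * config.levels + y, -1 - np.arange(x.shape[-1]))
        eq = code[..., :, None] == code[..., None, :]
        cnt = eq.sum(axis=-1).astype(float)  # run size of each element's cell
        sec = np.where(m > 0, (cnt * valid).sum(axis=-1) / m**2, np.nan)
        logp = np.where(valid & (cnt > 0), np.log(np.where(cnt > 0, cnt, 1.0))
                        - np.log(np.where(m > 0, m, 1.0))[..., None], 0.0)
        ent = np.where(m > 0, -(logp * valid).sum(axis=-1) / m, np.nan)
    return {"MEA": mea, "VAR": var, "HOM": hom, "CON": con,
            "DIS": dis, "ENT": ent, "SEC": sec, "COR": cor}


def glcm_raster(raster: Raster, config: GLCMConfig = GLCMConfig(),
                block_rows: int = 256) -> dict[str, Raster]:
    """Eight texture-statistic rasters from one band.

    The band is quantized to ``config.levels`` gray levels over its valid
    range, then the statistics are evaluated in a moving ``window`` with the
    configured offset.  Border pixels without a full window are NaN.
    """
    w = config.window
    if w > min(raster.shape):
        raise ValueError("window larger than raster")
    vals = raster.values
    finite = np.isfinite(vals)
    if finite.any() and vals[finite].min() == vals[finite].max():
        # constant band: a single gray level (flat texture), not an error
        q = np.where(finite, 0.0, np.nan)
    else:
        q = quantize_band(raster, config.levels).values
    q = np.where(np.isfinite(q), q, -1.0)  # sentinel for invalid pixels
    windows = sliding_window_view(q, (w, w))
    hh, ww = windows.shape[:2]
    half = w // 2
    out = {s: np.full(raster.shape, np.nan) for s in STAT_NAMES}
    for r0 in range(0, hh, block_rows):
        r1 = min(hh, r0 + block_rows)
        stats = _window_stats_block(windows[r0:r1], config)
        for s in STAT_NAMES:
            out[s][half + r0:half + r1, half:half + ww] = stats[s]
    return {s: raster.like(out[s]) for s in STAT_NAMES}


@dataclass
class TextureStack:
    """32 texture layers: 8 statistics x 4 bands, on a shared grid."""

    layers: dict[tuple[str, str], Raster]  # keyed by (band, statistic)

    def __post_init__(self) -> None:
        if len(self.layers) != len(BAND_ORDER) * len(STAT_NAMES):
            raise ValueError("texture stack must hold exactly 32 layers")

    @property
    def names(self) -> list[tuple[str, str]]:
        return [(b, s) for b in BAND_ORDER for s in STAT_NAMES]

    def layer(self, band: str, stat: str) -> Raster:
        return self.layers[(band, stat)]

    def to_raster(self) -> Raster:
        """All layers as one multiband raster, bands named ``<band>_<stat>``."""
        names = self.names
        grid = self.layers[names[0]]
        data = np.stack([self.layers[k].values for k in names])
        return Raster(data, grid.transform, grid.crs,
                      tuple(f"{b}_{s}" for b, s in names))


def texture_stack(bands: BandSet, config: GLCMConfig = GLCMConfig()) -> TextureStack:
    """The full 32-layer texture stack of a band set."""
    layers: dict[tuple[str, str], Raster] = {}
    for band_name in BAND_ORDER:
        stats = glcm_raster(getattr(bands, band_name), config)
        for s in STAT_NAMES:
            layers[(band_name, s)] = stats[s]
    return TextureStack(layers)


# ---------------------------------------------------------------------------
# Texture indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TextureIndexDef:
    """A texture index: one of NDTI/DTI/RTI over two distinct texture layers."""

    kind: str
    t1: tuple[str, str]  # (band, statistic)
    t2: tuple[str, str]

    def __post_init__(self) -> None:
        if self.kind not in TI_KINDS:
            raise ValueError(f"kind must be one of {TI_KINDS}")
        if self.t1 == self.t2:
            raise ValueError("t1 and t2 must differ")

    @property
    def name(self) -> str:
        (b1, s1), (b2, s2) = self.t1, self.t2
        return f"{self.kind}_{s1}({b1})-{s2}({b2})"


def evaluate_index(kind: str, t1: np.ndarray, t2: np.ndarray) -> np.ndarray:
    """Pointwise NDTI/DTI/RTI of two aligned layer arrays (NaN at singularities)."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "NDTI":
            den = t1 + t2
            return np.where(den == 0, np.nan, (t1 - t2) / den)
        if kind == "DTI":
            return t1 - t2
        if kind == "RTI":
            return np.where(t2 == 0, np.nan, t1 / t2)
    raise ValueError(f"unknown texture-index kind {kind!r}")


def enumerate_texture_indices(stack: TextureStack | Sequence[tuple[str, str]]
                              ) -> list[TextureIndexDef]:
    """All texture-index definitions over the stack's layers.

    NDTI and DTI are antisymmetric in their arguments, so only unordered
    layer pairs are kept (C(32,2) = 496 each); RTI(T1, T2) and RTI(T2, T1)
    are reciprocal but distinct predictors, so both orders are kept
    (32*31 = 992).  32 layers therefore yield 1984 definitions.
    """
    names = list(stack.names if isinstance(stack, TextureStack) else stack)
    defs: list[TextureIndexDef] = []
    for kind in ("NDTI", "DTI"):
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                defs.append(TextureIndexDef(kind, names[i], names[j]))
    for i in range(len(names)):
        for j in range(len(names)):
            if i != j:
                defs.append(TextureIndexDef("RTI", names[i], names[j]))
    return defs


def compute_texture_index(defn: TextureIndexDef, stack: TextureStack) -> Raster:
    """Raster of one texture index over the stack's grid."""
    t1 = stack.layer(*defn.t1)
    t2 = stack.layer(*defn.t2)
    return t1.like(evaluate_index(defn.kind, t1.values, t2.values))


def texture_index_values(defs: Iterable[TextureIndexDef],
                         layer_values: Mapping[tuple[str, str], np.ndarray]
                         ) -> dict[str, np.ndarray]:
    """Texture-index values from per-point layer values.

    Index formulas are pointwise, so extracting layers at sample points and
    combining equals combining rasters and extracting (at zero radius).
    """
    return {d.name: evaluate_index(d.kind, layer_values[d.t1], layer_values[d.t2])
            for d in defs}
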