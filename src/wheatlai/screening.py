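"""Feature screening by Pearson correlation and SPXY sample partitioning.

Screening keeps features whose absolute Pearson correlation with measured
LAI reaches the threshold (0.80 by default, applied after rounding |r| to
two decimals) at significance alpha.

SPXY (sample-set partitioning based on joint x-y distance) extends the
Kennard-Stone algorithm with a distance blending the feature space and the
target:

    d_xy(p,q) = d_x(p,q)/max d_x + d_y(p,q)/max d_y,

with d_x the Euclidean feature distance and d_y = |y_p - y_q|.  The
calibration set starts from the most distant pair, then greedily adds the
sample whose minimum d_xy to the current set is largest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist


@dataclass
class FeatureTable:
    """Samples x named features plus the LAI target, aligned on sample ids."""

    features: pd.DataFrame
    target: pd.Series

    def __post_init__(self) -> None:
        if self.features.shape[1] < 1:
            raise ValueError("feature table needs at least one feature")
        if self.features.columns.duplicated().any():
            raise ValueError("feature names must be unique")
        self.target = self.target.reindex(self.features.index)
        if self.target.isna().any():
            raise ValueError("missing target values are not allowed")

    @property
    def n(self) -> int:
        return len(self.features)

    def subset(self, columns) -> "FeatureTable":
        return FeatureTable(self.features[list(columns)].copy(), self.target.copy())


@dataclass
class ScreenReport:
    """Per-feature correlation screening result."""

    table: pd.DataFrame  # columns: r, p, selected; index: feature names
    threshold: float
    alpha: float

    @property
    def selected(self) -> list[str]:
        return list(self.table.index[self.table["selected"]])


@dataclass
class SplitResult:
    """Disjoint, exhaustive calibration/validation sample-id partition."""

    calibration_ids: list
    validation_ids: list

    def __post_init__(self) -> None:
        if set(self.calibration_ids) & set(self.validation_ids):
            raise ValueError("calibration and validation sets overlap")


def pearson_screen(table: FeatureTable, threshold: float = 0.80,
                   alpha: float = 0.01) -> ScreenReport:
    """Two-sided Pearson screening of every feature against the target.

    A feature is selected when |r| rounded to two decimals reaches the
    threshold and the test p-value is below alpha.  Constant features are
    excluded with a warning; an all-constant table is an error.
    """
    n = table.n
    if n < 3:
        raise ValueError("need at least 3 samples for correlation screening")
    X = table.features.to_numpy(dtype=float)
    y = table.target.to_numpy(dtype=float)
    sd = X.std(axis=0)
    constant = sd == 0
    if constant.all():
        raise ValueError("all features are constant; nothing to screen")
    if constant.any():
        names = list(table.features.columns[constant])
        warnings.warn(f"excluding constant features: {names}", stacklevel=2)
    yc = y - y.mean()
    ysd = yc.std()
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        r = ((X - X.mean(axis=0)) * yc[:, None]).mean(axis=0) / (sd * ysd)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1 - r**2, np.finfo(float).tiny))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    r[constant] = np.nan
    p[constant] = np.nan
    selected = ~constant & (np.abs(np.round(r, 2)) >= threshold) & (p < alpha)
    frame = pd.DataFrame({"r": r, "p": p, "selected": selected},
                         index=table.features.columns)
    return ScreenReport(frame, threshold, alpha)


def spxy_distances(table: FeatureTable, standardize: bool = True) -> np.ndarray:
    """Pairwise joint x-y distance matrix d_xy over the table's samples."""
    X = table.features.to_numpy(dtype=float)
    y = table.target.to_numpy(dtype=float)
    if standardize:
        sd = X.std(axis=0)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    dx = cdist(X, X)
    dy = np.abs(y[:, None] - y[None, :])
    mx, my = dx.max(), dy.max()
    if mx == 0 and my == 0:
        raise ValueError("all samples identical; SPXY distance degenerate")
    dxy = np.zeros_like(dx)
    if mx > 0:
        dxy += dx / mx
    if my > 0:
        dxy += dy / my
    return dxy


def spxy_split(table: FeatureTable, cal_fraction: float = 0.7,
               standardize: bool = True) -> SplitResult:
    """SPXY calibration/validation split.

    Features are z-scored before the feature distance by default (the table
    mixes unitless indices with height in cm).  The calibration size is
    round(cal_fraction * N) (nearest, half up); ties in the greedy selection
    break toward the lowest sample index.
    """
    n = table.n
    if n < 3:
        raise ValueError("SPXY needs at least 3 samples")
    if not 0 < cal_fraction < 1:
        raise ValueError("cal_fraction must be in (0, 1)")
    n_cal = int(np.floor(cal_fraction * n + 0.5))
    if n_cal < 2 or n_cal >= n:
        raise ValueError(f"calibration size {n_cal} leaves no usable split")
    dxy = spxy_distances(table, standardize=standardize)
    ids = list(table.features.index)

    flat = int(np.argmax(dxy))  # first occurrence = lowest (p, q) on ties
    p, q = divmod(flat, n)
    selected = [p, q]
    in_cal = np.zeros(n, dtype=bool)
    in_cal[[p, q]] = True
    min_d = np.minimum(dxy[:, p], dxy[:, q])
    while len(selected) < n_cal:
        cand = np.where(in_cal, -np.inf, min_d)
        nxt = int(np.argmax(cand))
        selected.append(nxt)
        in_cal[nxt] = True
        min_d = np.minimum(min_d, dxy[:, nxt])
    calibration = [ids[i] for i in selected]
    validation = [ids[i] for i in range(n) if not in_cal[i]]
    return SplitResult(calibration, validation)
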