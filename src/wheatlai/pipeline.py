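"""End-to-end experiment: simulate -> features -> screen -> split -> fit ->
evaluate -> map.

The pipeline mirrors a UAV LAI-estimation campaign: generate (or load) a
scene, compute vegetation indices, the 32-layer texture stack and the
1984 texture indices, difference the surface models into plant height,
extract everything at the ground sample points, screen features against
measured LAI, split the samples with SPXY, fit the requested regressors on
each feature combination (VI, VITI, VIPH, VITIPH), and evaluate with
R^2 / RMSE / RPD on both sets.

Texture indices are pointwise functions of two texture layers, so per-point
TI values are computed from the 32 extracted layer values rather than by
materializing 1984 rasters; only indices selected for the final map are
rendered as rasters.
"""

from __future__ import annotations

import logging
import re
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .height import DEFAULT_PH_RADIUS_M, SurfaceModelPair, compute_ph, ph_at_points
from .indices import BandSet, VI_NAMES, compute_all_vi, compute_vi
from .models import (ALGORITHMS, EvalReport, FitResult, MaskReport, ModelSpec,
                     evaluate, evaluate_mask, fit_model, train_wheat_mask)
from .raster import Raster, SamplePoint, extract_at_points
from .screening import FeatureTable, ScreenReport, SplitResult, pearson_screen, spxy_split
from .synthetic import SceneBundle, SceneConfig, generate_scene
from .texture import (GLCMConfig, TextureIndexDef, TextureStack,
                      compute_texture_index, enumerate_texture_indices,
                      texture_index_values, texture_stack)

log = logging.getLogger("wheatlai")

COMBINATIONS: tuple[str, ...] = ("VI", "VITI", "VIPH", "VITIPH")

_TI_NAME_RE = re.compile(
    r"^(NDTI|DTI|RTI)_([A-Z]+)\((G|R|RE|NIR)\)-([A-Z]+)\((G|R|RE|NIR)\)$")


def parse_ti_name(name: str) -> TextureIndexDef:
    """Recover a TextureIndexDef from its canonical column name."""
    m = _TI_NAME_RE.match(name)
    if not m:
        raise ValueError(f"not a texture-index name: {name!r}")
    kind, s1, b1, s2, b2 = m.group(1), m.group(2), m.group(3), m.group(4), m.group(5)
    return TextureIndexDef(kind, (b1, s1), (b2, s2))


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce a run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    glcm: GLCMConfig = field(default_factory=GLCMConfig)
    threshold: float = 0.80
    alpha: float = 0.01
    cal_fraction: float = 0.7
    combinations: tuple[str, ...] = COMBINATIONS
    algorithms: tuple[str, ...] = ALGORITHMS
    seed: int = 42
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.combinations:
            raise ValueError("at least one feature combination is required")
        if not self.algorithms:
            raise ValueError("at least one algorithm is required")
        for c in self.combinations:
            if c not in COMBINATIONS:
                raise ValueError(f"unknown combination {c!r}")
        for a in self.algorithms:
            if a not in ALGORITHMS:
                raise ValueError(f"unknown algorithm {a!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scene = SceneConfig(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in raw.pop("scene", {}).items()})
        glcm_raw = raw.pop("glcm", {})
        if "offset" in glcm_raw:
            glcm_raw["offset"] = tuple(glcm_raw["offset"])
        glcm = GLCMConfig(**glcm_raw)
        for key in ("combinations", "algorithms"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(scene=scene, glcm=glcm, **raw)


@dataclass
class PointFeatures:
    """Per-point feature values plus the texture-index definitions used."""

    table: FeatureTable            # all candidate features incl. PH
    vi_names: list[str]
    ti_names: list[str]
    ti_defs: dict[str, TextureIndexDef]


def build_point_features(bundle: SceneBundle, glcm: GLCMConfig = GLCMConfig(),
                         stack: TextureStack | None = None) -> PointFeatures:
    """Feature table at the bundle's sample points.

    Spectral and texture features are read at the sample pixel (one 0.1 m
    cell); plant height averages pixels within 0.5 m, matching the field
    protocol.  Texture-index columns that are undefined (NaN) at any point
    are dropped from the candidate set.
    """
    bands = BandSet.from_scene(bundle.scene)
    points = bundle.points
    t0 = time.perf_counter()
    vi = compute_all_vi(bands)
    vi_cols = {name: extract_at_points(r, points, radius=0.0)
               for name, r in vi.items()}
    log.info("vegetation indices: %.1fs", time.perf_counter() - t0)

    t0 = time.perf_counter()
    if stack is None:
        stack = texture_stack(bands, glcm)
    layer_vals = {key: extract_at_points(stack.layer(*key), points, radius=0.0)
                  for key in stack.names}
    defs = enumerate_texture_indices(stack)
    ti_cols = texture_index_values(defs, layer_vals)
    log.info("texture stack + %d indices: %.1fs", len(defs), time.perf_counter() - t0)

    ph_raster = compute_ph(SurfaceModelPair(bundle.dsm0, bundle.dsm1))
    ph_vals = ph_at_points(ph_raster, points, radius=DEFAULT_PH_RADIUS_M)

    data = {**vi_cols, **ti_cols, "PH": ph_vals}
    frame = pd.DataFrame(data, index=[p.id for p in points])
    ti_names = [n for n in ti_cols if frame[n].notna().all()]
    dropped = len(ti_cols) - len(ti_names)
    if dropped:
        log.info("dropped %d texture indices undefined at some point", dropped)
    keep = list(vi_cols) + ti_names + ["PH"]
    y = pd.Series([p.lai for p in points], index=frame.index, name="LAI")
    table = FeatureTable(frame[keep], y)
    return PointFeatures(table, list(vi_cols), ti_names,
                         {d.name: d for d in defs})


def screen_features(feats: PointFeatures, threshold: float = 0.80,
                    alpha: float = 0.01) -> dict[str, ScreenReport]:
    """Screen VI and TI families separately; PH is reported but always kept."""
    vi_report = pearson_screen(feats.table.subset(feats.vi_names), threshold, alpha)
    ti_report = pearson_screen(feats.table.subset(feats.ti_names), threshold, alpha)
    ph_report = pearson_screen(feats.table.subset(["PH"]), threshold=0.0, alpha=1.0)
    return {"VI": vi_report, "TI": ti_report, "PH": ph_report}


def combination_columns(combination: str, screens: Mapping[str, ScreenReport]
                        ) -> list[str]:
    cols = list(screens["VI"].selected)
    if "TI" in combination:
        cols += screens["TI"].selected
    if "PH" in combination:
        cols.append("PH")
    return cols


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    results: pd.DataFrame
    screens: dict[str, ScreenReport]
    splits: dict[str, SplitResult]
    fits: dict[tuple[str, str], FitResult]
    mask_report: MaskReport | None
    features: PointFeatures
    bundle: SceneBundle


def run_experiment(config: ExperimentConfig,
                   bundle: SceneBundle | None = None) -> ExperimentResult:
    """Execute all stages; identical config (and seeds) => identical outputs
    for the deterministic algorithms.  Artifacts are written to
    ``config.output_dir`` when set."""
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    def stage(name):
        log.info("stage: %s", name)

    stage("simulate")
    if bundle is None:
        bundle = generate_scene(config.scene)
    stage("features")
    feats = build_point_features(bundle, config.glcm)
    stage("screen")
    screens = screen_features(feats, config.threshold, config.alpha)

    rows = []
    splits: dict[str, SplitResult] = {}
    fits: dict[tuple[str, str], FitResult] = {}
    for comb in config.combinations:
        cols = combination_columns(comb, screens)
        if not cols:
            raise RuntimeError(f"stage split: no features survive screening "
                               f"for combination {comb}")
        table = feats.table.subset(cols)
        stage(f"split [{comb}]")
        split = spxy_split(table, config.cal_fraction)
        splits[comb] = split
        X_cal = table.features.loc[split.calibration_ids]
        y_cal = table.target.loc[split.calibration_ids]
        X_val = table.features.loc[split.validation_ids]
        y_val = table.target.loc[split.validation_ids]
        for alg in config.algorithms:
            stage(f"train {alg} [{comb}]")
            t0 = time.perf_counter()
            fit = fit_model(ModelSpec(alg, seed=config.seed), X_cal, y_cal)
            fits[(comb, alg)] = fit
            for label, X, y in (("calibration", X_cal, y_cal),
                                ("validation", X_val, y_val)):
                rep = evaluate(y, fit.predict(X), label)
                rows.append({"combination": comb, "algorithm": alg,
                             **rep.as_dict()})
            log.info("%s/%s: %.1fs", comb, alg, time.perf_counter() - t0)

    results = pd.DataFrame(rows)

    mask_report = None
    try:
        stage("mask")
        bands = BandSet.from_scene(bundle.scene)
        mask_model = train_wheat_mask(bands, bundle.truth_mask, seed=config.seed)
        predicted = mask_model.predict_raster(bands)
        mask_report = evaluate_mask(predicted.values > 0.5,
                                    bundle.truth_mask.values > 0.5)
    except ValueError as exc:  # e.g. single-class synthetic scene
        log.warning("mask stage skipped: %s", exc)

    if out:
        feats.table.features.assign(LAI=feats.table.target).to_csv(
            out / "feature_table.csv")
        for fam, rep in screens.items():
            rep.table.to_csv(out / f"screen_{fam.lower()}.csv")
        split_rows = [{"combination": c, "set": s, "id": i}
                      for c, sp in splits.items()
                      for s, ids in (("calibration", sp.calibration_ids),
                                     ("validation", sp.validation_ids))
                      for i in ids]
        pd.DataFrame(split_rows).to_csv(out / "splits.csv", index=False)
        results.to_csv(out / "results.csv", index=False)
        if mask_report is not None:
            pd.DataFrame([{"OA": mask_report.oa, "kappa": mask_report.kappa}]
                         ).to_csv(out / "mask_report.csv", index=False)

    return ExperimentResult(config, results, screens, splits, fits,
                            mask_report, feats, bundle)


# ---------------------------------------------------------------------------
# Per-pixel LAI inversion map
# ---------------------------------------------------------------------------

def make_lai_map(fit: FitResult, bands: BandSet,
                 stack: TextureStack | None = None,
                 ph_raster: Raster | None = None,
                 mask: Raster | None = None,
                 chunk: int = 200_000) -> Raster:
    """Apply a trained model per pixel over the scene.

    Feature rasters are assembled from the fit's frozen feature names: VI
    names evaluate the index, texture-index names combine stack layers, and
    "PH" uses the height raster.  Prediction is restricted to wheat-mask
    pixels when a mask is given; everything else is NaN.
    """
    grids = []
    for name in fit.feature_names:
        if name in VI_NAMES or name == "OSAVI":
            grids.append(compute_vi(bands, name).values)
        elif name == "PH":
            if ph_raster is None:
                raise ValueError("fit uses PH but no height raster was given")
            grids.append(ph_raster.values)
        else:
            if stack is None:
                raise ValueError(f"fit uses {name!r} but no texture stack was given")
            grids.append(compute_texture_index(parse_ti_name(name), stack).values)
    feats = np.stack([g.ravel() for g in grids], axis=1)
    valid = np.isfinite(feats).all(axis=1)
    if mask is not None:
        valid &= (mask.values.ravel() > 0.5)
    out = np.full(feats.shape[0], np.nan)
    idx = np.flatnonzero(valid)
    for start in range(0, idx.size, chunk):
        sel = idx[start:start + chunk]
        out[sel] = fit.predict(feats[sel])
    return bands.grid.like(out.reshape(bands.grid.shape))


def render_lai_map(lai_map: Raster, path: str | Path,
                   title: str = "Estimated LAI") -> None:
    """Write a PNG rendering with a legend."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(lai_map.values, cmap="YlGn", interpolation="nearest")
    fig.colorbar(im, ax=ax, label="LAI (m$^2$/m$^2$)")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
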