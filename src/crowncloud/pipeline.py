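"""End-to-end orchestration: cloud → classification → rasters → crowns → metrics."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import crowncloud
from crowncloud import io as ccio
from crowncloud.classify import classify_by_cvi
from crowncloud.detect import (
    DetectionParams,
    crowns_to_frame,
    delineate_crowns,
    export_geojson,
    find_treetops,
)
from crowncloud.evaluate import Plot, aggregate, evaluate_plot
from crowncloud.ground import TinParams, densify_tin
from crowncloud.pointcloud import ColoredPointCloud
from crowncloud.rasters import (
    RasterGrid,
    _grid_for_extent,
    gaussian_smooth,
    make_chm,
    make_dem,
    write_ascii_grid,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the production settings
    (1 m cells, 7 m height cutoff, 2.5 m crown radius, 0.66 exclusion,
    TIN 10/0.5/1/0.05, 12.7 m plots)."""

    input: str = ""
    method: str = "cvi"  # or "tin"
    cell: float = 1.0
    sigma: float = 0.5
    detection: DetectionParams = field(default_factory=DetectionParams)
    tin: TinParams = field(default_factory=TinParams)
    match_dist: float = 2.5
    plot_radius: float = 12.7
    reference: str | None = None
    plots: str | None = None
    outdir: str = "crowncloud_out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectionParams(**raw.pop("detection", {}))
        tin = TinParams(**raw.pop("tin", {}))
        return cls(detection=det, tin=tin, **raw)


@dataclass
class PipelineResult:
    """In-memory products of one run."""

    dem: RasterGrid
    chm: RasterGrid
    chm_smoothed: RasterGrid
    crowns: list
    detections: pd.DataFrame
    metrics: dict | None


def classify_cloud(cloud: ColoredPointCloud, method: str,
                   tin: TinParams = TinParams()) -> ColoredPointCloud:
    """Points usable for the DEM under the chosen method: the nonvegetation
    class (color route) or the TIN ground class (elevation route)."""
    if method == "cvi":
        _, nonveg, _ = classify_by_cvi(cloud)
        return nonveg
    if method == "tin":
        labeled = densify_tin(cloud, params=tin)
        return labeled.subset(labeled.classes == "ground")
    raise ValueError(f"unknown method: {method!r} (expected 'cvi' or 'tin')")


def run(cloud: ColoredPointCloud, config: RunConfig,
        reference: "crowncloud.ReferenceTreeSet | None" = None,
        plots: pd.DataFrame | None = None) -> PipelineResult:
    """Run the full individualization chain on an in-memory cloud."""
    logger.info("classifying %d points with method=%s", len(cloud), config.method)
    dem_source = classify_cloud(cloud, config.method, config.tin)
    if len(dem_source) == 0:
        raise RuntimeError(f"classification ({config.method}) produced no DEM points")
    grid = _grid_for_extent(cloud.x, cloud.y, config.cell)
    dem = make_dem(dem_source, cell=config.cell, grid=grid)
    chm = make_chm(cloud, dem)
    chm_s = gaussian_smooth(chm, window=3, sigma=config.sigma)
    tops = find_treetops(chm_s, config.detection)
    logger.info("detected %d treetops", len(tops))
    crowns = delineate_crowns(chm, tops, config.detection)
    detections = crowns_to_frame(crowns)
    metrics = None
    if reference is not None and plots is not None and len(plots):
        per_plot = []
        det_xy = detections[["x", "y"]].to_numpy(float) if len(detections) \
            else np.empty((0, 2))
        for _, row in plots.iterrows():
            plot = Plot(id=int(row["id"]), x=float(row["x"]), y=float(row["y"]),
                        radius=float(row.get("radius", config.plot_radius)))
            per_plot.append(evaluate_plot(det_xy, reference, plot,
                                          max_dist=config.match_dist))
        metrics = aggregate(per_plot)
    return PipelineResult(dem=dem, chm=chm, chm_smoothed=chm_s, crowns=crowns,
                          detections=detections, metrics=metrics)


def run_pipeline(config: RunConfig) -> Path:
    """File-to-file pipeline: read inputs, run, write all artifacts.

    Writes DEM/CHM ASCII grids, a detections CSV and GeoJSON, a metrics JSON
    (when reference trees and plots are given), and a run manifest.
    Returns the output directory.
    """
    cloud = ccio.read_point_cloud(config.input)
    if len(cloud) == 0:
        raise RuntimeError(f"input cloud {config.input} is empty")
    reference = ccio.read_reference_trees(config.reference) if config.reference else None
    plots = ccio.read_plots(config.plots) if config.plots else None

    result = run(cloud, config, reference=reference, plots=plots)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(result.dem, outdir / f"dem_{config.method}.asc")
    write_ascii_grid(result.chm, outdir / f"chm_{config.method}.asc")
    result.detections.to_csv(outdir / "detections.csv", index=False,
                             float_format="%.3f")
    export_geojson(result.crowns, result.chm, outdir / "crowns.geojson")
    if result.metrics is not None:
        (outdir / "metrics.json").write_text(json.dumps(result.metrics, indent=2))
    manifest = {
        "version": crowncloud.__version__,
        "seed": config.seed,
        "method": config.method,
        "parameters": {
            "cell": config.cell, "sigma": config.sigma,
            "detection": asdict(config.detection), "tin": asdict(config.tin),
            "match_dist": config.match_dist, "plot_radius": config.plot_radius,
        },
        "n_points": len(cloud),
        "n_trees_detected": len(result.detections),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return outdir
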