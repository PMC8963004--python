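"""Treetop detection and crown delineation on the canopy height model.

Treetops are local maxima of the Gaussian-smoothed CHM: a cell is an apex
if its value is at least ``min_height`` (the search cutoff, 7 m by default
for a mature pine plantation) and is the maximum of the square window whose
half-width corresponds to the maximum expected crown radius (2.5 m).
Crowns are then grown around each apex on the *unsmoothed* CHM by seeded
region growing: a cell can belong to a crown only while it stays within
``max_radius`` of the apex and its height is at least ``exclusion`` times
the apex height (0.66 by default, i.e. cells below 66% of the tree's own
height are excluded from its crown).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from crowncloud.rasters import RasterGrid


@dataclass(frozen=True)
class DetectionParams:
    """Crown detection settings.

    min_height : meters — smallest apex height considered a tree (default 7).
    max_radius : meters — largest crown radius grown around an apex (default 2.5).
    exclusion : fraction — cells below ``exclusion * apex height`` are
        excluded from that tree's crown (default 0.66).
    """

    min_height: float = 7.0
    max_radius: float = 2.5
    exclusion: float = 0.66

    def __post_init__(self) -> None:
        if self.min_height <= 0:
            raise ValueError("min_height must be positive")
        if self.max_radius <= 0:
            raise ValueError("max_radius must be positive")
        if not 0.0 <= self.exclusion <= 1.0:
            raise ValueError("exclusion must lie in [0, 1]")


@dataclass(frozen=True)
class TreeTop:
    """Detected apex: grid cell, its center coordinates and height."""

    i: int
    j: int
    x: float
    y: float
    height: float


@dataclass
class Crown:
    """Delineated crown: the owning apex, member cells and their centroid."""

    top: TreeTop
    cells: list[tuple[int, int]] = field(default_factory=list)
    centroid_x: float = float("nan")
    centroid_y: float = float("nan")
    area: float = float("nan")


def find_treetops(chm_smoothed: RasterGrid,
                  params: DetectionParams = DetectionParams()) -> list[TreeTop]:
    """Local-maximum apex search on the smoothed CHM.

    A cell is an apex iff its value is >= ``min_height`` and >= every cell
    of the square window of half-width ``round(max_radius / cell)`` centered
    on it.  Among equal-valued plateau cells inside one window only the
    first in row-major order is kept.  The result is sorted by descending
    apex height, ties by row-major cell index.
    """
    values = chm_smoothed.values
    half = int(round(params.max_radius / chm_smoothed.cell))
    size = 2 * half + 1
    local_max = ndimage.maximum_filter(values, size=size, mode="constant", cval=-np.inf)
    candidate = (values >= params.min_height) & (values >= local_max)
    tops: list[TreeTop] = []
    kept = np.zeros_like(candidate)
    for i, j in zip(*np.nonzero(candidate)):  # nonzero is row-major
        i0, i1 = max(0, i - half), min(values.shape[0], i + half + 1)
        j0, j1 = max(0, j - half), min(values.shape[1], j + half + 1)
        window_kept = kept[i0:i1, j0:j1]
        if np.any(window_kept & (values[i0:i1, j0:j1] == values[i, j])):
            continue  # plateau twin of an already-kept apex
        kept[i, j] = True
        x, y = chm_smoothed.cell_center(i, j)
        tops.append(TreeTop(int(i), int(j), float(x), float(y), float(values[i, j])))
    tops.sort(key=lambda t: (-t.height, t.i, t.j))
    return tops


def delineate_crowns(chm: RasterGrid, treetops: list[TreeTop],
                     params: DetectionParams = DetectionParams()) -> list[Crown]:
    """Seeded region growing of crowns on the unsmoothed CHM.

    Cells are visited in descending CHM order; a cell joins crown ``k`` when
    it is 4-connected to ``k``'s current cells, lies within ``max_radius``
    of ``k``'s apex (Euclidean distance between cell centers), has height
    >= ``exclusion`` × apex height, and is still unassigned.  A cell
    reachable by several crowns goes to the planimetrically nearest apex
    (ties to the higher apex).  Each crown's centroid is the unweighted mean
    of its member cell centers.
    """
    values = chm.values
    n_rows, n_cols = values.shape
    for top in treetops:
        if not (0 <= top.i < n_rows and 0 <= top.j < n_cols):
            raise ValueError(f"treetop cell ({top.i}, {top.j}) outside the grid")
    owner = np.full(values.shape, -1, dtype=np.int64)
    crowns = [Crown(top=t, cells=[(t.i, t.j)]) for t in treetops]
    for k, t in enumerate(treetops):
        owner[t.i, t.j] = k

    cx, cy = np.meshgrid(np.arange(n_cols), np.arange(n_rows))
    centers_x, centers_y = chm.cell_center(cy, cx)

    # descending-height visiting order, row-major on ties, swept repeatedly
    # until no cell changes hands (growth is monotone, so this terminates)
    flat_order = np.argsort(-values.ravel(), kind="stable")
    order_ij = np.column_stack(np.unravel_index(flat_order, values.shape))

    def eligible_crowns(i: int, j: int) -> list[int]:
        out = []
        for di, dj in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            ni, nj = i + di, j + dj
            if 0 <= ni < n_rows and 0 <= nj < n_cols and owner[ni, nj] >= 0:
                k = owner[ni, nj]
                if k in out:
                    continue
                t = treetops[k]
                dist = np.hypot(centers_x[i, j] - t.x, centers_y[i, j] - t.y)
                if dist <= params.max_radius and \
                        values[i, j] >= params.exclusion * t.height:
                    out.append(k)
        return out

    changed = True
    while changed:
        changed = False
        for i, j in order_ij:
            if owner[i, j] >= 0:
                continue
            cands = eligible_crowns(int(i), int(j))
            if not cands:
                continue
            if len(cands) > 1:
                def sort_key(k: int) -> tuple[float, float]:
                    t = treetops[k]
                    return (np.hypot(centers_x[i, j] - t.x, centers_y[i, j] - t.y),
                            -t.height)
                cands.sort(key=sort_key)
            k = cands[0]
            owner[i, j] = k
            crowns[k].cells.append((int(i), int(j)))
            changed = True

    for crown in crowns:
        cells = np.array(crown.cells)
        xs, ys = chm.cell_center(cells[:, 0], cells[:, 1])
        crown.centroid_x = float(np.mean(xs))
        crown.centroid_y = float(np.mean(ys))
        crown.area = len(cells) * chm.cell ** 2
    return crowns


def crowns_to_frame(crowns: list[Crown]) -> pd.DataFrame:
    """Tabular summary: one row per crown (id, apex, centroid, area)."""
    rows = [{
        "id": k,
        "apex_x": c.top.x, "apex_y": c.top.y, "height": c.top.height,
        "x": c.centroid_x, "y": c.centroid_y, "area": c.area,
        "n_cells": len(c.cells),
    } for k, c in enumerate(crowns)]
    return pd.DataFrame(rows, columns=["id", "apex_x", "apex_y", "height",
                                       "x", "y", "area", "n_cells"])


def export_treetops_csv(crowns: list[Crown], path: str | Path) -> Path:
    path = Path(path)
    crowns_to_frame(crowns).to_csv(path, index=False, float_format="%.3f")
    return path


def export_geojson(crowns: list[Crown], chm: RasterGrid, path: str | Path) -> Path:
    """Crowns as GeoJSON: apex points plus cell-union crown polygons."""
    features = []
    c = chm.cell
    for k, crown in enumerate(crowns):
        features.append({
            "type": "Feature",
            "properties": {"id": k, "kind": "treetop", "height": crown.top.height},
            "geometry": {"type": "Point", "coordinates": [crown.top.x, crown.top.y]},
        })
        polys = []
        for (i, j) in crown.cells:
            x0 = chm.x0 + j * c
            y1 = chm.y0 - i * c
            polys.append([[x0, y1 - c], [x0 + c, y1 - c], [x0 + c, y1], [x0, y1],
                          [x0, y1 - c]])
        features.append({
            "type": "Feature",
            "properties": {"id": k, "kind": "crown", "area": crown.area,
                           "centroid": [crown.centroid_x, crown.centroid_y]},
            "geometry": {"type": "MultiPolygon",
                         "coordinates": [[ring] for ring in polys]},
        })
    path = Path(path)
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
    return path
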