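"""Shared synthetic scenes.

Session-scoped because scene generation and the TIN filter are the slow
parts; every test treats the fixtures as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from crowncloud.rasters import RasterGrid
from crowncloud.simulate import ForestScene, SceneSample, generate_scene, plantation_layout


@pytest.fixture(scope="session")
def small_scene() -> SceneSample:
    """3×3 plantation, 22×22 m, modest density — quick classification checks."""
    trees = plantation_layout(3, 3, spacing=6.0, seed=1)
    scene = ForestScene(extent=(0, 22, 0, 22), trees=trees, density=25, seed=1)
    return generate_scene(scene)


@pytest.fixture(scope="session")
def plantation50() -> tuple[SceneSample, ForestScene]:
    """The 50-tree jittered-grid plantation used for end-to-end recovery."""
    trees = plantation_layout(5, 10, spacing=6.0, seed=7)
    scene = ForestScene(extent=(0, 64, 0, 34), trees=trees, density=25, seed=7)
    return generate_scene(scene), scene


@pytest.fixture(scope="session")
def shrub_scene() -> tuple[SceneSample, ForestScene]:
    """Dense ~0.3 m understory with 70% ground occlusion under crowns —
    the conditions under which elevation-based ground filtering degrades."""
    trees = plantation_layout(4, 6, spacing=6.0, seed=11)
    scene = ForestScene(extent=(0, 40, 0, 28), trees=trees, density=25, seed=11,
                        understory=True, occlusion=0.7,
                        shrub_height_range=(0.25, 0.35), shrub_cover=1.0)
    return generate_scene(scene), scene


def dem_rmse(dem: RasterGrid, terrain) -> float:
    """RMSE of a DEM against the scene's terrain oracle at cell centers."""
    ii, jj = np.meshgrid(np.arange(dem.n_rows), np.arange(dem.n_cols), indexing="ij")
    cx, cy = dem.cell_center(ii, jj)
    return float(np.sqrt(np.mean((dem.values - terrain(cx, cy)) ** 2)))
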