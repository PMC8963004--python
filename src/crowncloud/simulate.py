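"""Synthetic plantation scenes with known ground truth.

The generator emulates what UAV photogrammetric densification sees over a
planted conifer stand: a smooth terrain surface (plane plus low-frequency
sinusoids), cone- or paraboloid-shaped crowns sampled as green-tinted
points, brown/gray ground points thinned under dense canopy (the
photogrammetric occlusion that makes ground filtering hard), and an
optional green understory 0.2-0.5 m above the terrain — the layer that a
progressive-TIN filter erroneously accepts as ground but a color index
rejects.

All randomness flows from the scene's single seed through one
``numpy.random.Generator``; a scene generates bit-identically across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd

from crowncloud.pointcloud import ColoredPointCloud, ReferenceTreeSet

#: Mean 8-bit colors; chosen so canopy mean NGRDI is ~+0.27 and ground ~-0.13.
CANOPY_COLOR = (80, 140, 60)
GROUND_COLOR = (130, 100, 80)
SHRUB_COLOR = (90, 135, 70)


@dataclass
class ForestScene:
    """Declarative description of a synthetic plantation.

    Parameters
    ----------
    extent : (xmin, xmax, ymin, ymax), meters.
    trees : DataFrame with columns ``id, x, y, height, radius, shape``
        (shape in {"cone", "paraboloid"}).
    density : points per m² of footprint (default 79, a typical UAV
        photogrammetric densification at 100 m flight height).
    base_elevation, slope : terrain plane, meters and m/m.
    relief_amplitude, relief_wavelength : sinusoidal terrain undulation.
    color_noise_sd : per-channel Gaussian color noise, 8-bit counts.
    ground_noise_sd : vertical roughness of the terrain returns, meters.
    occlusion : fraction of ground points removed under crown footprints.
    understory : add a green shrub layer over the whole extent.
    shrub_height_range : shrub heights above the terrain, meters.
    shrub_cover : shrub point density as a fraction of ``density``.
    crown_depth_fraction : crown vertical extent as a fraction of tree height.
    interior_fraction : extra interior-scatter points as a fraction of the
        crown surface points (photogrammetric noise inside the crown).
    min_spacing : smallest allowed stem separation; closer stems are an error.
    seed : RNG seed; generation is bit-reproducible given the seed.
    """

    extent: tuple[float, float, float, float] = (0.0, 50.0, 0.0, 50.0)
    trees: pd.DataFrame = dc_field(default_factory=lambda: pd.DataFrame(
        columns=["id", "x", "y", "height", "radius", "shape"]))
    density: float = 79.0
    base_elevation: float = 100.0
    slope: tuple[float, float] = (0.02, -0.01)
    relief_amplitude: float = 0.5
    relief_wavelength: float = 40.0
    color_noise_sd: float = 12.0
    ground_noise_sd: float = 0.05
    occlusion: float = 0.5
    understory: bool = False
    shrub_height_range: tuple[float, float] = (0.2, 0.5)
    shrub_cover: float = 1.0
    crown_depth_fraction: float = 0.6
    interior_fraction: float = 0.2
    min_spacing: float = 1.0
    seed: int = 0

    def terrain(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Ground-truth terrain elevation at planimetric positions."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        w = 2.0 * np.pi / self.relief_wavelength
        return (self.base_elevation
                + self.slope[0] * x + self.slope[1] * y
                + self.relief_amplitude * (np.sin(w * x) * np.cos(w * y)))


class SceneSample(NamedTuple):
    """A generated scene: the cloud, the stem ground truth, the terrain
    oracle, and each point's true provenance ("ground"/"canopy"/"shrub")."""

    cloud: ColoredPointCloud
    trees: ReferenceTreeSet
    terrain: Callable[[np.ndarray, np.ndarray], np.ndarray]
    provenance: np.ndarray


def plantation_layout(n_rows: int, n_cols: int, spacing: float = 6.0,
                      jitter: float = 0.8,
                      height_range: tuple[float, float] = (15.0, 25.0),
                      radius_range: tuple[float, float] = (2.0, 2.5),
                      origin: tuple[float, float] = (5.0, 5.0),
                      shape: str = "cone", seed: int = 0) -> pd.DataFrame:
    """Jittered-grid plantation: ``n_rows`` × ``n_cols`` stems.

    Heights and radii are drawn uniformly from their ranges; planimetric
    jitter is uniform in ``[-jitter, jitter]`` per axis.
    """
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for i in range(n_rows):
        for j in range(n_cols):
            rows.append({
                "id": k,
                "x": origin[0] + j * spacing + rng.uniform(-jitter, jitter),
                "y": origin[1] + i * spacing + rng.uniform(-jitter, jitter),
                "height": rng.uniform(*height_range),
                "radius": rng.uniform(*radius_range),
                "shape": shape,
            })
            k += 1
    return pd.DataFrame(rows)


def _crown_points(rng: np.random.Generator, stem_x: float, stem_y: float,
                  z_ground: float, height: float, radius: float, shape: str,
                  depth_fraction: float, interior_fraction: float,
                  density: float) -> np.ndarray:
    """Sample one crown as (n, 3) coordinates; includes the exact apex."""
    z_apex = z_ground + height
    depth = depth_fraction * height
    n_surface = rng.poisson(density * np.pi * radius ** 2)
    rho = radius * np.sqrt(rng.uniform(0.0, 1.0, n_surface))
    theta = rng.uniform(0.0, 2.0 * np.pi, n_surface)
    frac = rho / radius
    if shape == "cone":
        drop = depth * frac
    elif shape == "paraboloid":
        drop = depth * frac ** 2
    else:
        raise ValueError(f"unknown crown shape: {shape!r}")
    xs = stem_x + rho * np.cos(theta)
    ys = stem_y + rho * np.sin(theta)
    zs = z_apex - drop
    n_interior = rng.poisson(interior_fraction * max(n_surface, 1))
    if n_interior:
        rho_i = radius * np.sqrt(rng.uniform(0.0, 1.0, n_interior))
        theta_i = rng.uniform(0.0, 2.0 * np.pi, n_interior)
        frac_i = rho_i / radius
        drop_i = depth * (frac_i if shape == "cone" else frac_i ** 2)
        z_top = z_apex - drop_i
        z_int = rng.uniform(z_apex - depth, z_top)
        xs = np.concatenate([xs, stem_x + rho_i * np.cos(theta_i)])
        ys = np.concatenate([ys, stem_y + rho_i * np.sin(theta_i)])
        zs = np.concatenate([zs, z_int])
    # the apex itself, exactly: the photogrammetric surface always sees it
    xs = np.concatenate([xs, [stem_x]])
    ys = np.concatenate([ys, [stem_y]])
    zs = np.concatenate([zs, [z_apex]])
    return np.column_stack([xs, ys, np.minimum(zs, z_apex)])


def _colorize(rng: np.random.Generator, n: int, mean: tuple[int, int, int],
              sd: float) -> np.ndarray:
    rgb = np.array(mean, dtype=float) + rng.normal(0.0, sd, size=(n, 3))
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def generate_scene(scene: ForestScene) -> SceneSample:
    """Sample a colored point cloud from a scene description.

    Raises
    ------
    ValueError
        If any two stems are closer than ``scene.min_spacing`` or any stem
        lies outside the extent.
    """
    rng = np.random.default_rng(scene.seed)
    xmin, xmax, ymin, ymax = scene.extent
    trees = scene.trees.reset_index(drop=True)
    if len(trees):
        tx = trees["x"].to_numpy(float)
        ty = trees["y"].to_numpy(float)
        if (tx < xmin).any() or (tx > xmax).any() or (ty < ymin).any() or (ty > ymax).any():
            raise ValueError("tree stems must lie inside the scene extent")
        if len(trees) > 1:
            d = np.hypot(tx[:, None] - tx[None, :], ty[:, None] - ty[None, :])
            np.fill_diagonal(d, np.inf)
            if d.min() < scene.min_spacing:
                raise ValueError(
                    f"stems closer than min_spacing={scene.min_spacing} m "
                    f"(closest pair at {d.min():.2f} m)")

    area = (xmax - xmin) * (ymax - ymin)
    coords: list[np.ndarray] = []
    colors: list[np.ndarray] = []
    prov: list[np.ndarray] = []

    # ground returns: uniform over the extent, thinned under crowns
    n_ground = rng.poisson(scene.density * area)
    gx = rng.uniform(xmin, xmax, n_ground)
    gy = rng.uniform(ymin, ymax, n_ground)
    gz = scene.terrain(gx, gy) + rng.normal(0.0, scene.ground_noise_sd, n_ground)
    keep = np.ones(n_ground, dtype=bool)
    if len(trees) and scene.occlusion > 0:
        under = np.zeros(n_ground, dtype=bool)
        for _, t in trees.iterrows():
            under |= np.hypot(gx - t["x"], gy - t["y"]) <= t["radius"]
        keep[under] = rng.uniform(size=int(under.sum())) >= scene.occlusion
    coords.append(np.column_stack([gx[keep], gy[keep], gz[keep]]))
    colors.append(_colorize(rng, int(keep.sum()), GROUND_COLOR, scene.color_noise_sd))
    prov.append(np.full(int(keep.sum()), "ground", dtype="U6"))

    # understory shrub layer
    if scene.understory:
        n_shrub = rng.poisson(scene.density * scene.shrub_cover * area)
        sx = rng.uniform(xmin, xmax, n_shrub)
        sy = rng.uniform(ymin, ymax, n_shrub)
        sz = scene.terrain(sx, sy) + rng.uniform(*scene.shrub_height_range, n_shrub)
        coords.append(np.column_stack([sx, sy, sz]))
        colors.append(_colorize(rng, n_shrub, SHRUB_COLOR, scene.color_noise_sd))
        prov.append(np.full(n_shrub, "shrub", dtype="U6"))

    # crowns
    for _, t in trees.iterrows():
        z_ground = float(scene.terrain(t["x"], t["y"]))
        pts = _crown_points(rng, float(t["x"]), float(t["y"]), z_ground,
                            float(t["height"]), float(t["radius"]),
                            str(t["shape"]), scene.crown_depth_fraction,
                            scene.interior_fraction, scene.density)
        coords.append(pts)
        colors.append(_colorize(rng, len(pts), CANOPY_COLOR, scene.color_noise_sd))
        prov.append(np.full(len(pts), "canopy", dtype="U6"))

    xyz = np.vstack(coords)
    rgb = np.vstack(colors)
    cloud = ColoredPointCloud(xyz[:, 0], xyz[:, 1], xyz[:, 2],
                              rgb[:, 0], rgb[:, 1], rgb[:, 2])
    ref = ReferenceTreeSet(trees[["id", "x", "y"]].copy())
    return SceneSample(cloud=cloud, trees=ref, terrain=scene.terrain,
                       provenance=np.concatenate(prov))
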