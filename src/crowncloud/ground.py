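"""Progressive TIN densification ground filter.

The conventional elevation-based baseline: seed a sparse terrain model with
the lowest point of every ``step`` × ``step`` grid cell, triangulate the
seeds, and iteratively accept unlabeled points that sit close enough to the
current triangulated surface — within ``bulge`` meters above or ``spike``
meters below a facet.  After the densification loop converges, a terminal
sweep also accepts every point within ``offset`` meters above the final
surface.  Defaults follow the settings customary for UAV photogrammetric
clouds over plantations: step 10 m, bulge 0.5 m, spike 1 m, offset 0.05 m.

The known failure mode of this filter — and the reason the color-index
route exists — is that low dense vegetation within ``bulge`` of the terrain
is accepted as ground, inflating the DEM under shrubs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from crowncloud.pointcloud import ColoredPointCloud


@dataclass(frozen=True)
class TinParams:
    """Densification tolerances, all in meters."""

    step: float = 10.0
    bulge: float = 0.5
    spike: float = 1.0
    offset: float = 0.05

    def __post_init__(self) -> None:
        for name in ("step", "bulge", "spike", "offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.offset > self.spike:
            raise ValueError("offset must not exceed spike")


def select_seeds(cloud: ColoredPointCloud, step: float = 10.0,
                 spike: float = 1.0) -> np.ndarray:
    """Indices of seed points: the lowest point of each non-empty grid cell.

    A seed whose elevation deviates from the median of its 8 neighboring
    cells' seeds by more than ``spike`` is discarded (removes birds and
    low-noise outliers before triangulation).
    """
    n = len(cloud)
    if n < 3:
        raise ValueError("need at least 3 points to seed a triangulation")
    ci = np.floor((cloud.x - cloud.x.min()) / step).astype(np.int64)
    cj = np.floor((cloud.y - cloud.y.min()) / step).astype(np.int64)
    seeds: dict[tuple[int, int], int] = {}
    for idx in range(n):
        key = (int(ci[idx]), int(cj[idx]))
        best = seeds.get(key)
        if best is None or cloud.z[idx] < cloud.z[best] or (
                cloud.z[idx] == cloud.z[best] and idx < best):
            seeds[key] = idx
    kept = []
    for (i, j), idx in sorted(seeds.items()):
        neigh = [cloud.z[seeds[(i + di, j + dj)]]
                 for di in (-1, 0, 1) for dj in (-1, 0, 1)
                 if (di, dj) != (0, 0) and (i + di, j + dj) in seeds]
        if neigh and abs(cloud.z[idx] - float(np.median(neigh))) > spike:
            continue
        kept.append(idx)
    return np.array(sorted(kept), dtype=np.int64)


def _facet_heights(tri: Delaunay, z_ground: np.ndarray,
                   xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interpolated TIN surface height under each query point.

    Points inside the hull use their containing facet; points outside use
    the plane of a facet incident to the nearest triangulated vertex,
    extended planimetrically.  Returns (surface height, inside-hull mask).
    """
    simplex = tri.find_simplex(xy)
    inside = simplex >= 0
    surface = np.empty(len(xy))
    if inside.any():
        s = simplex[inside]
        transform = tri.transform[s]
        bary2 = np.einsum("ijk,ik->ij", transform[:, :2, :],
                          xy[inside] - transform[:, 2, :])
        bary = np.column_stack([bary2, 1.0 - bary2.sum(axis=1)])
        surface[inside] = np.einsum("ij,ij->i", bary,
                                    z_ground[tri.simplices[s]])
    if (~inside).any():
        tree = cKDTree(tri.points)
        _, nearest = tree.query(xy[~inside])
        # first simplex listed for the nearest vertex; plane extension
        vertex_simplices = tri.vertex_to_simplex[nearest]
        verts = tri.simplices[vertex_simplices]
        p = np.dstack([tri.points[verts], z_ground[verts][..., None]])
        # plane through the 3 vertices of the facet
        v1 = p[:, 1] - p[:, 0]
        v2 = p[:, 2] - p[:, 0]
        normal = np.cross(v1, v2)
        # vertical facets would have normal[...,2]==0; Delaunay facets cannot
        q = xy[~inside]
        surface[~inside] = p[:, 0, 2] - (
            normal[:, 0] * (q[:, 0] - p[:, 0, 0])
            + normal[:, 1] * (q[:, 1] - p[:, 0, 1])
        ) / normal[:, 2]
    return surface, inside


def densify_tin(cloud: ColoredPointCloud, seeds: np.ndarray | None = None,
                params: TinParams = TinParams()) -> ColoredPointCloud:
    """Label ground points by iterative TIN densification.

    Returns a copy of the cloud with ``classes`` set to ``"ground"`` /
    ``"unclassified"``.

    Raises
    ------
    ValueError
        If the seeds are collinear (no triangulation exists).
    """
    if seeds is None:
        seeds = select_seeds(cloud, step=params.step, spike=params.spike)
    xy = np.column_stack([cloud.x, cloud.y])
    z = cloud.z
    is_ground = np.zeros(len(cloud), dtype=bool)
    is_ground[seeds] = True
    if is_ground.sum() < 3:
        raise ValueError("need at least 3 seed points")

    def triangulate() -> Delaunay:
        pts = xy[is_ground]
        try:
            tri = Delaunay(pts)
        except Exception as exc:  # QhullError on degenerate input
            raise ValueError(f"degenerate (collinear) seed geometry: {exc}") from exc
        if tri.simplices.size == 0:
            raise ValueError("degenerate (collinear) seed geometry")
        return tri

    # densification passes: accept points within bulge above / spike below
    # the current surface, re-triangulating between passes
    while True:
        tri = triangulate()
        candidates = np.flatnonzero(~is_ground)
        if candidates.size == 0:
            break
        order = candidates[np.argsort(z[candidates], kind="stable")]
        surface, inside = _facet_heights(tri, z[is_ground], xy[order])
        dz = z[order] - surface
        accept = inside & (dz <= params.bulge) & (-dz <= params.spike)
        if not accept.any():
            break
        is_ground[order[accept]] = True

    # terminal sweep: anything within offset above the final surface is
    # ground, including points outside the seed hull (plane extension)
    tri = triangulate()
    remaining = np.flatnonzero(~is_ground)
    if remaining.size:
        surface, _ = _facet_heights(tri, z[is_ground], xy[remaining])
        dz = z[remaining] - surface
        accept = (dz <= params.offset) & (-dz <= params.spike)
        is_ground[remaining[accept]] = True

    classes = np.where(is_ground, "ground", "unclassified").astype("U13")
    return cloud.with_classes(classes)
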