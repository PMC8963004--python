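"""Colored point cloud and reference tree containers.

Coordinates are planimetric meters in a projected CRS; the CRS itself is
carried as opaque metadata and never transformed.  Colors are 8-bit RGB as
produced by photogrammetric densification of UAV imagery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Allowed per-point class labels.
CLASS_LABELS = ("unclassified", "vegetation", "nonvegetation", "ground")

#: ASPRS LAS classification codes used on disk (2 = ground, 4 = medium vegetation).
LAS_CLASS_CODES = {"unclassified": 1, "ground": 2, "nonvegetation": 2, "vegetation": 4}
LAS_CODE_LABELS = {1: "unclassified", 2: "ground", 4: "vegetation"}


@dataclass
class ColoredPointCloud:
    """3D points with 8-bit RGB color and an optional per-point class label.

    Parameters
    ----------
    x, y, z : ndarray of float
        Coordinates in meters (projected CRS).
    red, green, blue : ndarray of int
        Color channels, integers in [0, 255].
    classes : ndarray of str, optional
        Per-point label, one of ``CLASS_LABELS``.  ``None`` means the cloud
        is entirely unclassified.
    crs : str, optional
        Free-form CRS description (metadata only).
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    classes: np.ndarray | None = None
    crs: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        n = self.x.size
        if not (self.y.size == self.z.size == n):
            raise ValueError("coordinate arrays must have equal length")
        for name in ("red", "green", "blue"):
            chan = np.asarray(getattr(self, name))
            if chan.size != n:
                raise ValueError(f"color channel {name!r} length mismatch")
            if n and (chan.min() < 0 or chan.max() > 255):
                raise ValueError(f"color channel {name!r} outside [0, 255]")
            setattr(self, name, chan.astype(np.uint8))
        if self.classes is not None:
            self.classes = np.asarray(self.classes, dtype="U13")
            if self.classes.size != n:
                raise ValueError("classes length mismatch")
            bad = set(np.unique(self.classes)) - set(CLASS_LABELS)
            if bad:
                raise ValueError(f"unknown class labels: {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def rgb(self) -> np.ndarray:
        """(n, 3) uint8 color matrix."""
        return np.column_stack([self.red, self.green, self.blue])

    def subset(self, mask: np.ndarray) -> "ColoredPointCloud":
        """Cloud restricted to the points selected by a boolean mask or index array."""
        cls = self.classes[mask] if self.classes is not None else None
        return ColoredPointCloud(
            self.x[mask], self.y[mask], self.z[mask],
            self.red[mask], self.green[mask], self.blue[mask],
            classes=cls, crs=self.crs,
        )

    def with_classes(self, classes: np.ndarray) -> "ColoredPointCloud":
        """Copy of the cloud with the given per-point labels."""
        return ColoredPointCloud(
            self.x, self.y, self.z, self.red, self.green, self.blue,
            classes=np.asarray(classes, dtype="U13"), crs=self.crs,
        )


@dataclass
class ReferenceTreeSet:
    """Ground-truth stem positions, typically digitized on an orthomosaic.

    ``table`` has columns ``id``, ``x``, ``y`` and optionally ``plot``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"id", "x", "y"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"reference tree table missing columns: {sorted(missing)}")
        if self.table["id"].duplicated().any():
            dupes = self.table.loc[self.table["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate tree ids: {dupes}")
        if not np.isfinite(self.table[["x", "y"]].to_numpy(dtype=float)).all():
            raise ValueError("tree positions must be finite")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of stem positions."""
        return self.table[["x", "y"]].to_numpy(dtype=float)
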