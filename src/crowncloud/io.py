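"""Point-cloud and tabular file IO.

Two cloud formats are supported: plain-text ``X Y Z R G B`` (whitespace or
comma delimited, 8-bit colors) and binary LAS 1.2 with point formats 2/3
(which carry 16-bit RGB).  LAS colors are rescaled between the 16-bit value
stored on disk and the 8-bit value used in memory with the full-scale factor
257 (0xFFFF / 0xFF), rounding half-up, so a write/read round trip is exact.

LAZ (compressed LAS) is recognized by extension but not supported: no
decompressor is bundled.
"""

from __future__ import annotations

import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from crowncloud.pointcloud import (
    LAS_CLASS_CODES,
    LAS_CODE_LABELS,
    ColoredPointCloud,
    ReferenceTreeSet,
)

_LAS_HEADER_SIZE = 227  # LAS 1.2 public header block
_POINT_RECORD = {2: 26, 3: 34}  # formats carrying RGB that we read/write
_RGB_OFFSET = {2: 20, 3: 28}  # byte offset of the red channel in the record

_POINT_DTYPE_2 = np.dtype([
    ("X", "<i4"), ("Y", "<i4"), ("Z", "<i4"),
    ("intensity", "<u2"), ("flags", "u1"), ("classification", "u1"),
    ("scan_angle", "i1"), ("user_data", "u1"), ("point_source", "<u2"),
    ("red", "<u2"), ("green", "<u2"), ("blue", "<u2"),
])


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".las":
        return "las"
    if suffix == ".laz":
        return "laz"
    return "xyzrgb-text"


def read_point_cloud(path: str | Path, format: str | None = None) -> ColoredPointCloud:
    """Read a colored cloud from LAS or delimited text.

    Parameters
    ----------
    path : path
        File to read.
    format : {"las", "laz", "xyzrgb-text"}, optional
        Force a format; inferred from the extension when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path, format)
    if fmt == "laz":
        raise NotImplementedError("LAZ decompression is not supported; decompress to LAS first")
    if fmt == "las":
        return _read_las(path)
    if fmt == "xyzrgb-text":
        return _read_text(path)
    raise ValueError(f"unknown point cloud format: {fmt!r}")


def write_point_cloud(cloud: ColoredPointCloud, path: str | Path,
                      format: str | None = None) -> Path:
    """Write a non-empty cloud to LAS or delimited text.

    Class labels go to the LAS classification field using ASPRS codes
    (vegetation→4, ground/nonvegetation→2, unclassified→1); the text format
    stores the label string in a seventh column.
    """
    path = Path(path)
    if len(cloud) == 0:
        raise ValueError("refusing to write an empty point cloud")
    fmt = _detect_format(path, format)
    if fmt == "laz":
        raise NotImplementedError("LAZ compression is not supported; write LAS instead")
    if fmt == "las":
        _write_las(cloud, path)
    elif fmt == "xyzrgb-text":
        _write_text(cloud, path)
    else:
        raise ValueError(f"unknown point cloud format: {fmt!r}")
    return path


# -- text -------------------------------------------------------------------

def _read_text(path: Path) -> ColoredPointCloud:
    raw = path.read_text()
    rows: list[list[str]] = []
    for line in raw.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append(line.replace(",", " ").split())
    if not rows:
        warnings.warn(f"{path}: empty point cloud file", stacklevel=3)
        empty = np.empty(0)
        return ColoredPointCloud(empty, empty, empty, empty, empty, empty)
    ncol = len(rows[0])
    if ncol < 6:
        raise ValueError(f"{path}: expected at least 6 columns X Y Z R G B, found {ncol}")
    arr = np.array([r[:6] for r in rows], dtype=np.float64)
    classes = None
    if ncol >= 7:
        classes = np.array([r[6] for r in rows], dtype="U13")
    return ColoredPointCloud(
        arr[:, 0], arr[:, 1], arr[:, 2],
        arr[:, 3].round().astype(int), arr[:, 4].round().astype(int),
        arr[:, 5].round().astype(int), classes=classes,
    )


def _write_text(cloud: ColoredPointCloud, path: Path) -> None:
    with open(path, "w") as fh:
        if cloud.classes is None:
            for i in range(len(cloud)):
                fh.write(f"{cloud.x[i]:.3f} {cloud.y[i]:.3f} {cloud.z[i]:.3f} "
                         f"{cloud.red[i]} {cloud.green[i]} {cloud.blue[i]}\n")
        else:
            for i in range(len(cloud)):
                fh.write(f"{cloud.x[i]:.3f} {cloud.y[i]:.3f} {cloud.z[i]:.3f} "
                         f"{cloud.red[i]} {cloud.green[i]} {cloud.blue[i]} "
                         f"{cloud.classes[i]}\n")


# -- LAS 1.2 ----------------------------------------------------------------

def _color_16_to_8(values: np.ndarray) -> np.ndarray:
    # full-scale 16→8-bit: divide by 257, round half-up
    return np.floor(values.astype(np.float64) / 257.0 + 0.5).astype(np.uint8)


def _color_8_to_16(values: np.ndarray) -> np.ndarray:
    return values.astype(np.uint16) * np.uint16(257)


def _read_las(path: Path) -> ColoredPointCloud:
    data = path.read_bytes()
    if len(data) == 0:
        warnings.warn(f"{path}: empty point cloud file", stacklevel=3)
        empty = np.empty(0)
        return ColoredPointCloud(empty, empty, empty, empty, empty, empty)
    if data[:4] != b"LASF":
        raise ValueError(f"{path}: not a LAS file (bad signature)")
    (offset_to_points,) = struct.unpack_from("<I", data, 96)
    point_format = data[104]
    (record_length,) = struct.unpack_from("<H", data, 105)
    (n_points,) = struct.unpack_from("<I", data, 107)
    scales = struct.unpack_from("<3d", data, 131)
    offsets = struct.unpack_from("<3d", data, 155)
    if point_format not in _RGB_OFFSET:
        raise ValueError(
            f"{path}: LAS point format {point_format} carries no RGB dimension; "
            f"need format 2 or 3"
        )
    body = np.frombuffer(data, dtype=np.uint8,
                         count=n_points * record_length, offset=offset_to_points)
    body = body.reshape(n_points, record_length)

    def field(off: int, dtype: str) -> np.ndarray:
        width = np.dtype(dtype).itemsize
        return body[:, off:off + width].copy().view(dtype).ravel()

    xyz_raw = np.column_stack([field(0, "<i4"), field(4, "<i4"), field(8, "<i4")])
    coords = xyz_raw * np.array(scales) + np.array(offsets)
    rgb_off = _RGB_OFFSET[point_format]
    red = _color_16_to_8(field(rgb_off, "<u2"))
    green = _color_16_to_8(field(rgb_off + 2, "<u2"))
    blue = _color_16_to_8(field(rgb_off + 4, "<u2"))
    codes = field(15, "u1")
    classes = np.array([LAS_CODE_LABELS.get(int(c), "unclassified") for c in codes],
                       dtype="U13")
    return ColoredPointCloud(coords[:, 0], coords[:, 1], coords[:, 2],
                             red, green, blue, classes=classes)


def _write_las(cloud: ColoredPointCloud, path: Path) -> None:
    n = len(cloud)
    scale = 0.001  # millimeter quantization keeps round trips within 1e-3 m
    off = np.array([cloud.x.min(), cloud.y.min(), cloud.z.min()])
    rec = np.zeros(n, dtype=_POINT_DTYPE_2)
    rec["X"] = np.round((cloud.x - off[0]) / scale).astype(np.int32)
    rec["Y"] = np.round((cloud.y - off[1]) / scale).astype(np.int32)
    rec["Z"] = np.round((cloud.z - off[2]) / scale).astype(np.int32)
    rec["flags"] = 0x09  # single return, first of one
    if cloud.classes is None:
        rec["classification"] = LAS_CLASS_CODES["unclassified"]
    else:
        rec["classification"] = [LAS_CLASS_CODES[c] for c in cloud.classes]
    rec["red"] = _color_8_to_16(cloud.red)
    rec["green"] = _color_8_to_16(cloud.green)
    rec["blue"] = _color_8_to_16(cloud.blue)

    header = bytearray(_LAS_HEADER_SIZE)
    header[0:4] = b"LASF"
    header[24] = 1  # version major
    header[25] = 2  # version minor
    header[26:26 + len(b"crowncloud")] = b"crowncloud"
    header[58:58 + len(b"crowncloud")] = b"crowncloud"
    struct.pack_into("<H", header, 94, _LAS_HEADER_SIZE)
    struct.pack_into("<I", header, 96, _LAS_HEADER_SIZE)
    struct.pack_into("<I", header, 100, 0)  # VLR count
    header[104] = 2
    struct.pack_into("<H", header, 105, _POINT_RECORD[2])
    struct.pack_into("<I", header, 107, n)
    struct.pack_into("<I", header, 111, n)  # points by return, first
    struct.pack_into("<3d", header, 131, scale, scale, scale)
    struct.pack_into("<3d", header, 155, *off)
    struct.pack_into("<6d", header, 179,
                     cloud.x.max(), cloud.x.min(),
                     cloud.y.max(), cloud.y.min(),
                     cloud.z.max(), cloud.z.min())
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(rec.tobytes())


# -- tabular ----------------------------------------------------------------

def read_reference_trees(path: str | Path) -> ReferenceTreeSet:
    """Read reference stems from CSV with columns ``id, x, y[, plot]``."""
    table = pd.read_csv(path)
    return ReferenceTreeSet(table)


def write_reference_trees(trees: ReferenceTreeSet, path: str | Path) -> Path:
    path = Path(path)
    trees.table.to_csv(path, index=False)
    return path


def read_plots(path: str | Path) -> pd.DataFrame:
    """Read circular plot definitions from CSV with columns ``id, x, y, radius``."""
    table = pd.read_csv(path)
    missing = {"id", "x", "y", "radius"} - set(table.columns)
    if missing:
        raise ValueError(f"plot table missing columns: {sorted(missing)}")
    return table
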