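"""Reading and writing image stacks, boundary ROIs and experiment manifests.

Conventions
-----------
* Pixel coordinates are 0-based; ``x`` runs rightward (columns), ``y``
  downward (rows). Polygon vertices sit at pixel centers, so a pixel belongs
  to the organoid interior iff its center passes the point-in-polygon test.
* Stacks are stored channel-first as ``(channel, z, y, x)``.
* ROIs are closed simple polygons; the last→first edge is implicit.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml


class ImageIOError(ValueError):
    """Base class for file-level errors raised by this module."""


class PixelSizeError(ImageIOError):
    """Pixel size absent from metadata and no override supplied."""


class ChannelMismatchError(ImageIOError):
    """Channel names do not match the channel count of the stack."""


class ROIError(ValueError):
    """Invalid boundary polygon (too few vertices, self-intersection, ...)."""


class ManifestError(ValueError):
    """Invalid experiment manifest."""


# --------------------------------------------------------------------------
# ImageStack
# --------------------------------------------------------------------------

@dataclass
class ImageStack:
    """Multichannel 3D fluorescence volume with physical pixel size.

    Parameters
    ----------
    data : ndarray, shape (channel, z, y, x)
        Non-negative intensities.
    channel_names : list of str
        One unique label per channel (e.g. ``["DAPI", "eGFP"]``).
    pixel_size_um : float
        In-plane pixel size in micrometres (> 0).
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ImageIOError(
                f"stack data must be (channel, z, y, x); got ndim={self.data.ndim}"
            )
        if np.any(self.data < 0):
            raise ImageIOError("stack intensities must be non-negative")
        if len(self.channel_names) != self.data.shape[0]:
            raise ChannelMismatchError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ImageIOError("channel names must be unique")
        if not self.pixel_size_um > 0:
            raise ImageIOError("pixel_size_um must be > 0")

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) volume of one named channel."""
        try:
            i = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None
        return self.data[i]


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with channel names and pixel size."""
    path = Path(path)
    tifffile.imwrite(
        path,
        stack.data.astype(np.float32),
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(stack.channel_names)},
            "PhysicalSizeX": float(stack.pixel_size_um),
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": float(stack.pixel_size_um),
            "PhysicalSizeYUnit": "µm",
        },
    )
    return path


def _axes_to_czyx(data: np.ndarray, axes: str) -> np.ndarray:
    """Rearrange a tifffile series to (C, Z, Y, X), inserting missing axes."""
    axes = axes.upper().replace("S", "C")  # samples-per-pixel as channels
    keep = [a for a in axes if a in "CZYX"]
    if len(keep) != data.ndim:
        # drop singleton axes tifffile may report (T, Q, ...)
        for i, a in enumerate(axes):
            if a not in "CZYX":
                if data.shape[i] != 1:
                    raise ImageIOError(f"unsupported non-singleton axis {a!r}")
        sl = tuple(0 if a not in "CZYX" else slice(None) for a in axes)
        data = data[sl]
        axes = "".join(keep)
    for missing in "CZYX":
        if missing not in axes:
            data = data[np.newaxis]
            axes = missing + axes
    order = [axes.index(a) for a in "CZYX"]
    return np.transpose(data, order)


def read_stack(
    path: str | Path,
    channel_names: Sequence[str] | None = None,
    pixel_size_um: float | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack.

    Channel names and pixel size are taken from OME metadata when present;
    explicit arguments override the file. Plain TIFFs (no OME metadata)
    require ``channel_names`` and ``pixel_size_um``: the page axis is
    interpreted as channels when ``len(channel_names)`` matches the page
    count, and as z otherwise.
    """
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such file: {path}")
    try:
        tf = tifffile.TiffFile(path)
    except Exception as exc:  # pragma: no cover - corrupt file path
        raise ImageIOError(f"unreadable TIFF {path}: {exc}") from exc
    with tf:
        series = tf.series[0]
        data = series.asarray()
        meta_names: list[str] | None = None
        meta_px: float | None = None
        if tf.ome_metadata:
            ome = tifffile.xml2dict(tf.ome_metadata)
            image = ome.get("OME", {}).get("Image", {})
            if isinstance(image, list):
                image = image[0]
            pixels = image.get("Pixels", {})
            if "PhysicalSizeX" in pixels:
                meta_px = float(pixels["PhysicalSizeX"])
            chans = pixels.get("Channel", [])
            if isinstance(chans, dict):
                chans = [chans]
            names = [c.get("Name") for c in chans]
            if names and all(n is not None for n in names):
                meta_names = [str(n) for n in names]
        if data.ndim == 2:
            data = data[np.newaxis, np.newaxis]
        elif tf.ome_metadata:
            data = _axes_to_czyx(data, series.axes)
        else:
            # plain multi-page TIFF: disambiguate with channel_names
            if channel_names is None:
                raise ChannelMismatchError(
                    "plain TIFF requires explicit channel_names"
                )
            if data.ndim == 3:
                if len(channel_names) == data.shape[0]:
                    data = data[:, np.newaxis]
                elif len(channel_names) == 1:
                    data = data[np.newaxis]
                else:
                    raise ChannelMismatchError(
                        f"{len(channel_names)} channel names for "
                        f"{data.shape[0]} pages"
                    )
            else:
                data = _axes_to_czyx(data, series.axes)

    names = list(channel_names) if channel_names is not None else meta_names
    if names is None:
        names = [f"C{i}" for i in range(data.shape[0])]
    if len(names) != data.shape[0]:
        raise ChannelMismatchError(
            f"{len(names)} channel names for {data.shape[0]} channels"
        )
    px = pixel_size_um if pixel_size_um is not None else meta_px
    if px is None:
        raise PixelSizeError(
            f"{path}: no pixel size in metadata and no override given"
        )
    return ImageStack(data=data, channel_names=names, pixel_size_um=float(px))


# --------------------------------------------------------------------------
# BoundaryROI
# --------------------------------------------------------------------------

def _segments_cross(p1, p2, p3, p4) -> bool:
    """Proper intersection test between open segments p1p2 and p3p4."""

    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if v == 0 else (1 if v > 0 else -1)

    o1 = orient(p1, p2, p3)
    o2 = orient(p1, p2, p4)
    o3 = orient(p3, p4, p1)
    o4 = orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


@dataclass
class BoundaryROI:
    """Closed simple polygon delimiting the neural-organoid interior.

    Vertices are ordered (x, y) pairs in pixel coordinates; the closing edge
    from the last vertex back to the first is implicit.
    """

    vertices: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ROIError("vertices must be an (n, 2) array of (x, y)")
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]  # explicit closure tolerated, stored open
        if len(v) < 3:
            raise ROIError("polygon needs at least 3 distinct vertices")
        self.vertices = v
        cross = self.find_self_intersection()
        if cross is not None:
            raise ROIError(
                f"polygon is self-intersecting: edge {cross[0]} crosses "
                f"edge {cross[1]}"
            )
        if abs(self.signed_area()) == 0:
            raise ROIError("polygon has zero area")

    def find_self_intersection(self) -> tuple[int, int] | None:
        """O(n^2) check for properly crossing edge pairs; None if simple."""
        v = self.vertices
        n = len(v)
        edges = [(v[i], v[(i + 1) % n]) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if j == i or (j == i + 1) or (i == 0 and j == n - 1):
                    continue  # adjacent edges share a vertex
                if _segments_cross(*edges[i], *edges[j]):
                    return (i, j)
        return None

    def signed_area(self) -> float:
        """Shoelace area; positive for counterclockwise vertex order."""
        v = self.vertices
        x, y = v[:, 0], v[:, 1]
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    @property
    def area(self) -> float:
        return abs(self.signed_area())


# ---- ImageJ .roi binary dialect (polygon type only) ----------------------
#
# Fixed 64-byte big-endian header: magic "Iout", version, type byte
# (0 = polygon), bounding box (top, left, bottom, right), vertex count;
# then x offsets from `left` and y offsets from `top` as int16.

_ROI_MAGIC = b"Iout"
_ROI_TYPE_POLYGON = 0


def _write_imagej_roi(roi: BoundaryROI, path: Path) -> None:
    v = np.rint(roi.vertices).astype(int)
    xs, ys = v[:, 0], v[:, 1]
    left, top = int(xs.min()), int(ys.min())
    right, bottom = int(xs.max()) + 1, int(ys.max()) + 1
    n = len(v)
    header = bytearray(64)
    header[0:4] = _ROI_MAGIC
    struct.pack_into(">h", header, 4, 228)  # format version
    header[6] = _ROI_TYPE_POLYGON
    struct.pack_into(">hhhh", header, 8, top, left, bottom, right)
    struct.pack_into(">H", header, 16, n)
    body = struct.pack(f">{n}h", *(xs - left)) + struct.pack(f">{n}h", *(ys - top))
    path.write_bytes(bytes(header) + body)


def _read_imagej_roi(path: Path) -> BoundaryROI:
    raw = path.read_bytes()
    if len(raw) < 64 or raw[0:4] != _ROI_MAGIC:
        raise ROIError(f"{path}: not an ImageJ .roi file")
    roi_type = raw[6]
    if roi_type != _ROI_TYPE_POLYGON:
        raise ROIError(
            f"{path}: unsupported ImageJ ROI type {roi_type}; only polygon "
            "(type 0) ROIs are accepted"
        )
    top, left, _bottom, _right = struct.unpack_from(">hhhh", raw, 8)
    (n,) = struct.unpack_from(">H", raw, 16)
    xs = np.array(struct.unpack_from(f">{n}h", raw, 64)) + left
    ys = np.array(struct.unpack_from(f">{n}h", raw, 64 + 2 * n)) + top
    return BoundaryROI(np.column_stack([xs, ys]).astype(float))


def write_roi(roi: BoundaryROI, path: str | Path, dialect: str = "json") -> Path:
    """Write a boundary polygon as ImageJ ``.roi`` or JSON.

    The ImageJ dialect stores integer pixel coordinates (vertices are
    rounded); the JSON dialect preserves full float precision.
    """
    path = Path(path)
    if dialect == "imagej_roi":
        _write_imagej_roi(roi, path)
    elif dialect == "json":
        payload = {"type": "polygon", "vertices": roi.vertices.tolist()}
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown ROI dialect {dialect!r}")
    return path


def read_roi(path: str | Path) -> BoundaryROI:
    """Read a boundary polygon from ImageJ ``.roi`` or JSON (by sniffing)."""
    path = Path(path)
    raw = path.read_bytes()
    if raw[:4] == _ROI_MAGIC:
        return _read_imagej_roi(path)
    try:
        payload = json.loads(raw.decode())
    except Exception as exc:
        raise ROIError(f"{path}: neither ImageJ .roi nor JSON polygon") from exc
    if payload.get("type") != "polygon" or "vertices" not in payload:
        raise ROIError(f"{path}: JSON ROI must have type 'polygon' and vertices")
    return BoundaryROI(np.asarray(payload["vertices"], dtype=float))


# --------------------------------------------------------------------------
# ExperimentManifest
# --------------------------------------------------------------------------

_MANIFEST_COLUMNS = [
    "image", "roi", "group", "treatment", "replicate",
    "channels", "is_control_group", "is_untreated",
]


@dataclass
class ExperimentManifest:
    """Grouped-experiment table: one row per image.

    Columns: image path, ROI path, group label (e.g. NT / ITGa6-KD),
    treatment label (e.g. radiation dose), replicate id, semicolon-separated
    channel names, and flags marking the control group and the untreated
    treatment arm.
    """

    records: pd.DataFrame
    base_dir: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in _MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise ManifestError(f"manifest missing columns: {missing}")
        if not df["is_control_group"].any():
            raise ManifestError("no control group designated in manifest")
        key = df[["group", "treatment", "replicate"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ManifestError(
                f"duplicate replicate id: group={dup['group']} "
                f"treatment={dup['treatment']} replicate={dup['replicate']}"
            )

    @property
    def control_group(self) -> str:
        return str(self.records.loc[self.records["is_control_group"], "group"].iloc[0])

    def channels_of(self, row) -> list[str]:
        return [c.strip() for c in str(row["channels"]).split(";") if c.strip()]

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.base_dir / p


def load_manifest(path: str | Path, check_files: bool = True) -> ExperimentManifest:
    """Load and validate a CSV or YAML experiment manifest."""
    path = Path(path)
    if path.suffix.lower() in {".yaml", ".yml"}:
        rows = yaml.safe_load(path.read_text())
        df = pd.DataFrame(rows)
    else:
        df = pd.read_csv(path)
    for col in ("is_control_group", "is_untreated"):
        if col in df.columns:
            df[col] = df[col].astype(bool)
    manifest = ExperimentManifest(records=df, base_dir=path.parent)
    if check_files:
        for col in ("image", "roi"):
            for rel in df[col]:
                p = manifest.resolve(str(rel))
                if not p.exists():
                    raise ManifestError(f"dangling {col} path in manifest: {rel}")
    return manifest
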