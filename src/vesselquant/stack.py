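"""Multichannel 3D image stacks with physical voxel spacing.

The in-memory container used by every downstream stage is :class:`ImageStack`:
a ``(channel, z, y, x)`` intensity array plus the voxel spacing in μm and the
ordered channel names.  All physical coordinates in this package are
``(z, y, x)`` μm measured from the corner of voxel ``(0, 0, 0)``; the center
of voxel ``i`` along an axis with spacing ``d`` is at ``(i + 0.5) * d``.

On disk, stacks are OME-TIFF (channel names and physical sizes in the OME
metadata).  A plain multi-page TIFF accompanied by a YAML sidecar
(``{spacing: [dz, dy, dx], channels: [...]}``) is also accepted.
"""

from __future__ import annotations

import xml.etree.ElementTree as _ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
import yaml

__all__ = ["ImageStack", "read_stack", "write_stack", "get_channel"]


@dataclass
class ImageStack:
    """A multichannel 3D intensity grid in physical μm coordinates.

    Parameters
    ----------
    data : ndarray, shape (C, Z, Y, X)
        Non-negative, finite intensities.
    voxel_spacing : (dz, dy, dx)
        Strictly positive voxel spacing in μm.
    channel_names : sequence of str
        One unique label per channel, same order as the channel axis.
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float]
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4-axis (C, Z, Y, X); got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel_spacing must be 3 strictly positive μm values; got {self.voxel_spacing}")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        """(nz, ny, nx) voxel counts."""
        return self.data.shape[1:]

    def channel(self, name: str) -> np.ndarray:
        """Return the (z, y, x) grid for a named channel (exact-match lookup)."""
        try:
            idx = self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"unknown channel {name!r}; available: {list(self.channel_names)}"
            ) from None
        return self.data[idx]

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-center coordinate vectors (z, y, x) in μm."""
        nz, ny, nx = self.grid_shape
        dz, dy, dx = self.voxel_spacing
        return (
            (np.arange(nz) + 0.5) * dz,
            (np.arange(ny) + 0.5) * dy,
            (np.arange(nx) + 0.5) * dx,
        )


def get_channel(stack: ImageStack, name: str) -> np.ndarray:
    """Functional alias for :meth:`ImageStack.channel`."""
    return stack.channel(name)


def write_stack(stack: ImageStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF with channel names and physical sizes."""
    path = Path(path)
    dz, dy, dx = stack.voxel_spacing
    tifffile.imwrite(
        path,
        stack.data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": list(stack.channel_names)},
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def _parse_ome(xml_text: str) -> tuple[tuple[float, float, float] | None, list[str] | None]:
    """Extract (dz, dy, dx) and channel names from OME-XML, if present."""
    root = _ET.fromstring(xml_text)
    ns = ""
    if root.tag.startswith("{"):
        ns = root.tag[: root.tag.index("}") + 1]
    pixels = root.find(f".//{ns}Pixels")
    if pixels is None:
        return None, None
    spacing = None
    sz, sy, sx = (pixels.get("PhysicalSizeZ"), pixels.get("PhysicalSizeY"), pixels.get("PhysicalSizeX"))
    if sz is not None and sy is not None and sx is not None:
        spacing = (float(sz), float(sy), float(sx))
    names = [ch.get("Name") for ch in pixels.findall(f"{ns}Channel")]
    if not names or any(n is None for n in names):
        names = None
    return spacing, names


def read_stack(
    path: str | Path,
    spacing_override: tuple[float, float, float] | None = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack.

    Spacing comes from the OME metadata or a YAML sidecar (``<stem>.yaml``
    next to the file, keys ``spacing`` and ``channels``); ``spacing_override``
    is used when metadata carries no spacing.  Missing spacing with no
    override is an error, as is 2D-only data.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes  # e.g. "CZYX", "ZYX", "YX"
        spacing = None
        names: list[str] | None = None
        if tf.ome_metadata:
            spacing, names = _parse_ome(tf.ome_metadata)

    sidecar = path.with_suffix(".yaml")
    if (spacing is None or names is None) and sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text())
        if spacing is None and "spacing" in meta:
            spacing = tuple(float(v) for v in meta["spacing"])
        if names is None and "channels" in meta:
            names = [str(c) for c in meta["channels"]]

    if set(axes) <= set("CZYX") and len(set(axes)) == len(axes):
        if "Z" not in axes:
            raise ValueError(f"{path}: 2D-only data without a declared z axis (axes={axes!r})")
        if "C" not in axes:
            data = data[np.newaxis]
            axes = "C" + axes
        data = np.transpose(data, [axes.index(a) for a in "CZYX"])
    else:
        # plain TIFF with unlabeled leading axes: trailing two are (y, x),
        # 3D is (z, y, x), 4D is (c, z, y, x)
        if data.ndim == 2:
            raise ValueError(f"{path}: 2D-only data without a declared z axis")
        if data.ndim == 3:
            data = data[np.newaxis]
        if data.ndim != 4:
            raise ValueError(f"{path}: cannot interpret {data.ndim}-axis data as (C, Z, Y, X)")

    if spacing is None:
        spacing = spacing_override
    if spacing is None:
        raise ValueError(f"{path}: no voxel spacing in metadata and no spacing_override given")
    if names is None:
        names = [f"ch{i}" for i in range(data.shape[0])]
    return ImageStack(data=data, voxel_spacing=tuple(spacing), channel_names=tuple(names))
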