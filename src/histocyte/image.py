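"""Multichannel fluorescence image container and OME-TIFF I/O.

The in-memory representation is a plain float32/uint16 array indexed
``(channel, [z,] y, x)`` together with the ordered channel names and the
physical pixel size.  Images are written as OME-TIFF with channel names and
pixel size recorded in the OME metadata so that round trips through disk
preserve the full container.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

__all__ = ["MultichannelImage"]


@dataclass
class MultichannelImage:
    """Fluorophore-indexed intensity image.

    Parameters
    ----------
    data:
        Array of shape ``(C, Y, X)`` or ``(C, Z, Y, X)``; non-negative.
    channel_names:
        Ordered, unique channel (fluorophore) names, one per channel plane.
    pixel_size:
        Lateral pixel size in micrometres per pixel.
    z_step:
        Axial step in micrometres, only for z-stacks.
    metadata:
        Free-form provenance flags (e.g. ``{"compensated": True}``).
    """

    data: np.ndarray
    channel_names: list[str]
    pixel_size: float
    z_step: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim not in (3, 4):
            raise ValueError(
                f"expected (C, Y, X) or (C, Z, Y, X) data, got shape {self.data.shape}"
            )
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} channel planes"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")

    # -- basic accessors -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def is_stack(self) -> bool:
        return self.data.ndim == 4

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[-2], self.data.shape[-1]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in image (have {self.channel_names})"
            ) from None

    def channel(self, name: str) -> np.ndarray:
        """Return the plane (or stack) for a named channel."""
        return self.data[self.channel_index(name)]

    def with_data(self, data: np.ndarray, **meta) -> "MultichannelImage":
        """Copy of this image with new pixel data and updated metadata."""
        out = replace(self, data=data, metadata={**self.metadata, **meta})
        return out

    # -- disk round trip -------------------------------------------------
    def write(self, path) -> None:
        """Write as uint16 OME-TIFF with channel names and pixel size."""
        arr = np.clip(np.rint(np.asarray(self.data, dtype=np.float64)), 0, 65535)
        arr = arr.astype(np.uint16)
        axes = "CZYX" if self.is_stack else "CYX"
        ome_md = {
            "axes": axes,
            "Channel": {"Name": list(self.channel_names)},
            "PhysicalSizeX": float(self.pixel_size),
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": float(self.pixel_size),
            "PhysicalSizeYUnit": "µm",
        }
        if self.z_step is not None:
            ome_md["PhysicalSizeZ"] = float(self.z_step)
            ome_md["PhysicalSizeZUnit"] = "µm"
        tifffile.imwrite(path, arr, ome=True, metadata=ome_md)

    @classmethod
    def read(cls, path) -> "MultichannelImage":
        with tifffile.TiffFile(path) as tif:
            arr = tif.asarray()
            ome = tif.ome_metadata
        if ome is None:
            raise ValueError(f"{path} carries no OME metadata")
        root = ET.fromstring(ome)
        ns = {"ome": root.tag.split("}")[0].strip("{")}
        pixels = root.find(".//ome:Pixels", ns)
        names = [
            ch.get("Name") or f"ch{i}"
            for i, ch in enumerate(pixels.findall("ome:Channel", ns))
        ]
        pixel_size = float(pixels.get("PhysicalSizeX", "1.0"))
        z_step = pixels.get("PhysicalSizeZ")
        if arr.ndim == 2:
            arr = arr[None]
        return cls(
            data=arr,
            channel_names=names,
            pixel_size=pixel_size,
            z_step=float(z_step) if z_step is not None else None,
        )
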