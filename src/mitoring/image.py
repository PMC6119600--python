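"""Multi-channel image container and TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

#: Channel order used on disk (axis C of the OME-TIFF).
CHANNEL_ORDER = ("nucleus", "marker", "potential")


@dataclass
class MultiChannelImage:
    """Aligned 2D intensity grids for one field of view.

    Channels follow the acquisition scheme of the assay: a DNA stain
    (``nucleus_channel``, DAPI), a mitochondrial-compartment marker
    (``marker_channel``, Tom70 immunofluorescence) and a potential-dependent
    dye (``potential_channel``, MitoTracker CMX ROS).  Intensities are in
    arbitrary units; ``pixel_size_um`` carries the physical calibration.
    """

    nucleus_channel: np.ndarray
    marker_channel: np.ndarray
    potential_channel: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        shapes = {
            self.nucleus_channel.shape,
            self.marker_channel.shape,
            self.potential_channel.shape,
        }
        if len(shapes) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        if self.nucleus_channel.ndim != 2:
            raise ValueError("channels must be 2D grids")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.nucleus_channel.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNEL_ORDER:
            raise KeyError(f"unknown channel {name!r}; expected one of {CHANNEL_ORDER}")
        return getattr(self, f"{name}_channel")

    def save(self, path: str | Path) -> None:
        """Write a 3-channel uint16 OME-TIFF with pixel size metadata."""
        stack = np.stack([np.asarray(self.channel(c), dtype=float) for c in CHANNEL_ORDER])
        stack = np.clip(np.rint(stack), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        tifffile.imwrite(
            str(path),
            stack,
            ome=True,
            metadata={
                "axes": "CYX",
                "PhysicalSizeX": self.pixel_size_um,
                "PhysicalSizeXUnit": "µm",
                "PhysicalSizeY": self.pixel_size_um,
                "PhysicalSizeYUnit": "µm",
                "Channel": {"Name": list(CHANNEL_ORDER)},
            },
        )

    @classmethod
    def load(cls, path: str | Path, pixel_size_um: float | None = None) -> "MultiChannelImage":
        """Read a 3-channel TIFF/OME-TIFF written by :meth:`save`.

        ``pixel_size_um`` overrides (or supplies, for plain TIFFs) the
        calibration stored in the OME metadata.
        """
        with tifffile.TiffFile(str(path)) as tif:
            stack = tif.asarray()
            if pixel_size_um is None:
                try:
                    import xml.etree.ElementTree as ET

                    root = ET.fromstring(tif.ome_metadata)
                    ns = {"ome": root.tag.split("}")[0].strip("{")}
                    px = root.find(".//ome:Pixels", ns)
                    pixel_size_um = float(px.attrib["PhysicalSizeX"])
                except Exception as exc:  # pragma: no cover - malformed metadata
                    raise ValueError(
                        f"{path}: no pixel size in metadata; pass pixel_size_um explicitly"
                    ) from exc
        if stack.ndim != 3 or stack.shape[0] != 3:
            raise ValueError(f"{path}: expected a 3-channel CYX stack, got shape {stack.shape}")
        nuc, marker, pot = (stack[i].astype(float) for i in range(3))
        return cls(nuc, marker, pot, pixel_size_um)
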