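"""Background correction, nucleus/cell/mitochondria segmentation.

The field is partitioned into per-cell territories by nearest-nucleus
distance, and the mitochondrial compartment is demarcated from the marker
(Tom70) channel by Otsu thresholding -- globally or per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .image import MultiChannelImage

log = logging.getLogger(__name__)


@dataclass
class CellSegmentation:
    """Per-field segmentation: nuclei, cell territories, mitochondria.

    ``mito_mask`` carries the owning cell's label on every mitochondrial
    pixel; it is disjoint from ``nucleus_labels`` and contained in
    ``territory_labels``.  ``border_cells`` lists cells whose nucleus touches
    the field edge.
    """

    nucleus_labels: np.ndarray
    territory_labels: np.ndarray
    mito_mask: np.ndarray
    pixel_size_um: float
    border_cells: tuple[int, ...] = ()

    @property
    def cell_ids(self) -> list[int]:
        return [int(v) for v in np.unique(self.nucleus_labels) if v > 0]


def subtract_background(
    channel: np.ndarray, method: str = "mode", level: float = 1.0
) -> np.ndarray:
    """Subtract a per-image scalar background and clip at zero.

    ``method="percentile"`` uses the ``level``-th percentile of all pixels;
    ``method="mode"`` uses the mode of the integer-rounded intensity
    histogram, which estimates the background plateau without the downward
    bias a low percentile has under noise.
    """
    channel = np.asarray(channel, dtype=float)
    if channel.size == 0:
        raise ValueError("empty intensity grid")
    if method == "percentile":
        if not 0 <= level <= 100:
            raise ValueError("percentile level must be in [0, 100]")
        b = float(np.percentile(channel, level))
    elif method == "mode":
        vals = np.rint(channel).astype(np.int64)
        vals -= vals.min()
        b = float(np.bincount(vals.ravel()).argmax() + np.rint(channel).min())
    else:
        raise ValueError(f"unknown background method {method!r}")
    return np.maximum(channel - b, 0.0)


def segment_nuclei(
    dapi: np.ndarray, min_area_um2: float, pixel_size_um: float
) -> np.ndarray:
    """Otsu-threshold the DNA channel, fill holes, drop small components.

    Returns a labeled mask (0 = background).  If nothing survives the area
    filter an empty labeling is returned with a warning rather than an error.
    """
    dapi = np.asarray(dapi, dtype=float)
    if dapi.max() <= 0 or np.isclose(dapi.max(), dapi.min()):
        log.warning("nucleus channel is flat; returning empty labeling")
        return np.zeros(dapi.shape, dtype=np.int32)
    mask = dapi > threshold_otsu(dapi)
    mask = ndimage.binary_fill_holes(mask)
    labels = cc_label(mask, connectivity=2)
    min_px = min_area_um2 / pixel_size_um**2
    counts = np.bincount(labels.ravel())
    keep = np.flatnonzero(counts >= min_px)
    keep = keep[keep > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(keep, start=1):
        out[labels == old] = new
    if out.max() == 0:
        log.warning("no nucleus above %.2f µm²; returning empty labeling", min_area_um2)
    return out


def assign_cell_territories(nucleus_labels: np.ndarray) -> np.ndarray:
    """Assign every pixel to the cell with the nearest nucleus pixel.

    The resulting labels partition the field (no unassigned pixels); nucleus
    pixels keep their own label.
    """
    if nucleus_labels.max() == 0:
        raise ValueError("assign_cell_territories requires at least one nucleus")
    _, (ir, ic) = ndimage.distance_transform_edt(nucleus_labels == 0, return_indices=True)
    return nucleus_labels[ir, ic]


def segment_mitochondria(
    marker: np.ndarray,
    territory_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    pixel_size_um: float,
    method: str = "otsu_per_cell",
    min_object_area_um2: float = 0.1,
) -> np.ndarray:
    """Demarcate the mitochondrial compartment from the marker channel.

    ``otsu_global`` thresholds the whole image once; ``otsu_per_cell``
    thresholds each cell territory separately (robust to per-cell marker
    abundance differences).  Nucleus pixels are excluded, objects below
    ``min_object_area_um2`` removed, and surviving pixels labeled with the
    owning cell's territory label.
    """
    marker = np.asarray(marker, dtype=float)
    if marker.shape != territory_labels.shape:
        raise ValueError("marker and territory shapes differ")
    out = np.zeros(marker.shape, dtype=np.int32)
    if marker.max() <= 0:
        log.warning("marker channel is empty; returning empty mitochondrial mask")
        return out

    if method == "otsu_global":
        mask = marker > threshold_otsu(marker)
    elif method == "otsu_per_cell":
        mask = np.zeros(marker.shape, dtype=bool)
        for cell in np.unique(territory_labels[territory_labels > 0]):
            sel = territory_labels == cell
            vals = marker[sel]
            if vals.max() <= vals.min():
                continue
            mask |= sel & (marker > threshold_otsu(vals))
    else:
        raise ValueError(f"unknown mitochondria method {method!r}")

    mask &= nucleus_labels == 0
    min_px = max(1, int(np.ceil(min_object_area_um2 / pixel_size_um**2)))
    comp = cc_label(mask, connectivity=2)
    counts = np.bincount(comp.ravel())
    small = np.flatnonzero(counts < min_px)
    mask[np.isin(comp, small[small > 0])] = False
    out[mask] = territory_labels[mask]
    return out


def segment_image(
    image: MultiChannelImage,
    background_method: str = "mode",
    background_level: float = 1.0,
    min_nucleus_area_um2: float = 20.0,
    mito_method: str = "otsu_per_cell",
    min_object_area_um2: float = 0.1,
    exclude_border_cells: bool = False,
) -> tuple[CellSegmentation, MultiChannelImage]:
    """Full preprocessing of one field: background correction + segmentation.

    Returns the segmentation and the background-corrected image.  Cells whose
    nucleus touches the field edge are flagged (``border_cells``) and, when
    ``exclude_border_cells`` is set, dropped from the labeling.
    """
    corrected = MultiChannelImage(
        subtract_background(image.nucleus_channel, background_method, background_level),
        subtract_background(image.marker_channel, background_method, background_level),
        subtract_background(image.potential_channel, background_method, background_level),
        image.pixel_size_um,
    )
    nuclei = segment_nuclei(corrected.nucleus_channel, min_nucleus_area_um2, image.pixel_size_um)
    border: list[int] = []
    if nuclei.max() > 0:
        edge = np.zeros_like(nuclei, dtype=bool)
        edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
        border = sorted(int(v) for v in np.unique(nuclei[edge]) if v > 0)
        if exclude_border_cells and border:
            for b in border:
                nuclei[nuclei == b] = 0
            nuclei = _relabel_consecutive(nuclei)
            border = []
    if nuclei.max() == 0:
        empty = np.zeros_like(nuclei)
        return (
            CellSegmentation(nuclei, empty, empty, image.pixel_size_um, ()),
            corrected,
        )
    territories = assign_cell_territories(nuclei)
    mito = segment_mitochondria(
        corrected.marker_channel,
        territories,
        nuclei,
        image.pixel_size_um,
        method=mito_method,
        min_object_area_um2=min_object_area_um2,
    )
    return (
        CellSegmentation(nuclei, territories, mito, image.pixel_size_um, tuple(border)),
        corrected,
    )


def _relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    out = np.zeros_like(labels)
    for new, old in enumerate(sorted(int(v) for v in np.unique(labels) if v > 0), start=1):
        out[labels == old] = new
    return out
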