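"""Per-region intensity readouts and ring profiles.

Three readouts are computed over the mitochondrial compartment restricted to
a region of interest (whole cell or ring):

* ``ratio_potential_marker`` -- MitoTracker/Tom70, the membrane-potential
  proxy normalized to mitochondrial mass;
* ``potential_per_area`` -- MitoTracker per µm² of mitochondrial area;
* ``marker_per_area`` -- Tom70 per µm² of mitochondrial area.

Ratios aggregate by summed intensities over the compartment (ratio of sums);
a pixel-mean mode is available for the potential/marker ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .image import MultiChannelImage
from .rings import build_rings
from .segment import CellSegmentation

log = logging.getLogger(__name__)

METRIC_NAMES = ("ratio_potential_marker", "potential_per_area", "marker_per_area")


@dataclass
class RegionMetrics:
    """Areas, channel sums and ratio metrics for one (cell x region)."""

    cell_id: int
    region_id: str
    mito_area_px: int
    mito_area_um2: float
    sum_marker: float
    sum_potential: float
    ratio_potential_marker: float
    potential_per_area: float
    marker_per_area: float
    valid: bool

    def value(self, metric_name: str) -> float:
        if metric_name not in METRIC_NAMES:
            raise KeyError(f"unknown metric {metric_name!r}; expected one of {METRIC_NAMES}")
        return getattr(self, metric_name)


@dataclass
class RingProfile:
    """Ring-ordered metric values, normalized to ring 1 (entry 1 = 1.0)."""

    cell_id: int | str
    metric_name: str
    values_by_ring: list[float]
    normalized_by_ring: list[float]


def compute_region_metrics(
    mito_mask: np.ndarray,
    region_mask: np.ndarray,
    marker: np.ndarray,
    potential: np.ndarray,
    pixel_size_um: float,
    cell_id: int = 0,
    region_id: str = "whole_cell",
    ratio_mode: str = "sum",
) -> RegionMetrics:
    """Sums and ratios over ``mito_mask & region_mask``.

    When the intersection is empty the record is returned with
    ``valid=False`` and NaN ratios (undefined, not zero).
    """
    mito_mask = np.asarray(mito_mask, dtype=bool)
    region_mask = np.asarray(region_mask, dtype=bool)
    if not (mito_mask.shape == region_mask.shape == marker.shape == potential.shape):
        raise ValueError("mask and channel shapes differ")
    if ratio_mode not in ("sum", "pixel_mean"):
        raise ValueError(f"unknown ratio_mode {ratio_mode!r}")
    sel = mito_mask & region_mask
    n_px = int(sel.sum())
    area_um2 = n_px * pixel_size_um**2
    if n_px == 0:
        return RegionMetrics(
            cell_id, region_id, 0, 0.0, 0.0, 0.0,
            math.nan, math.nan, math.nan, valid=False,
        )
    sm = float(marker[sel].sum())
    sp = float(potential[sel].sum())
    if ratio_mode == "sum":
        ratio = sp / sm if sm > 0 else math.nan
    else:
        m = marker[sel]
        ok = m > 0
        ratio = float(np.mean(potential[sel][ok] / m[ok])) if ok.any() else math.nan
    return RegionMetrics(
        cell_id=cell_id,
        region_id=region_id,
        mito_area_px=n_px,
        mito_area_um2=area_um2,
        sum_marker=sm,
        sum_potential=sp,
        ratio_potential_marker=ratio,
        potential_per_area=sp / area_um2,
        marker_per_area=sm / area_um2,
        valid=True,
    )


def whole_cell_metrics(
    seg: CellSegmentation,
    image: MultiChannelImage,
    ratio_mode: str = "sum",
) -> list[RegionMetrics]:
    """One RegionMetrics per segmented cell, region = the cell's territory."""
    out = []
    for cell in seg.cell_ids:
        out.append(
            compute_region_metrics(
                seg.mito_mask == cell,
                seg.territory_labels == cell,
                image.marker_channel,
                image.potential_channel,
                image.pixel_size_um,
                cell_id=cell,
                region_id="whole_cell",
                ratio_mode=ratio_mode,
            )
        )
    return out


def ring_metrics(
    seg: CellSegmentation,
    image: MultiChannelImage,
    ring_width_um: float = 1.0,
    n_rings: int = 4,
    clip_to_territory: bool = True,
    ratio_mode: str = "sum",
) -> dict[int, list[RegionMetrics]]:
    """Per-cell, per-ring RegionMetrics (ring 1 innermost)."""
    out: dict[int, list[RegionMetrics]] = {}
    for cell in seg.cell_ids:
        rings = build_rings(
            seg.nucleus_labels == cell,
            seg.territory_labels == cell,
            image.pixel_size_um,
            ring_width_um=ring_width_um,
            n_rings=n_rings,
            clip_to_territory=clip_to_territory,
            cell_id=cell,
        )
        out[cell] = [
            compute_region_metrics(
                seg.mito_mask == cell,
                ring_mask,
                image.marker_channel,
                image.potential_channel,
                image.pixel_size_um,
                cell_id=cell,
                region_id=f"ring{k}",
                ratio_mode=ratio_mode,
            )
            for k, ring_mask in enumerate(rings.ring_masks, start=1)
        ]
    return out


def ring_profile(
    cell_ring_metrics: list[RegionMetrics], metric_name: str
) -> RingProfile | None:
    """Normalize a cell's ring metrics to ring 1.

    Returns None (and logs) when ring 1 is invalid or zero -- the cell is
    excluded from profile averaging, which the caller counts in its QC
    report.  Later rings that are invalid yield NaN entries.
    """
    if not cell_ring_metrics:
        raise ValueError("no ring metrics supplied")
    first = cell_ring_metrics[0]
    ref = first.value(metric_name) if first.valid else math.nan
    if not first.valid or not math.isfinite(ref) or ref == 0:
        log.info("cell %s excluded: ring-1 %s invalid or zero", first.cell_id, metric_name)
        return None
    values = [
        m.value(metric_name) if m.valid else math.nan for m in cell_ring_metrics
    ]
    return RingProfile(
        cell_id=first.cell_id,
        metric_name=metric_name,
        values_by_ring=values,
        normalized_by_ring=[v / ref for v in values],
    )
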