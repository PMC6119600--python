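"""Synthetic fluorescence scenes with ground truth.

Generates fields of adherent epithelial-like cells: an elliptical nucleus per
cell and a perinuclear-to-peripheral network of curvilinear mitochondrial
objects (dilated random-walk polylines).  Channel intensities follow
programmed linear laws in the distance ``d`` (µm) from the nucleus boundary:

    marker(d)    = marker_density * (1 + marker_slope_per_um * d)
    potential(d) = marker(d) * polarization_base * (1 + polarization_slope_per_um * d)

so the potential-per-marker ratio carries a known radial polarization
gradient that the ring analysis must recover.  Camera noise is Poisson on
the signal (scaled) plus additive Gaussian background noise.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .image import MultiChannelImage

#: Rendered intensity inside nuclei (a.u.), before noise.
NUCLEUS_INTENSITY = 400.0


class PlacementError(RuntimeError):
    """Raised when scene geometry cannot be placed under its constraints."""


def _dilate(mask: np.ndarray, radius: int) -> np.ndarray:
    return ndimage.binary_dilation(mask, structure=disk(radius))


def _crop_dilate(
    points: list[tuple[int, int]], shape: tuple[int, int], radius: int
) -> tuple[slice, slice, np.ndarray]:
    """Rasterize a polyline and dilate it inside a padded bounding box."""
    ys = [p[0] for p in points]
    xs = [p[1] for p in points]
    pad = radius + 1
    r0, r1 = max(min(ys) - pad, 0), min(max(ys) + pad + 1, shape[0])
    c0, c1 = max(min(xs) - pad, 0), min(max(xs) + pad + 1, shape[1])
    crop = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    for (y0, x0), (y1, x1) in zip(points[:-1], points[1:]):
        rr, cc = draw_line(y0 - r0, x0 - c0, y1 - r0, x1 - c0)
        crop[rr, cc] = True
    crop[points[0][0] - r0, points[0][1] - c0] = True
    return slice(r0, r1), slice(c0, c1), _dilate(crop, radius)


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic field.

    Defaults emulate a 63x confocal field of renal proximal tubule epithelial
    cells: 102 µm field at 0.2 µm/px, nuclei with 4-6.5 µm semi-axes, ~20
    mitochondrial objects per cell, and a positive polarization gradient
    (potential-per-marker rising away from the nucleus) over a declining
    marker density, as seen in control cells.  Default noise gives a marker
    signal-to-noise ratio near 10.
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = 0.2
    n_cells: int = 4
    nucleus_radii_um: tuple[float, float] = (4.0, 6.5)
    mito_object_count_per_cell: int = 20
    mito_object_length_um: float = 4.0
    mito_width_um: float = 0.5
    marker_density: float = 150.0
    polarization_base: float = 1.5
    polarization_slope_per_um: float = 0.05
    marker_slope_per_um: float = -0.03
    background_level: float = 50.0
    gaussian_noise_sd: float = 6.0
    poisson_scaling: float = 1.0
    seed: int = 0
    # placement constraints (not part of the imaging model)
    max_extent_um: float = 12.0
    min_object_gap_px: int = 2
    ring_width_um: float = 1.0
    n_rings: int = 4

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if min(self.nucleus_radii_um) <= 0:
            raise ValueError("nucleus semi-axes must be positive")
        if self.mito_object_count_per_cell < 1:
            raise ValueError("mito_object_count_per_cell must be >= 1")


@dataclass
class SyntheticScene:
    """A placed scene: geometry, ownership and the ground-truth table.

    ``truth_table`` has one row per cell with the programmed object count,
    total mitochondrial area (µm²), a border flag, and the true per-ring
    potential/marker ratio (ratio of pre-noise sums over ring pixels).
    """

    params: SceneParams
    nuclei: np.ndarray  # labeled nucleus mask, 0 = background
    territory_labels: np.ndarray  # nearest-nucleus partition of the field
    mito_truth_mask: np.ndarray  # labeled by owning cell
    mito_object_labels: np.ndarray  # labeled by object id (1..N over the field)
    distance_um: np.ndarray  # Euclidean distance to the nearest nucleus, µm
    truth_table: pd.DataFrame

    def render(self) -> MultiChannelImage:
        return render(self)


def _nearest_nucleus_partition(nuclei: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance (px) to the nearest nucleus pixel and the label of that pixel."""
    dist, (ir, ic) = ndimage.distance_transform_edt(nuclei == 0, return_indices=True)
    return dist, nuclei[ir, ic]


def _place_nuclei(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.field_size_px
    ps = params.pixel_size_um
    rmin, rmax = sorted(params.nucleus_radii_um)
    gap_px = max(2, int(round(3.0 / ps)))  # >= 3 µm between nuclei
    labels = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    for cell in range(1, params.n_cells + 1):
        placed = False
        for _ in range(300):
            a = rng.uniform(rmin, rmax) / ps
            b = rng.uniform(rmin, rmax) / ps
            theta = rng.uniform(0, math.pi)
            margin = max(a, b) + 2
            if 2 * margin >= min(h, w):
                break
            cy = rng.uniform(margin, h - 1 - margin)
            cx = rng.uniform(margin, w - 1 - margin)
            rr, cc = draw_ellipse(cy, cx, a, b, shape=(h, w), rotation=theta)
            cand = np.zeros((h, w), dtype=bool)
            cand[rr, cc] = True
            grown = _dilate(cand, gap_px)
            if not (grown & occupied).any():
                labels[cand] = cell
                occupied |= cand
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place nucleus {cell}/{params.n_cells} in a "
                f"{h}x{w} px field without overlap (>= {gap_px} px gap); "
                "reduce n_cells or nucleus_radii_um, or enlarge the field"
            )
    return labels


def _walk_object(
    start: tuple[int, int],
    allowed: np.ndarray,
    n_steps: int,
    step_px: float,
    outward: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Persistent random walk with outward drift, confined to ``allowed``."""
    h, w = allowed.shape
    pts = [start]
    y, x = float(start[0]), float(start[1])
    heading = float(outward[start[0], start[1]]) + rng.normal(0, 0.6)
    for _ in range(n_steps):
        moved = False
        for _ in range(8):
            trial = heading + rng.normal(0, 0.5)
            ny = y + step_px * math.sin(trial)
            nx = x + step_px * math.cos(trial)
            iy, ix = int(round(ny)), int(round(nx))
            if 0 <= iy < h and 0 <= ix < w and allowed[iy, ix]:
                # mild drift back toward the local outward direction
                heading = 0.8 * trial + 0.2 * float(outward[iy, ix])
                y, x = ny, nx
                pts.append((iy, ix))
                moved = True
                break
        if not moved:
            break
    return pts


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Place nuclei and mitochondrial objects; compute the truth table.

    Identical ``params`` (including the seed) give bit-identical scenes.
    Mitochondrial objects are confined to their own cell's territory, kept
    clear of nuclei, and separated from each other by at least
    ``min_object_gap_px`` pixels so that the programmed object count is
    recoverable by connected-component analysis.

    Raises
    ------
    PlacementError
        If nuclei or objects cannot be placed after bounded retries.
    """
    rng = np.random.default_rng([max(params.seed, 0) % (2**31), 11])
    h, w = params.field_size_px
    ps = params.pixel_size_um

    nuclei = _place_nuclei(params, rng)
    dist_px, territory = _nearest_nucleus_partition(nuclei)
    # half-pixel boundary correction: distance 0 at the nucleus boundary,
    # matching the ring-construction convention of the analysis
    dist_um = np.maximum(dist_px - 0.5, 0.0) * ps

    # outward direction = gradient of the distance map
    gy, gx = np.gradient(ndimage.gaussian_filter(dist_px, 2.0))
    outward = np.arctan2(gy, gx)

    half_width_px = max(1, int(round(params.mito_width_um / (2 * ps))))
    gap_px = half_width_px + params.min_object_gap_px
    step_px = max(1.5, 0.4 / ps)
    n_steps = max(2, int(round(params.mito_object_length_um / (step_px * ps))))

    mito_cells = np.zeros((h, w), dtype=np.int32)
    mito_objects = np.zeros((h, w), dtype=np.int32)
    occupied_grown = np.zeros((h, w), dtype=bool)

    obj_id = 0
    for cell in range(1, params.n_cells + 1):
        own = territory == cell
        # clearance from territory boundary so dilated objects stay inside
        clear = ndimage.distance_transform_edt(own) > (half_width_px + 1)
        allowed = (
            clear
            & (dist_um >= params.mito_width_um / 2 + ps)
            & (dist_um <= params.max_extent_um)
        )
        # seed new objects preferentially near the nucleus (perinuclear density)
        seed_zone = allowed & (dist_um <= max(3.0, 4 * ps))
        seed_idx = np.flatnonzero(seed_zone)
        any_idx = np.flatnonzero(allowed)
        if any_idx.size == 0:
            raise PlacementError(
                f"cell {cell}: no admissible pixels for mitochondria "
                f"(max_extent_um={params.max_extent_um}, field too crowded)"
            )
        for _ in range(params.mito_object_count_per_cell):
            placed = False
            for attempt in range(80):
                pool = seed_idx if (seed_idx.size and rng.random() < 0.7) else any_idx
                flat = int(pool[rng.integers(pool.size)])
                start = (flat // w, flat % w)
                pts = _walk_object(start, allowed, n_steps, step_px, outward, rng)
                rs, cs, cand = _crop_dilate(pts, (h, w), half_width_px)
                if (cand & occupied_grown[rs, cs]).any():
                    continue
                obj_id += 1
                mito_cells[rs, cs][cand] = cell
                mito_objects[rs, cs][cand] = obj_id
                _, _, grown = _crop_dilate(pts, (h, w), half_width_px + params.min_object_gap_px)
                rs2 = slice(max(rs.start - params.min_object_gap_px, 0), min(rs.stop + params.min_object_gap_px, h))
                cs2 = slice(max(cs.start - params.min_object_gap_px, 0), min(cs.stop + params.min_object_gap_px, w))
                occupied_grown[rs2, cs2] |= grown
                placed = True
                break
            if not placed:
                placed_so_far = len(np.unique(mito_cells[territory == cell])) - 1
                raise PlacementError(
                    f"cell {cell}: could not place mitochondrial object "
                    f"{placed_so_far + 1}/{params.mito_object_count_per_cell} "
                    f"after 80 attempts (min gap {params.min_object_gap_px} px); "
                    "lower the object count or the gap"
                )

    truth = _truth_table(params, nuclei, territory, mito_cells, dist_um)
    return SyntheticScene(
        params=params,
        nuclei=nuclei,
        territory_labels=territory,
        mito_truth_mask=mito_cells,
        mito_object_labels=mito_objects,
        distance_um=dist_um,
        truth_table=truth,
    )


def _programmed_intensities(params: SceneParams, d_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    marker = params.marker_density * (1 + params.marker_slope_per_um * d_um)
    potential = marker * params.polarization_base * (1 + params.polarization_slope_per_um * d_um)
    return marker, potential


def _truth_table(
    params: SceneParams,
    nuclei: np.ndarray,
    territory: np.ndarray,
    mito_cells: np.ndarray,
    dist_um: np.ndarray,
) -> pd.DataFrame:
    h, w = nuclei.shape
    px_area = params.pixel_size_um**2
    rows = []
    border = np.zeros(nuclei.max() + 1, dtype=bool)
    edge = np.zeros_like(nuclei, dtype=bool)
    edge[0, :] = edge[-1, :] = edge[:, 0] = edge[:, -1] = True
    for lab in np.unique(nuclei[nuclei > 0]):
        border[lab] = bool((nuclei == lab)[edge].any())
    for cell in range(1, params.n_cells + 1):
        mito = mito_cells == cell
        d = dist_um[mito]
        marker, potential = _programmed_intensities(params, d)
        n_objects = len(np.unique(
            ndimage.label(mito, structure=np.ones((3, 3)))[0][mito]
        ))
        row = {
            "cell_id": cell,
            "object_count": n_objects,
            "mito_area_um2": float(mito.sum()) * px_area,
            "border_flag": bool(border[cell]),
        }
        wd = params.ring_width_um
        for k in range(1, params.n_rings + 1):
            in_ring = (d >= (k - 1) * wd) & (d < k * wd)
            if in_ring.any() and marker[in_ring].sum() > 0:
                row[f"true_ratio_ring{k}"] = float(
                    potential[in_ring].sum() / marker[in_ring].sum()
                )
            else:
                row[f"true_ratio_ring{k}"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def render(scene: SyntheticScene) -> MultiChannelImage:
    """Render the three channels from the scene's programmed intensity laws.

    Pre-noise intensities follow the linear distance laws exactly on
    mitochondrial pixels; the nucleus channel is flat inside nuclei.  Then
    ``background_level`` is added, Poisson noise is applied to the full
    signal (scaled by ``poisson_scaling``; 0 disables it), Gaussian noise of
    ``gaussian_noise_sd`` is added, and the result is clipped at 0.

    Raises
    ------
    ValueError
        If the programmed slopes drive any pre-noise intensity negative over
        the placed mitochondria.
    """
    p = scene.params
    mito = scene.mito_truth_mask > 0
    d = scene.distance_um
    marker = np.zeros(scene.nuclei.shape, dtype=float)
    potential = np.zeros_like(marker)
    m_vals, p_vals = _programmed_intensities(p, d[mito])
    if mito.any() and (m_vals.min() < 0 or p_vals.min() < 0):
        raise ValueError(
            "programmed slopes produce negative pre-noise intensity at "
            f"distance {d[mito].max():.1f} µm; shrink |marker_slope_per_um| / "
            "|polarization_slope_per_um| or max_extent_um"
        )
    marker[mito] = m_vals
    potential[mito] = p_vals
    nucleus = np.where(scene.nuclei > 0, NUCLEUS_INTENSITY, 0.0)

    rng = np.random.default_rng([max(p.seed, 0) % (2**31), 29])
    out = []
    for chan in (nucleus, marker, potential):
        img = chan + p.background_level
        if p.poisson_scaling > 0:
            img = rng.poisson(img * p.poisson_scaling).astype(float) / p.poisson_scaling
        if p.gaussian_noise_sd > 0:
            img = img + rng.normal(0, p.gaussian_noise_sd, size=img.shape)
        out.append(np.clip(img, 0, None))
    return MultiChannelImage(out[0], out[1], out[2], p.pixel_size_um)


# ---------------------------------------------------------------------------
# scenario presets

#: Treatment scenarios, expressed as parameter overrides of the vehicle
#: condition.  Magnitudes are design choices emulating the qualitative
#: effects of AMPK-modulating drugs on renal epithelial cells:
#:   hyperpolarized_fragmented  -- raised potential per marker, more and
#:                                 shorter objects (compound C-like);
#:   marker_up_gradient_steep   -- more marker per pixel and a steeper
#:                                 polarization gradient (phenformin-like);
#:   gradient_flattened         -- polarization gradient near zero
#:                                 (resveratrol-like).
PRESETS: dict[str, dict] = {
    "vehicle": {},
    "hyperpolarized_fragmented": {
        "polarization_base": 1.5 * 1.3,
        "mito_object_count_per_cell": 36,
        "mito_object_length_um": 2.0,
    },
    "marker_up_gradient_steep": {
        "marker_density": 150.0 * 1.25,
        "polarization_slope_per_um": 0.10,
    },
    "gradient_flattened": {
        "polarization_slope_per_um": 0.005,
    },
}


def scenario_preset(name: str, seed: int = 0, **overrides) -> SceneParams:
    """Parameter set for a named treatment scenario.

    Extra keyword overrides (e.g. ``n_cells``) are applied on top of the
    preset.  Unknown names raise with the list of available presets.
    """
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    kwargs = dict(PRESETS[name])
    kwargs.update(overrides)
    kwargs["seed"] = seed
    return SceneParams(**kwargs)


def match_cells(scene: SyntheticScene, nucleus_labels: np.ndarray) -> dict[int, int]:
    """Map segmentation labels to ground-truth cell ids via nucleus overlap."""
    out: dict[int, int] = {}
    for lab in np.unique(nucleus_labels[nucleus_labels > 0]):
        overlap = scene.nuclei[nucleus_labels == lab]
        vals, counts = np.unique(overlap[overlap > 0], return_counts=True)
        if vals.size:
            out[int(lab)] = int(vals[np.argmax(counts)])
    return out


# ---------------------------------------------------------------------------
# on-disk artifacts


def save_scene(scene: SyntheticScene, out_dir: str | Path) -> dict[str, Path]:
    """Write the rendered OME-TIFF, label masks and the truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "image.ome.tif",
        "nuclei": out / "nuclei_labels.tif",
        "mito": out / "mito_labels.tif",
        "truth": out / "truth.json",
    }
    scene.render().save(paths["image"])
    tifffile.imwrite(str(paths["nuclei"]), scene.nuclei.astype(np.uint16))
    tifffile.imwrite(str(paths["mito"]), scene.mito_truth_mask.astype(np.uint16))
    payload = {
        "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(scene.params).items()},
        "truth_table": scene.truth_table.to_dict(orient="records"),
    }
    paths["truth"].write_text(json.dumps(payload, indent=2))
    return paths
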