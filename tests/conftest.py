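import numpy as np
import pytest
from dataclasses import replace

from mitoring.synthetic import generate_scene, render, scenario_preset
from mitoring.segment import segment_image


@pytest.fixture(scope="session")
def vehicle_scene():
    return generate_scene(scenario_preset("vehicle", seed=11))


@pytest.fixture(scope="session")
def vehicle_image(vehicle_scene):
    return render(vehicle_scene)


@pytest.fixture(scope="session")
def vehicle_segmented(vehicle_image):
    return segment_image(vehicle_image)


@pytest.fixture(scope="session")
def noiseless_scene():
    params = replace(
        scenario_preset("vehicle", seed=11),
        gaussian_noise_sd=0.0,
        poisson_scaling=0.0,
    )
    return generate_scene(params)


@pytest.fixture(scope="session")
def noiseless_image(noiseless_scene):
    return render(noiseless_scene)


@pytest.fixture(scope="session")
def noiseless_segmented(noiseless_image):
    return segment_image(noiseless_image)


def random_nucleus_mask(rng: np.random.Generator, shape=(128, 128)) -> np.ndarray:
    """A random blob-shaped nucleus mask (non-empty) for oracle tests."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(rng.normal(size=shape), 8.0)
    mask = field > np.quantile(field, 0.93)
    # keep the largest connected component so the mask is one nucleus
    labels, n = ndimage.label(mask)
    if n == 0:
        mask = np.zeros(shape, dtype=bool)
        mask[shape[0] // 2, shape[1] // 2] = True
        return mask
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def brute_force_ring_index(
    nucleus_mask: np.ndarray, pixel_size_um: float, ring_width_um: float, n_rings: int
) -> np.ndarray:
    """Exhaustive nearest-nucleus-pixel scan -> ring index map (0 = none)."""
    ny, nx = np.nonzero(nucleus_mask)
    h, w = nucleus_mask.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1).astype(float)
    nuc = np.stack([ny, nx], axis=1).astype(float)
    out = np.zeros(h * w, dtype=np.int32)
    chunk = 2048
    for i in range(0, pts.shape[0], chunk):
        d2 = (
            (pts[i : i + chunk, 0:1] - nuc[None, :, 0]) ** 2
            + (pts[i : i + chunk, 1:2] - nuc[None, :, 1]) ** 2
        ).min(axis=1)
        d_um = np.maximum(np.sqrt(d2) - 0.5, 0.0) * pixel_size_um
        ring = np.zeros(d_um.shape, dtype=np.int32)
        for k in range(1, n_rings + 1):
            sel = (d_um >= (k - 1) * ring_width_um) & (d_um < k * ring_width_um)
            ring[sel] = k
        out[i : i + chunk] = ring
    out = out.reshape(h, w)
    out[nucleus_mask] = 0
    return out
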