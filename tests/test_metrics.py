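"""Region metrics: ratio definitions, linearity, additivity, profiles."""

import math

import numpy as np
import pytest

from mitoring.metrics import (
    compute_region_metrics,
    ring_metrics,
    ring_profile,
    whole_cell_metrics,
)
from mitoring.synthetic import match_cells


def uniform_case(marker_val=1.0, potential_val=2.0, n_px=100, pixel_size=1.0):
    shape = (20, 20)
    mito = np.zeros(shape, dtype=bool)
    mito.ravel()[:n_px] = True
    region = np.ones(shape, dtype=bool)
    marker = np.full(shape, marker_val)
    potential = np.full(shape, potential_val)
    return mito, region, marker, potential, pixel_size


def test_ratio_is_sum_potential_over_sum_marker():
    mito, region, marker, potential, ps = uniform_case(100 / 100, 200 / 100)
    m = compute_region_metrics(mito, region, marker, potential, ps)
    assert m.sum_marker == pytest.approx(100)
    assert m.sum_potential == pytest.approx(200)
    assert m.ratio_potential_marker == pytest.approx(2.0)


def test_whole_cell_example_area_and_ratios():
    mito, region, marker, potential, ps = uniform_case(1.0, 2.0, n_px=100)
    m = compute_region_metrics(mito, region, marker, potential, ps)
    assert m.mito_area_um2 == pytest.approx(100.0)
    assert m.ratio_potential_marker == pytest.approx(2.0)
    assert m.potential_per_area == pytest.approx(2.0)
    assert m.marker_per_area == pytest.approx(1.0)


def test_empty_intersection_is_invalid_not_zero():
    mito, _, marker, potential, ps = uniform_case()
    m = compute_region_metrics(mito, np.zeros_like(mito), marker, potential, ps)
    assert not m.valid
    assert math.isnan(m.ratio_potential_marker)
    assert math.isnan(m.potential_per_area)
    assert m.mito_area_px == 0


def test_scaling_potential_scales_ratio_and_density_exactly():
    mito, region, marker, potential, ps = uniform_case()
    base = compute_region_metrics(mito, region, marker, potential, ps)
    scaled = compute_region_metrics(mito, region, marker, potential * 3.0, ps)
    assert scaled.ratio_potential_marker == base.ratio_potential_marker * 3.0
    assert scaled.potential_per_area == base.potential_per_area * 3.0
    assert scaled.marker_per_area == base.marker_per_area


def test_scaling_both_channels_leaves_ratio_unchanged():
    rng = np.random.default_rng(0)
    mito, region, _, _, ps = uniform_case()
    marker = rng.uniform(50, 150, mito.shape)
    potential = rng.uniform(50, 300, mito.shape)
    a = compute_region_metrics(mito, region, marker, potential, ps)
    b = compute_region_metrics(mito, region, marker * 5.0, potential * 5.0, ps)
    assert b.ratio_potential_marker == pytest.approx(a.ratio_potential_marker, abs=1e-12)


def test_shape_mismatch_errors():
    mito, region, marker, potential, ps = uniform_case()
    with pytest.raises(ValueError):
        compute_region_metrics(mito[:10], region, marker, potential, ps)


def test_additivity_over_disjoint_regions():
    rng = np.random.default_rng(1)
    mito, _, _, _, ps = uniform_case(n_px=300)
    marker = rng.uniform(1, 10, mito.shape)
    potential = rng.uniform(1, 10, mito.shape)
    left = np.zeros_like(mito)
    left[:, :10] = True
    right = ~left
    whole = compute_region_metrics(mito, np.ones_like(mito), marker, potential, ps)
    a = compute_region_metrics(mito, left, marker, potential, ps)
    b = compute_region_metrics(mito, right, marker, potential, ps)
    assert a.mito_area_px + b.mito_area_px == whole.mito_area_px
    assert a.sum_marker + b.sum_marker == pytest.approx(whole.sum_marker)
    assert (a.sum_potential + b.sum_potential) / (a.sum_marker + b.sum_marker) == pytest.approx(
        whole.ratio_potential_marker
    )


class TestRingProfile:
    def make_metrics(self, values):
        mito, region, _, _, ps = uniform_case()
        out = []
        for k, v in enumerate(values, start=1):
            m = compute_region_metrics(
                mito, region, np.ones(mito.shape), np.full(mito.shape, float(v)), ps,
                region_id=f"ring{k}",
            )
            out.append(m)
        return out

    def test_normalizes_to_ring_one(self):
        prof = ring_profile(self.make_metrics([2, 3, 4, 5]), "ratio_potential_marker")
        assert prof.normalized_by_ring == pytest.approx([1.0, 1.5, 2.0, 2.5])

    def test_cell_with_invalid_ring_one_excluded(self):
        metrics = self.make_metrics([2, 3, 4, 5])
        empty = compute_region_metrics(
            np.zeros((20, 20), dtype=bool), np.ones((20, 20), dtype=bool),
            np.ones((20, 20)), np.ones((20, 20)), 1.0,
        )
        assert ring_profile([empty] + metrics[1:], "ratio_potential_marker") is None


def test_flat_gradient_profile_is_unity(noiseless_scene):
    from dataclasses import replace
    from mitoring.segment import segment_image
    from mitoring.synthetic import generate_scene, render

    params = replace(
        noiseless_scene.params, polarization_slope_per_um=0.0, marker_slope_per_um=0.0,
        n_cells=1, field_size_px=(256, 256),
    )
    scene = generate_scene(params)
    seg, corr = segment_image(render(scene))
    for cms in ring_metrics(seg, corr).values():
        prof = ring_profile(cms, "ratio_potential_marker")
        if prof is None:
            continue
        finite = [v for v in prof.normalized_by_ring if math.isfinite(v)]
        assert finite == pytest.approx([1.0] * len(finite), rel=1e-9)


def test_noiseless_profile_matches_pixelwise_truth(noiseless_scene, noiseless_segmented):
    """Ring ratios from the pipeline equal a brute-force recomputation from
    generator truth (programmed intensities on truth pixels, same binning)."""
    seg, corr = noiseless_segmented
    p = noiseless_scene.params
    mapping = match_cells(noiseless_scene, seg.nucleus_labels)
    checked = 0
    for cell, cms in ring_metrics(seg, corr).items():
        prof = ring_profile(cms, "ratio_potential_marker")
        if prof is None:
            continue
        truth_row = noiseless_scene.truth_table.set_index("cell_id").loc[mapping[cell]]
        for k, value in enumerate(prof.values_by_ring, start=1):
            expected = truth_row[f"true_ratio_ring{k}"]
            if math.isfinite(expected) and math.isfinite(value):
                assert value == pytest.approx(expected, rel=0.01)
                checked += 1
    assert checked >= 8


def test_whole_cell_sums_equal_union_of_extended_rings(noiseless_scene, noiseless_segmented):
    seg, corr = noiseless_segmented
    cell = seg.cell_ids[0]
    whole = [m for m in whole_cell_metrics(seg, corr) if m.cell_id == cell][0]
    # enough territory-clipped rings to cover the whole territory
    from mitoring.rings import build_rings
    from mitoring.metrics import compute_region_metrics

    rings = build_rings(
        seg.nucleus_labels == cell, seg.territory_labels == cell,
        corr.pixel_size_um, n_rings=120, clip_to_territory=True,
    )
    total_marker = sum(
        compute_region_metrics(
            seg.mito_mask == cell, rm, corr.marker_channel, corr.potential_channel,
            corr.pixel_size_um,
        ).sum_marker
        for rm in rings.ring_masks
    )
    assert total_marker == pytest.approx(whole.sum_marker, rel=1e-9)
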