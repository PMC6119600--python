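"""Simulation experiments quantifying what the pipeline recovers.

Each function renders synthetic fields with known ground truth, runs the
full analysis (background correction, segmentation, rings, metrics) and
returns measured-versus-programmed quantities.  They power the numbered
analysis scripts and the validation summary.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd

from .metrics import ring_metrics, ring_profile, whole_cell_metrics
from .morphology import measure_morphology
from .segment import segment_image
from .synthetic import SceneParams, generate_scene, match_cells, render, scenario_preset


def _derive_seed(base: int, *idx: int) -> int:
    s = base
    for i in idx:
        s = (s * 9973 + i * 131 + 17) % (2**31)
    return s


def quantify_fields(
    preset: str,
    seeds: list[int],
    overrides: dict | None = None,
    noiseless: bool = False,
) -> pd.DataFrame:
    """Render fields and return one row per analyzed cell.

    Columns combine pipeline measurements (whole-cell metrics, normalized
    ring ratios, object counts) with the matched ground truth for the same
    cell.  Cells excluded by ring-1 QC carry NaN profile entries.
    """
    rows = []
    for seed in seeds:
        params = scenario_preset(preset, seed=seed, **(overrides or {}))
        if noiseless:
            params = replace(params, gaussian_noise_sd=0.0, poisson_scaling=0.0)
        scene = generate_scene(params)
        seg, corr = segment_image(render(scene))
        mapping = match_cells(scene, seg.nucleus_labels)
        truth = scene.truth_table.set_index("cell_id")
        rings = ring_metrics(seg, corr)
        whole = {m.cell_id: m for m in whole_cell_metrics(seg, corr)}
        for cell in seg.cell_ids:
            t = truth.loc[mapping[cell]]
            w = whole[cell]
            morph = measure_morphology(seg.mito_mask == cell, corr.pixel_size_um, cell)
            row = {
                "seed": seed,
                "cell": cell,
                "ratio_potential_marker": w.ratio_potential_marker,
                "potential_per_area": w.potential_per_area,
                "marker_per_area": w.marker_per_area,
                "mito_area_um2": w.mito_area_um2,
                "object_count": morph.object_count,
                "true_object_count": int(t["object_count"]),
                "true_mito_area_um2": float(t["mito_area_um2"]),
            }
            prof = ring_profile(rings[cell], "ratio_potential_marker")
            for k in range(1, 5):
                true_k = t[f"true_ratio_ring{k}"]
                true_1 = t["true_ratio_ring1"]
                row[f"norm_ring{k}"] = (
                    prof.normalized_by_ring[k - 1] if prof is not None else math.nan
                )
                row[f"true_norm_ring{k}"] = (
                    true_k / true_1 if math.isfinite(true_k) and true_1 else math.nan
                )
            rows.append(row)
    return pd.DataFrame(rows)


def gradient_recovery(seed: int, n_cells: int = 50, noiseless: bool = False) -> dict:
    """How well the ring analysis recovers the programmed polarization
    gradient: mean measured vs mean true normalized ring-4 ratio over at
    least ``n_cells`` analyzed cells."""
    n_fields = max(1, int(np.ceil(n_cells / SceneParams().n_cells)))
    seeds = [_derive_seed(seed, 1, i) for i in range(n_fields)]
    df = quantify_fields("vehicle", seeds, noiseless=noiseless)
    ok = df.dropna(subset=["norm_ring4", "true_norm_ring4"])
    per_ring_err = {}
    for k in range(2, 5):
        sub = df.dropna(subset=[f"norm_ring{k}", f"true_norm_ring{k}"])
        per_ring_err[k] = float(
            abs(sub[f"norm_ring{k}"].mean() / sub[f"true_norm_ring{k}"].mean() - 1)
        )
    return {
        "n_cells": int(len(ok)),
        "measured_ring4": float(ok["norm_ring4"].mean()),
        "true_ring4": float(ok["true_norm_ring4"].mean()),
        "ring4_rel_err": float(abs(ok["norm_ring4"].mean() / ok["true_norm_ring4"].mean() - 1)),
        "max_ring_rel_err": max(per_ring_err.values()),
    }


def noiseless_profile_max_error(seed: int) -> dict:
    """Per-cell agreement between measured and programmed ring profiles in a
    noiseless render (pixel-level truth, same binning)."""
    df = quantify_fields("vehicle", [_derive_seed(seed, 2, 0)], noiseless=True)
    errs = []
    for k in range(1, 5):
        sub = df.dropna(subset=[f"norm_ring{k}", f"true_norm_ring{k}"])
        if len(sub):
            errs.append(
                float(np.abs(sub[f"norm_ring{k}"] / sub[f"true_norm_ring{k}"] - 1).max())
            )
    return {"max_rel_err": max(errs), "n_cells": int(len(df))}


def effect_recovery(seed: int, factors=(1.1, 1.25, 1.5), n_cells: int = 50) -> dict:
    """Recovery of programmed whole-cell potential effects: the treated
    condition scales polarization_base by ``f``; the estimate is the ratio
    of group mean MitoTracker/Tom70 ratios."""
    n_fields = max(1, int(np.ceil(n_cells / SceneParams().n_cells)))
    vehicle = quantify_fields(
        "vehicle", [_derive_seed(seed, 3, i) for i in range(n_fields)]
    )
    base = scenario_preset("vehicle").polarization_base
    out = {}
    for j, f in enumerate(factors):
        treated = quantify_fields(
            "vehicle",
            [_derive_seed(seed, 4 + j, i) for i in range(n_fields)],
            overrides={"polarization_base": base * f},
        )
        est = treated["ratio_potential_marker"].mean() / vehicle["ratio_potential_marker"].mean()
        out[f] = {
            "estimate": float(est),
            "abs_err": float(abs(est - f)),
            "n_per_group": int(min(len(vehicle), len(treated))),
        }
    return out


def fragmentation_recovery(seed: int, n_fields: int = 3, noiseless: bool = False) -> dict:
    """Recovery of programmed object counts in the fragmented scenario."""
    seeds = [_derive_seed(seed, 8, i) for i in range(n_fields)]
    df = quantify_fields("hyperpolarized_fragmented", seeds, noiseless=noiseless)
    exact = float((df["object_count"] == df["true_object_count"]).mean())
    total_err = float(
        abs(df["object_count"].sum() / df["true_object_count"].sum() - 1)
    )
    return {
        "n_cells": int(len(df)),
        "fraction_exact": exact,
        "total_count_rel_err": total_err,
    }


def t_test_type_one_error(seed: int, n_reps: int = 1000, n: int = 35, alpha: float = 0.05) -> float:
    """Null rejection rate of the package's two-tailed t-test."""
    from .stats import t_test_two_tailed

    rng = np.random.default_rng(_derive_seed(seed, 9))
    hits = 0
    for _ in range(n_reps):
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        if t_test_two_tailed(a, b).p_raw < alpha:
            hits += 1
    return hits / n_reps
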