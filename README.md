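# mitoring

Ring-resolved quantification of mitochondrial membrane-potential readouts in
2D fluorescence micrographs, with a synthetic ground-truth image generator.

## The problem

Mitochondria within a single cell are not uniform: their membrane potential
(Δψ_m) and mass density depend on where the organelle sits relative to the
nucleus. A standard way to quantify this in adherent cells (e.g. renal
proximal tubule epithelium) images three channels — DAPI (nuclei), Tom70
immunofluorescence (an outer-membrane import receptor marking the
mitochondrial compartment and serving as a mass proxy) and MitoTracker
CMX ROS (a fixable potential-dependent dye) — and computes, per cell and per
region:

* **MitoTracker/Tom70** = Σ potential / Σ marker over the mitochondrial
  compartment — Δψ_m normalized to mitochondrial mass;
* **MitoTracker/area** = Σ potential / mitochondrial area (a.u./µm²);
* **Tom70/area** = Σ marker / mitochondrial area (a.u./µm²).

Spatial heterogeneity is resolved with concentric rings around each nucleus:
ring *k* contains the pixels whose Euclidean distance *d* from the nucleus
boundary satisfies (k−1)·w ≤ d < k·w with w = 1 µm, four rings per cell,
no overlap. Ring 1 is perinuclear; profiles are normalized to ring 1.
Fragmentation of the network is summarized as connected-component
morphometrics (objects per µm² of mitochondrial area).

Because no public raw micrographs accompany this assay, the package ships a
synthetic scene generator that renders fields of cells with elliptical
nuclei and curvilinear mitochondria whose channel intensities follow
programmed linear distance laws

    marker(d)    = m0 · (1 + s_m · d)
    potential(d) = marker(d) · b · (1 + s_p · d)

plus Poisson/Gaussian camera noise — so every stage of the analysis can be
validated against exact ground truth.

## Worked example

```python
from mitoring import (scenario_preset, generate_scene, render, segment_image,
                      whole_cell_metrics, ring_metrics, ring_profile)
from mitoring.stats import summarize

scene = generate_scene(scenario_preset("vehicle", seed=7))
seg, corrected = segment_image(render(scene))
for m in whole_cell_metrics(seg, corrected):
    print(f"cell {m.cell_id}: mito area {m.mito_area_um2:.1f} um^2, "
          f"MitoTracker/Tom70 {m.ratio_potential_marker:.3f}")

profiles = [ring_profile(rm, "ratio_potential_marker")
            for rm in ring_metrics(seg, corrected).values()]
ring4 = summarize([p.normalized_by_ring[3] for p in profiles if p is not None])
print(f"ring 4 vs ring 1 (n={ring4.n} cells): {ring4.mean:.3f} +/- {ring4.sem:.3f}")
```

prints

```
cell 1: mito area 39.3 um^2, MitoTracker/Tom70 1.881
cell 2: mito area 45.6 um^2, MitoTracker/Tom70 1.919
cell 3: mito area 44.1 um^2, MitoTracker/Tom70 1.855
cell 4: mito area 41.6 um^2, MitoTracker/Tom70 1.924
ring 4 vs ring 1 (n=4 cells): 1.075 +/- 0.043
```

Per-cell MitoTracker/Tom70 sits near the programmed polarization base
(1.5 a.u./a.u. at the nucleus boundary, rising 5%/µm outward, averaged over
the compartment), and the ring-4/ring-1 ratio above 1 recovers the
programmed outward polarization gradient of the vehicle scenario.

The same workflow is available from a shell:

```
mitoring simulate --preset vehicle --seed 7 --out sim/
mitoring quantify --in sim/image.ome.tif --out out/
mitoring profile  --in sim/image.ome.tif --out out/
mitoring run      --config cfg.yaml --seed 7 --out results/
```

The `analysis/` directory contains numbered drivers that run the full study
narrative (simulate scenarios, whole-cell comparisons, ring profiles,
fragmentation, ground-truth recovery) and write tables under `results/`.

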