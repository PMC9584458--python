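# holowbc

A holographic-projection toolkit for visualizing and discriminating normal
and cancer white blood cells (WBCs) in stained peripheral-blood-film
images — implemented as a fully numerical, desk-scale pipeline.

Manual examination of blood films is slow and observer-dependent.  One
proposed alternative is to segment individual WBCs from microscope images,
encode them as phase-only computer-generated holograms (CGHs), and project
them optically: a single 2D hologram can then display a cell floating in
air, bring individual structures (cell body, edges, nucleus) into focus at
different depths, and place normal and cancer cells at different focal
planes so a viewer can tell them apart at a glance.  `holowbc` implements
every computational stage of that system — the optical bench is replaced by
numerical reconstruction — so the method's quantitative claims can be
studied, tested and reused.

## What it computes

* **Synthetic blood films** (`holowbc.synthetic`) — microscope-like scenes
  of the five WBC kinds (basophil, eosinophil, lymphocyte, monocyte,
  neutrophil) plus the enlarged irregular cancer-lymphocyte phenotype, with
  exact ground-truth masks.  Stain palette: dark purple nucleus, pink
  cytoplasm, bright background.
* **Segmentation** (`holowbc.segmentation`) — green channel, histogram
  stretch, binarization at 70% of the bright-area intensity I_B, removal of
  components below 50 000 px, hole filling, Gaussian smoothing (window 15,
  re-threshold 50%), Sobel edge tracing with the fixed kernels
  `[-1 0 1; -2 0 2; -1 0 1]` and `[1 2 1; 0 0 0; -1 -2 -1]`.
* **Morphometry** (`holowbc.morphometry`) — moment-equivalent-ellipse axis
  lengths (μm), nucleus and cell areas (μm²), and normal-vs-cancer percent
  increases.
* **Phase-only CGH synthesis** (`holowbc.cgh`) — the iterative Fourier
  transform algorithm (IFTA, Gerchberg–Saxton family) between the SLM plane
  (amplitude 1) and the object plane (amplitude = √intensity), with the
  intensity error `mean((I_ref − I_NR)²)` and the RMS wrapped-phase change
  per iteration as convergence monitors, and 8-bit phase quantization
  (0–255 ↔ [0, 2π)).
* **Hologram modulation** (`holowbc.modulation`) — per-component phase
  ramps `R = exp(ik[sin α·ν_i + sin β·ν_j])` and defocus chirps
  `χ_z = exp(iπλz|f|²)`; the complex sum of the modulated components gives
  one hologram `φ_all = arg(Σ_m e^{iφ_m} R_m χ_m)` whose reconstruction
  focuses each component at its own distance z_m.
* **Speckle reduction** (`holowbc.speckle`) — zero-pad the target to 4× the
  SLM window (7680 × 4320), synthesize one extended hologram, split it into
  sixteen 1920 × 1080 sub-holograms, and average their sixteen reconstructed
  intensities (temporal multiplexing); speckle contrast C = σ/μ drops
  roughly like 1/√16.
* **Quality metrics** (`holowbc.metrics`) — intensity error, speckle
  contrast, scale-invariant SNR `‖I_ref‖²/‖I_ref − βI_or‖²` with
  `β² = ‖I_ref‖²/‖I_or‖²`, PSNR, Jaccard mask overlap.

The default optical constants match a bench with a 670 nm laser diode, a
1920 × 1080 phase-only SLM at 8 μm pitch and a 125 mm Fourier lens; all are
configurable (`holowbc.OpticalConfig`).

## Worked example

```python
import holowbc as h

records = {}
for label, cancer in [("normal", False), ("cancer", True)]:
    spec = h.CellSpec.for_kind("lymphocyte", center=(128, 128), cancer=cancer)
    scene = h.render_scene([spec], size=(256, 256), noise_sigma=0.01, seed=7)
    seg = h.segment_wbc(scene.image, h.SegmentationConfig().rescaled(0.1))
    nucleus = scene.nucleus_masks[0] & seg.cell_mask
    records[label] = h.measure_cell(seg.cell_mask, nucleus, scene.um_per_px)

print(h.percent_increase(records["cancer"].major_axis_um,
                         records["normal"].major_axis_um))
```

Output of the full example (also covering the speckle chain on a
segmented eosinophil, desk-scale 68 × 120 SLM window):

```
normal: major=6.91 um  minor=6.52 um  cell area=35.37 um^2
cancer: major=9.78 um  minor=8.66 um  cell area=66.51 um^2
major-axis increase: 41.50%
speckle contrast C: 0.811 -> 0.345 (16 tiles)
sigma: 0.4574 -> 0.2750
```

The segmented normal lymphocyte measures 6.91 × 6.52 μm with a 35.4 μm²
area — the scale of a real normal lymphocyte — and the rendered cancer
phenotype is ~42% larger along its major axis, the built-in effect size.
The pad/tile/average chain cuts the speckle contrast of the reconstruction
by more than half.

## Command line

```bash
holowbc synth --kind lymphocyte --cancer --seed 7 --out scene
holowbc segment --in scene.png --min-component 500 --out-prefix cell
holowbc cgh --target cell_mask.png --pad 4 --iters 60 --seed 1 --out holo.png
holowbc speckle --target cell_mask.png --seed 3 --report report.json
holowbc run --image scene.png --out-dir results/
```

`holowbc run` executes the whole chain (segment → morphometry → CGH →
tiling/multiplexing → metrics) and writes every artifact plus a JSON
manifest keyed by seed and config hash.

## Documentation

`docs/methods.md` describes the numerical model, the synthetic-data
generator, parameter defaults and known limitations.
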