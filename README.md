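# fiberdens

Automated quantification of immunostained fiber density in brightfield
micrographs, with built-in focus quality control and the planned
orthogonal-contrast statistics used in lesion/depletion studies — plus
synthetic-data generators with exact ground truth so the entire pipeline
can be validated without any microscope.

## The problem

Depletion experiments (e.g. saporin or 6-OHDA lesions of noradrenergic or
dopaminergic afferents to prefrontal cortex) are verified by quantifying
DAB-immunostained axons (DBH- or TH-positive) in small cortical ROIs.
Fibers are thin (~1 px at 0.227 µm/px), darkly stained, and sparse on a
bright background; manual counting does not scale and is not blind.
`fiberdens` implements an automated detector:

- gray = **B − 0.25·R − 0.25·G** (DAB brown absorbs blue, so stain is
  dark on this plane);
- median filter (disk, r = 3 px) for shot noise;
- high-pass: subtract a Gaussian blur (σ = 8 px) to isolate fiber-scale
  structure;
- exclusion of large dark stains (intensity + connected-component area
  ≥ 2000 px + 5 px margin);
- fixed threshold (gray level 11) → detected pixels;
- **fiber volume (%)** = 100 × detected pixels / ROI pixels.

A second pass with σ = 20 px admits lower spatial frequencies; the ratio
of the two detected fractions is a focus criterion (defocus destroys
fine-scale energy first), and ROIs below the cutoff (default 0.5) are
excluded as blurry.

Group comparisons (fiber volume by group × region, lever-press rates by
group × treatment × devaluation) use sets of between × within **planned
orthogonal contrasts** with the error rate controlled per contrast at
α = 0.05, each reported as F(1, N − cells), and simple-effects
decomposition of significant interactions against the pooled error term.

## Worked example

```python
from fiberdens import (FiberSceneParams, generate_fiber_scene,
                       quantify_roi)

scene = generate_fiber_scene(FiberSceneParams(target_density=0.03, seed=42))
m = quantify_roi(scene.image)
print(f"true density     {scene.realized_density:.4f}")
print(f"volume percent   {m.volume_percent:.4f}")
print(f"qc ratio         {m.qc_ratio:.3f}  pass={m.qc_pass}")
print(f"stain px excluded {m.n_stain_pixels_excluded}")
```

prints

```
true density     0.0300
volume percent   0.6662
qc ratio         0.998  pass=True
stain px excluded 5029
```

The detector reports ~0.67% detected area for a scene whose true fiber
density is 3% — thin fibers only partially survive the median filter, so
the readout is a *relative* volume index (it tracks true density with
rank correlation > 0.95), exactly how it is used for group comparisons.
The QC ratio near 1 says fine-scale structure is intact (in-focus); the
large-stain blob (~5000 px with its margin) was excluded from the count.

A devaluation analysis, with the effect present only in control cells:

```python
from fiberdens import (BehaviorSimParams, generate_behavior_table,
                       run_devaluation_analysis)

table = generate_behavior_table(BehaviorSimParams(
    n_per_cell=14, devaluation_effect=5.0,
    affected_cells=[{"treatment": "CTL"}], seed=7))
res = run_devaluation_analysis(
    table, {"group": ("Pre", "Post"), "treatment": ("CTL", "SAP")})
print(res["report"]["contrast_table"][["contrast", "F", "p"]])
```

reports, among the seven contrasts of the 2×2×2 design,
`treatment x devaluation: F(1, 52) = 28.50, p < 0.001`, and the triggered
simple effects localize the devaluation effect to the CTL level
(F(1, 52) = 49.64, p < 0.001) but not SAP (F(1, 52) = 0.25, p = 0.62) —
the signature of a treatment that abolishes goal-directed responding.

## Command line

```bash
fiberdens simulate-images  --n 8 --seed 1 --out scenes/
fiberdens quantify         --manifest scenes/manifest.csv --out measurements.csv
fiberdens simulate-behavior --seed 1 --out behavior.csv
fiberdens analyze          --table behavior.csv --design design.yaml --out report.json
fiberdens run-study        --manifest manifest.csv --design design.yaml --out results/
```

Manifest CSVs carry `path, subject, region, hemisphere, ap_mm,
pixel_size_um` plus one column per between-subject factor; YAML parameter
files mirror `QuantParams` / `FiberSceneParams` / `BehaviorSimParams`
field-for-field.

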