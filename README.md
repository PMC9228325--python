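# bovimetry

3D morphometrics of growing cattle: extract body surface area (BSA), volume
and the classic linear traits — heart girth (HG), withers height (WH), chest
depth (CD), hip width (HW), buttock width (KW) — from triangulated body
meshes; predict body weight (BW) from those traits; and analyse longitudinal
growth (interpolated weights, stage summaries, growth ratios, the
surface-to-volume decay).

The package targets the workflow of portal-type 3D body scanners for dairy
heifers: a point cloud of the standing animal is reconstructed into a
watertight mesh, the mesh is measured, each scan is scored 1–4 for
usability (leg "skirt" membranes and missing heads or legs are the common
defects), and BW is predicted from image traits. Because no public
animal-level scan data exist for growing heifers, a parametric
synthetic-heifer generator with closed-form ground truth stands in for the
scanner, calibrated to a published table of stage means from 2 to 20 months
of age.

## The models at the core

**Allometric BSA laws** (adult cows / growing heifers):

    BSA = 0.0839 · BW^0.67        BSA = 0.147 · BW^0.56

**Linear BW predictions** from image traits (adult-cow forms eq3–eq5 and
their heifer refits eq6–eq8), e.g.:

    BW = 827.5 · volume + 45.8            (adult, volume only)
    BW = 922.3 · volume − 34.4            (heifer refit, volume only, R² = 0.97)

**Refitting**: ordinary least squares with optional through-origin
constraint (uncentered R²) and backward elimination of non-significant
predictors at a familywise threshold (α divided by 2·m for m candidates).

**Growth**: BW follows a monomolecular (Brody) curve
`BW(t) = A − (A − BW₀)·e^(−kt)`; each trait follows an allometry
`trait = a·BW^b`; the surface-to-volume ratio is fitted as
`BSA/volume = a·BW^(−b)` (isometric growth gives b = 1/3).

## Worked example

```python
from bovimetry import shape_preset, build_heifer_mesh, sample_point_cloud
from bovimetry.morphometrics import measure_all
from bovimetry.reconstruction import reconstruct_surface
from bovimetry.weight_models import get_model, predict_bw

mesh, truth = build_heifer_mesh(shape_preset("month12"), resolution=128)
rec = measure_all(mesh, animal_id="demo", age=369)
print(f"volume {rec.volume:.3f} m3  bsa {rec.bsa:.2f} m2  "
      f"hg {100*rec.hg:.1f} cm  wh {100*rec.wh:.1f} cm  quality {rec.quality}")

cloud = sample_point_cloud(mesh, 100_000, noise_sd=0.002, seed=1)
recon = reconstruct_surface(cloud, "implicit", {"depth": 8})
print(f"reconstructed volume {recon.volume:.3f} m3")

print(f"BW(eq8) = {predict_bw(get_model('eq8'), rec):.1f} kg")
```

prints

```
volume 0.429 m3  bsa 4.63 m2  hg 188.1 cm  wh 133.6 cm  quality 4
reconstructed volume 0.429 m3
BW(eq8) = 361.4 kg
```

The 12-month preset is calibrated so its girth (188.1 cm), withers height
(133.6 cm) and volume (0.43 m³) match the published stage means of a pilot
herd of five Holstein heifers at one year of age; the volume-only heifer
equation then puts its weight near 360 kg, a few percent below the scale
weight of that herd — the direction and size of discrepancy this family of
image-based predictors shows in practice.

A shell interface wraps the same functions
(`bovimetry simulate | reconstruct | measure | qc | predict | fit |
summarize | sv-curve | run`); `bovimetry run` executes the whole synthetic
pipeline and writes meshes, trait tables, quality reports, predictions and
a hashed manifest into a run directory, fully reproducible from its seed.

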