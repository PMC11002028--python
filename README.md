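# fundusflow

Retinal displacement vector field analysis for longitudinal fundus
photographs.

After epiretinal membrane (ERM) peeling the macula slowly relaxes; the
retina visibly stretches over months. fundusflow measures that structural
change from ordinary color fundus photographs of one eye taken at
different visits: it aligns the images, registers their vessel patterns
non-rigidly, and reports a dense per-pixel displacement vector field on
the latest (reference) image, summarized over a 24-sector macular grid in
device-independent units. It is intended for ophthalmic imaging
researchers studying macular structural change (ERM surgery follow-up
being the motivating case) who have image series plus fovea/disc landmark
coordinates for the reference image.

## Method at a glance

For an earlier image *M* and the reference image *F* of the same eye:

1. right-eye images are mirrored so all eyes share one orientation;
2. *M* is globally aligned to *F* by SIFT feature matching + RANSAC
   similarity fit (rotation, isotropic scale, translation);
3. vessel probability maps of both images are computed with a multiscale
   Hessian (Frangi) vesselness filter (or loaded from an external
   segmenter);
4. a cubic b-spline free-form deformation **T** is optimized with
   L-BFGS-B to maximize the normalized cross-correlation of the vessel
   maps, coarse-to-fine, until the binarized maps overlap (Dice ≥ 0.8);
5. the field u(x) = −(T(x) − x) on the reference grid gives, per pixel,
   the motion of tissue from its earlier to its later position.

With fovea center **f** and disc center **d** on the reference image
(fovea–disc distance FDD = ‖d − f‖), every vector is reported as

* standardized magnitude = ‖u‖ · 1000 / FDD (a displacement of one FDD
  scores 1000), and
* direction in degrees with nasal (fovea→disc) = 0°, superior = 90°,
  temporal = 180°, inferior = 270°.

The macular disc of radius (2/3)·FDD around the fovea is divided into 3
rings × 8 wedges = 24 sectors; each sector's vectors are summed and
reported via the mean vector, with ring and quadrant aggregates. With all
timepoints registered to one reference, displacement between any two
earlier visits is obtained by per-sector vector subtraction.

No clinical images ship with the package; a synthetic-data module
generates vessel-tree fundus images deformed by known global + b-spline
warps with ground-truth fields, masks and landmarks, so the full pipeline
is testable end-to-end.

## Worked example

```python
import fundusflow as ff
from fundusflow.sectors import build_sector_grid, summarize_field

# a synthetic eye: reference image + earlier image deformed by a known
# 12 px contraction-release warp and camera jitter
case = ff.make_pair(seed=1)

result = ff.compute_pair_field(case.moving_image, case.fixed_image, case.landmarks)
grid = build_sector_grid(result.landmarks, result.field.shape)
summary = summarize_field(result.field, grid)

print(f"FDD: {result.fdd:.1f} px   final NCC: {result.nonrigid_report.final_ncc:.3f}   "
      f"vessel Dice: {result.nonrigid_report.final_dice:.3f}")
print(f"whole-macula mean standardized magnitude: {summary.mean_sector_std_magnitude():.1f}")
for ring in ("central_fovea", "inner_macula", "outer_macula"):
    agg = summary.ring_aggregate(ring)
    print(f"{ring:14s}  std magnitude {agg['std_magnitude']:5.1f}   "
          f"direction {agg['direction_deg']:6.1f} deg")
```

prints

```
FDD: 170.7 px   final NCC: 0.982   vessel Dice: 0.909
whole-macula mean standardized magnitude: 23.8
central_fovea   std magnitude  25.7   direction  109.0 deg
inner_macula    std magnitude  21.2   direction  115.2 deg
outer_macula    std magnitude  14.1   direction  127.9 deg
```

The registration converged (NCC 0.982, Dice 0.909 between the vessel
masks). The macula moved by about 2.4% of the fovea–disc distance on
average (mean standardized magnitude 23.8, i.e. ~4 px at this FDD),
strongest in the central fovea and fading outward — the expected pattern
for a contraction centered near the fovea. Directions around 110–130°
say the mean motion points superotemporally, toward this case's randomly
placed contraction center. `summary.to_frame()` gives the full 24-sector
table (one row per sector with pixel counts, standardized magnitudes,
directions and mean-vector components), and
`ff.sectors.group_quadrants(summary, "cardinal")` the 4-quadrant view.

## Command line

```sh
fundusflow simulate --seed 3 --out demo/                  # synthetic pair with ground truth
fundusflow register demo/moving.tif demo/fixed.tif \
    --landmarks demo/landmarks.json --out out/            # field + sector CSV + overlays
fundusflow series pre.tif m01.tif m04.tif m10.tif m22.tif \
    --landmarks landmarks.json --labels pre,m01,m04,m10,m22 --out out/
```

`register` writes the dense field (2-channel float TIFF), a JSON report
(global transform, NCC/Dice), the sector table (CSV), and two overlays: a
quiver plot of the field sampled every 25 px and one arrow per sector.
`series` registers every earlier image to the last one and emits
per-timepoint and between-timepoint sector tables plus one combined CSV.

## Documentation

See `docs/methods.md` for the full model description: conventions,
registration details and their rationale, what the synthetic generator
does and does not emulate, numerical choices, and known limitations.
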