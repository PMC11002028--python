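# Methods

fundusflow quantifies how retinal tissue moves between longitudinal color
fundus photographs of one eye — for example before and after epiretinal
membrane (ERM) peeling, where release of the membrane's traction lets the
macula relax over months. The output is a dense per-pixel displacement
vector field on the latest (reference) image, summarized over a
landmark-anchored 24-sector macular grid in device-independent units.

## Conventions

All coordinates are (row, col), 0-based, row increasing downward. Every
directional and metric convention is anchored to two landmarks on the
reference image only: the fovea center and the optic-disc center.

* **Fovea-disc distance (FDD)** — Euclidean pixel distance between the two
  landmarks; the anatomical yardstick.
* **Standardized magnitude** — `magnitude_px * 1000 / FDD`; a displacement
  equal to one FDD scores 1000, making magnitudes comparable across
  cameras, resolutions and patients.
* **Direction** — measured in the orthonormal frame (n, s) where n is the
  unit vector fovea → disc (nasal, 0°) and s is the perpendicular with
  non-positive row component (superior, 90°). Temporal is 180°, inferior
  270°. The zero vector is assigned 0° by convention (it carries zero
  weight in every summary).
* **Laterality** — right-eye (OD) images are mirrored about the vertical
  midline before any processing so that both eyes share the left-eye (OS)
  orientation; landmark columns map c → W−1−c and field column components
  are negated. A metadata flag forbids double flipping. Because the flip is
  an exact index permutation, an OD case and its mirrored OS twin produce
  bit-identical summaries.

An exactly vertical fovea-disc axis leaves "superior" undefined and is an
error; axes within 15° of vertical are anatomically implausible and warn
(configurable to an error).

## Pipeline

For a pair (moving = earlier image, fixed = reference):

1. **Working resolution.** Both images are resampled so the FDD equals a
   canonical 170 px (skipped when within 5%). This fixes the anatomical
   sampling density, so vesselness filter scales, control-grid spacings and
   similarity supports mean the same thing for every input resolution —
   outputs in standardized units become nearly independent of the camera.
   The final field is mapped back to the native reference grid
   (`u_native(x) = u_work(c·x)/c`).
2. **Global alignment.** SIFT keypoints on the green channel (highest
   vessel contrast), mutual-nearest-neighbour matching with a 0.8 ratio
   test, then RANSAC (inlier threshold 3 px, fixed seed 17) for a
   similarity transform — rotation, isotropic scale and translation; scale
   is included because magnification can change between visits (e.g. after
   cataract surgery). The consensus model is then refit by least squares on
   a broadened inlier set (matches within 5× the RANSAC threshold, iterated
   to convergence). The broad refit matters: before non-rigid registration
   the pair still differs by a smooth deformation, and a refit restricted
   to a tight consensus set describes one locally-rigid patch rather than
   the global viewing-geometry change; the broad fit averages the
   deformation out (bias < 1 px on synthetic truth versus ~5 px without
   it). Estimates with inlier fraction < 25% or scale outside [0.5, 2] are
   rejected. Collinear point sets are rejected explicitly. The global
   transform aligns *viewing geometry* and is deliberately excluded from
   the reported tissue-motion field.
3. **Vessel probability maps.** Multiscale Hessian (Frangi) vesselness of
   the green channel, dark-vessel polarity, maximum over sigmas
   {1.5, 2.5, 4} px at the working resolution, normalized to [0, 1] by
   robust 1st/99th-percentile clipping (stable against hot pixels). Sigmas
   grow proportionally for inputs whose FDD exceeds 1000 px but are never
   reduced below the base values — sub-pixel sigmas cannot resolve vessels
   and only amplify noise. Externally computed probability maps (e.g. CNN
   output) can be loaded instead; downstream code consumes only the map.
4. **Non-rigid registration.** A cubic b-spline free-form deformation,
   optimized coarse-to-fine with control spacings FDD/2, FDD/4, FDD/8.
   Similarity is Pearson normalized cross-correlation (NCC) between the
   fixed map and the moving map pulled back through the transform,
   restricted to the dilated (8 px) union of the binarized (0.5) vessel
   masks — full-frame NCC is dominated by empty background. Each level is
   solved with L-BFGS-B and an analytic gradient; coefficients are
   box-bounded at half the level's spacing, which both regularizes the
   field and guarantees a fold-free map (no explicit bending-energy term;
   Jacobian positivity is verified in tests). A level that would end worse
   than it started is discarded. "Clearly aligned" is operationalized as
   Dice ≥ 0.80 between the binarized maps; the finest level is repeated up
   to 3 outer rounds until that target is met. Levels combine additively;
   all-zero coefficients are the identity.
5. **Densification and sign.** The optimized transform is the resampling
   map T(x) = x + u_pb(x) from the reference grid into the moving image;
   the reported field is u = −u_pb, so each vector points from the tissue's
   earlier position toward its later (reference) position. Validity masks
   exclude pixels outside the globally warped moving footprint.

### Sector analysis

The macular region is the disc of radius R = (2/3)·FDD around the fovea;
rings at R/3 and 2R/3 (central fovea / inner / outer macula, half-open,
outer circle closed) and eight half-open 45° wedges counted from the nasal
axis (SNN, SSN, SST, STT, ITT, IIT, IIN, INN) give 24 sectors. Per sector
the representative vector is the pixel-wise sum; reported polar values use
the mean vector (sum ÷ count) so sectors of different areas are
comparable; the mean-of-per-pixel-magnitudes alternative is available via
`magnitude_mode="pixel_mean"`. Ring and quadrant aggregates (cardinal:
nasal/superior/temporal/inferior; diagonal: superonasal/superotemporal/
inferotemporal/inferonasal; 6 sectors each) are pixel-count-weighted means.
The whole-macula summary statistic is the mean over the 24 per-sector
standardized magnitudes — the magnitude of the macula-wide mean vector
would cancel for centripetal patterns and is not used.

With every timepoint registered to one reference, the displacement between
two earlier timepoints a and b is the per-sector vector difference
v(a→ref) − v(b→ref); this telescopes exactly.

## Synthetic data

No public fundus series with ground-truth deformation exists, so the
generator builds one: a seeded branching vessel tree grown from the disc,
trunks arcing around the macula, deeper branches and dedicated twigs
reaching inward to the foveal avascular zone (0.12·FDD); dark vessels with
Gaussian cross-profile (widths 1.6–4.2 px, tapering with depth) on a bright
background with radial illumination falloff, a brighter disc, a darker
macula, low-frequency texture, additive Gaussian noise (σ = 0.01) and a
circular field-of-view mask. The fovea and disc are placed exactly
`fdd_px` apart (default: image width / 3) with a random ±8° axis tilt.
Default vessel coverage is 4–13% of the field of view.

Pairs deform the reference by a random smooth b-spline field (spacing
64 px, max amplitude exactly `amplitude_px`, default 12) blended with a
centripetal component toward a contraction center inside the macula
(|offset| ≤ 0.2·FDD; membrane traction is a macular phenomenon), composed
with a similarity jitter (rotation ≤ 3°, scale 0.95–1.05, translation
≤ 15 px) and fresh noise. Two guarantees make recovery errors well
defined: the warp is fold-free (checked via the Jacobian determinant), and
its net similarity component is projected out exactly at the coefficient
level (cubic b-splines reproduce affine fields), weighted over the vessel
mask — otherwise the rigid stage would legitimately absorb part of the
"non-rigid" truth and endpoint error against truth would be ill-posed.
The exact dense correspondence is obtained by fixed-point inversion of the
resampling map. Longitudinal series share one contraction pattern with
non-increasing amplitudes (default 12/6/3/1.2 px over 5 timepoints),
emulating recovery that concentrates early after surgery.

What the generator does **not** emulate: pathology textures (membrane
reflexes, edema), local photometric changes between visits, vessel caliber
change, optic-disc torsion, and non-smooth displacement (e.g. at the
membrane edge). Passing tests therefore demonstrate correct recovery of
smooth deformation under realistic geometry and noise, not clinical-grade
accuracy on diseased eyes.

## Numerical choices

* NCC returns 0 for constant inputs; its gradient uses the sampled moving-
  image gradient at warped positions (standard first-order approximation).
* Bilinear interpolation throughout (map evaluation, warping, field
  transport); nearest-neighbour for masks.
* Convergence: L-BFGS-B ftol 1e-5 per level, ≤ 100 iterations.
* Determinism: the RANSAC seed (17) is fixed in config; SIFT, Frangi and
  the optimizer are deterministic; synthetic cases derive one RNG stream
  per (seed, case) so every artifact is bit-reproducible.
* Degenerate inputs are rejected with typed errors: coincident landmarks,
  vertical fovea-disc axis, featureless images, signal-free vessel maps,
  collinear correspondences, shape/frame mismatches.

## Problem sizes

The test-suite and reproduction runs use 384–512 px frames (FDD ≈ 110–170,
working resolution 170): one pair registers end-to-end in ~5–10 s and a
5-timepoint series in ~40 s on one CPU, with mean endpoint error on vessel
pixels of 0.3–1.0 px for warp amplitudes of 8–15 px.

## Known limitations

* The global/non-rigid split is a gauge choice: a net similarity component
  of true tissue motion (e.g. a uniform nasal shift) is partially absorbed
  by the rigid stage and under-reported in the field. This is inherent to
  the rigid-then-deformable design.
* Displacement is measured in the image plane only; axial motion and true
  metric (µm) calibration are out of scope.
* In vessel-free areas the field is b-spline interpolation between
  constraints, so fine local motion between vessels is smoothed.
* Sectors partially outside the camera field are summarized over their
  visible pixels and flagged; heavily clipped maculae warn.
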