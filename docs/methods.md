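# Methods

## Dose model and its assumptions

stereomu implements the isocentric TMR formalism for circular small fields.
All quantities are evaluated on the central axis at the isocenter, so the
off-axis ratio and the SSD-dependent inverse-square correction are fixed at
1; the model is one-dimensional and deliberately ignores scatter changes
near heterogeneities. The per-beam dose at the isocenter is

D = MU · DRref · OF_TMRmax(S) · TMR(d, S),

inverted for MU. Two MU values are always computed in a single pass sharing
the ray geometry: MU_NHC uses the geometric depth d (water-equivalent
patient), MU_WHC substitutes the effective depth deff in every TMR lookup.
The `heterogeneity` flag only selects which of the two is the headline
value of a run.

Consequences of the 1-D assumption: the model is reliable for target points
far from density interfaces (typical cranial SRS); it does not represent
dose inside or immediately beyond an inhomogeneity, and it cannot model
loss of lateral charged-particle equilibrium in lung-like media.

## Beam data

* **TMR tables** are resampled to a 1 mm grid by linear interpolation and
  normalized so TMR(dmax) = 1. Smoothing is off by default (an optional
  centred moving average of odd width is available at archive build);
  reproducibility is preferred over emulating an unspecified vendor filter.
  Below the first grid point the lookup clamps to the first value, with a
  warning — such depths indicate surface proximity the 1-D model cannot
  represent anyway. Beyond the last grid point the lookup extrapolates
  log-linearly from the last two nodes, since TMR decays near-exponentially
  at depth.
* **TMR ↔ PDD**: PDD(d, SSD, S) = 100 · TMR(d, S) · ((SSD + dmax)/(SSD + d))²,
  with the phantom-scatter ratio taken as unity for these very small
  circular fields (kept as an explicit named constant so the assumption can
  be revisited).
* **Equivalent square**: s = r·√π for a circular field of radius r (equal
  area). The nominal cone diameter stands in for the FWHM by default; a
  per-cone measured-FWHM override field exists in the archive.
* **Output correction factors** k(s) are fitted to a two-term exponential
  a·e^{b·s} + c·e^{d·s} by least squares from a fixed list of seven
  starting quadruples (lowest residual wins, ties by start index), because
  single-start fits of exponential sums are initialization-sensitive. Only
  curve *values* are meaningful — the two terms are exchangeable, so
  parameter identity is never asserted. Extrapolation below the smallest
  fitted s is supported (needed for the 4 mm cone, whose 3.54 mm equivalent
  square lies below tabulated correction-factor data).
* **Archive**: one JSON container per machine + energy (version field
  mandatory) holding TMR tables, OFs with their measurement geometry,
  DRref with calibration geometry, the HU→RED curve, and optionally the
  correction-factor fit. Serialization uses shortest-round-trip float
  repr, so save → load → save is byte-identical.

## Geometry

* **Coordinates**: DICOM patient LPS (mm) throughout; gantry/couch angles
  per IEC 61217 as stored in the plan. For head-first supine, gantry 0°
  places the source anterior, gantry 90° on the patient's left; the couch
  angle rotates the gantry plane about the patient's vertical axis. The
  source offset is SAD·(sin g·cos c, −cos g, −sin g·sin c).
* **Arc segmentation**: inclusive angle sequence from start to stop in the
  plan's rotation direction, default 1° steps, wrapping through 360°→0°;
  both endpoints included (n = span/res + 1). A static beam yields one
  angle. The resolution is exposed as a parameter because strongly
  irregular surfaces can benefit from finer steps.
* **Geometric depth** d: the source→isocenter ray is intersected with the
  external contour's polygon stack *exactly* (each planar contour extruded
  over one slice thickness; 2-D edge intersections per slice band, entry
  located by an even-odd walk). This resolves the skin entry point below
  voxel resolution and keeps d free of both HU noise and couch structures.
  A rasterized-mask fallback path (first in-mask voxel along the
  traversal) exists for callers that only have a mask.
* **Effective depth** deff: exact voxel-boundary (Siddon-type) traversal —
  all axis-plane crossings between the domain ends are merged, sorted, and
  each inter-crossing segment attributed to the voxel containing its
  midpoint — then deff = Σ RED(HUᵢ)·xᵢ. No step-size tuning is involved and
  lengths are exact. With couch attenuation on (default), accumulation
  starts at the proximal CT volume face, so air contributes ≈ 0 and couch
  structures contribute through their HU; with it off, accumulation starts
  at the exact body-surface entry point, which excludes everything upstream
  of the skin. The domain choice (rather than mask-filtering voxels) avoids
  corner-clipping artifacts where a traversed voxel's centre falls just
  outside the rasterized mask.
* **Surface ambiguity**: on any voxelized CT there remains ~half a voxel of
  ambiguity between the contour surface and the HU field at the skin; with
  2 mm voxels and a TMR slope of ~0.4%/mm this bounds the WHC-vs-NHC
  residual on a water phantom at ≈ 0.2%. The all-water identity
  (deff ≡ d) is exact when the HU field itself is water.

## DICOM handling

Reading uses pydicom for all four objects. CT slices are sorted by position
along the slice normal (file order is irrelevant), slice spacing must be
uniform within 0.01 mm, and rescale slope/intercept are required so values
are HU. The external structure is the ROI with interpreted type EXTERNAL,
else a case-insensitive name match against BODY/External/SKIN. Contours are
rasterized per slice with even-odd polygon tests on voxel centres when a
mask is needed.

The per-beam isocenter dose D is resolved in a fixed, logged order: the
plan's referenced BeamDose; else trilinear sampling of a per-beam (BEAM
summation) RT Dose grid at the isocenter; else a plan-total grid sample
apportioned by beam MU weights. The DICOM standard does not pin down which
element carries D, so the source used is recorded per beam.

## Synthetic fixtures

The fixture generator emulates both commissioning data and exported DICOM
studies, with no external inputs:

* The analytic TMR shape — (d/dmax)² below dmax, e^{−μ(d−dmax)} beyond — is
  chosen for exact invertibility, not radiological realism. Defaults:
  dmax 15 mm and μ = 0.004/mm (the ~0.4%/mm distal falloff of a 6 MV FFF
  beam); a 25 mm dmax variant models a 10 MV FFF-like beam. OFs increase
  monotonically with cone size and stay below 1; DRref = 0.01 Gy/MU; the
  HU→RED curve is (−1000, 0), (0, 1), (1000, 1.6), (3000, 2.5).
* Phantoms: a homogeneous water cylinder (r = 80 mm); a thorax-like
  elliptical cylinder (100 × 75 mm) with two low-density lung-like inserts
  (RED 0.45), a bone-like insert (RED 1.3) in the vertebra position, and a
  thin couch slab posterior to the body; an ellipsoidal head with a
  high-RED shell for tangential-vs-normal incidence experiments. Default
  voxel pitch is 2 mm (all fixtures build in seconds); 1 mm is available
  for tolerance-sensitive work.
* Boundary voxels receive partial-volume HU from 3×3 in-plane
  supersampling, emulating scanner partial-volume averaging and keeping the
  EPL free of binary-membership quantization noise. z-direction partial
  volume is not modelled (contours are per-slice anyway).
* Every study embeds a known answer: the per-beam isocenter dose is
  forward-computed from a chosen MU through the same water model the
  calculator inverts (exactly what a cone planning system without density
  correction would report), so MU_NHC recovery is a closed-loop check even
  on heterogeneous phantoms.
* DICOM UIDs are derived from an explicit seed and all timestamps are
  fixed, so regeneration with the same seed is byte-identical.

What passing these tests does *not* show about real data: fixture contours
are analytic ellipses (no segmentation noise), the TMR shape is synthetic,
there is no image noise beyond int16 rounding, and the comparator MU is the
package's own water model rather than an independent planning system.
Agreement statistics against a clinical TPS cannot be reproduced from desk
fixtures.

## Numerical choices and degenerate inputs

Tolerances: cone diameters are matched within 0.05 mm; slice spacing
uniformity within 0.01 mm; ray/edge intersections use a 1e-9 parameter
window so a ray through a shared contour vertex is never lost. Errors are
typed: invalid values (negative depth, zero diameter) raise `InputError`;
incomplete commissioning data raises `ConfigurationError` naming the
offending field; rays that miss the body, isocenters outside the external
contour, or CT scans that do not cover the skin entry raise
`GeometryError`; per-beam failures are re-raised with the beam id attached.

Action levels default to 2% for Diff_NHC (equivalence of two homogeneous
algorithms) and 5% for Diff_WHC (clinical tolerance); both are advisory
flags, configurable, and only `--strict` turns them into a non-zero exit —
a QA check should still produce its report.

## Problem sizes used in the validation suite

The packaged suite uses 2 mm fixtures throughout: the homogeneous closure
study (6 beams), the thorax signs study (3 beams), 100 random rays for the
traversal-vs-integration check (0.05 mm sampling oracle), 50 random beams
for the water-equivalence check, and a 181-segment arc for arc/static
consistency. These sizes were chosen so the whole suite runs in well under
a minute while every tolerance is exercised at its stated value.
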