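# Methods

This note documents the models, numerical choices and limitations behind
`guideval`. Units are millimetres and degrees throughout; all randomness
flows from explicit integer seeds via `numpy.random.SeedSequence`.

## Bone phantoms

Real validation studies of saw-guide placement use cadaveric bones imaged
at three resolutions (CT, MRI-derived synthetic CT, and micro-CT as
geometric ground truth). No such scans ship with this package; the
phantom generator replaces them with an analytic long-bone model whose
true surface is known exactly, so the micro-CT role is played by a
tessellation of the analytic surface rather than by another image.

**Geometry.** The bone is a superellipse tube (exponent 2.5) along z:
semi-axes `a(z) = R·f(z)`, `b(z) = a(z)·(1−e)` with eccentricity
`e ∈ [0,1)`. Two features were added deliberately because plain tubes are
unrealistic *and* pathological for registration:

- a lateral shaft bow (default 3 mm, sinusoidal along the shaft), and
- asymmetric end flare (the distal end flares by `end_flare_factor`,
  default 1.5–1.6; the proximal end by half that fraction), developing
  over the last 15 mm.

A straight, end-symmetric tube has an exact 180° rotational symmetry, so
rigid registration could lock onto the symmetric copy with near-zero
residual; no real bone has that symmetry. The medullary canal is a
concentric superellipse that tapers closed 10 mm before each end, so the
cortical compartment is a closed solid whose boundary (outer surface plus
canal wall) is watertight. Per-bone defaults: radius shaft R = 8.5 mm,
e = 0.25; ulna R = 7.0 mm, e = 0.08 (the distal ulna is nearly circular
and anchorless, which is why it shows the largest placement errors).

**Intensities.** Per-voxel Gaussian draws around class means (soft tissue
40 HU, cortical bone 1200 HU, marrow −50 HU, calcified tendon 700 HU; SDs
20/60/25/60 HU). The `sct_like` modality multiplies all SDs by 2.5 and
optionally adds (a) a low-frequency negative bias field within 12 mm of
the bone ends — a minimal stand-in for the inhomogeneous densities a
learned MRI→CT mapping produces near the edge of its training field of
view — and (b) a calcified-tendon blob adjacent to, and by construction
disjoint from, the cortex: the classic false-positive failure of such
mappings. Default voxel spacing is 0.6 mm isotropic (the reconstructed
MRI resolution scale); the CT volume uses the same grid so modality
differences come from the intensity model, not the raster.

## Segmentation and surface models

Bone is segmented with an HU window (default lower bound 226 HU, the
standard adult-bone preset; the upper bound is open) or with Otsu's
automatic threshold computed on a 256-bin histogram — implemented on the
histogram directly so the between-class variance, the tie-break (toward
the lower threshold) and the binning are explicit and testable.
`keep_largest` retains the largest 26-connected component, which is what
removes disconnected false-positive structures such as the tendon blob.

Surfaces are marching-cubes isosurfaces at level 0.5 in physical
coordinates, re-oriented so normals point out of the segmented material,
then smoothed with Taubin's two-pass filter: per iteration one shrink
step λ (the "smoothing factor", default 0.3) and one inflate step
μ = −1.02·λ, for a default of 2 iterations. Taubin was chosen over plain
Laplacian smoothing because it preserves enclosed volume to well under a
percent at these settings; `smoothing_iterations=0` returns the raw
marching-cubes mesh bit-for-bit. With the default phantom the segmented
CT-like model sits ~0.11 mm mean absolute distance from the true surface
— the sub-voxel regime a real CT/micro-CT comparison lands in.

## Signed surface distances

`signed_vertex_distances(query, reference)` maps every query vertex to
its nearest point on the reference surface. Candidate triangles come from
a k-d tree over triangle centroids (16 candidates) with exact
point-triangle distances (Eberly's region algorithm, vectorized); the
sign is taken from the angle-weighted pseudo-normal of the closest
primitive — face, edge, or vertex — which is exact for watertight,
outward-oriented meshes. Positive means the query vertex lies outside the
reference (query model locally larger). The reference must be watertight;
an inward-wound reference is flipped automatically. Summaries report the
arithmetic mean and the sample SD (n−1); both signed and absolute
variants exist because a signed mean measures bias (over-/under-
segmentation) while an absolute mean measures fidelity.

## Registration

The inner solve is the closed-form Kabsch/SVD least-squares rigid fit
with determinant correction (reflections excluded); collinear point sets
are rejected. ICP uses seeded uniform subsampling of source vertices
(default 600), closest-point-on-surface correspondences against the
target, and that closed-form update.

Three robustness choices matter and are deliberate:

- **Initialization** is centroid + principal-axes alignment. All four
  proper-rotation sign disambiguations are refined for 20 cheap
  iterations before committing; if the winner is not decisively better
  than the runner-up (RMS ratio > 0.6) the full loop is run from both and
  the better end state kept. On near-tubular shapes the raw initial RMS
  can prefer a candidate that converges into a pseudo-symmetric local
  minimum; the refinement separates the basins. Capture range is
  therefore limited to offsets the axes disambiguate plus roughly
  15°/10 mm; no global search is attempted.
- **Step extrapolation.** Plain ICP converges only linearly, and along a
  weakly constrained mode (azimuthal rotation of a near-circular ulna
  shaft) it can need thousands of iterations. When successive incremental
  updates point the same way (cosine > 0.9, shrinking magnitude), the
  geometric series they form is extrapolated in a single jump (capped at
  25×), accepted only if the measured RMS does not increase — so the
  monotone-descent property of ICP is preserved, which the tests assert
  on the iteration trace. This cuts clean-recovery runs from ~350 to ~40
  iterations and eliminates the flat-valley stalls.
- **Outlier trimming is off by default.** Percentile trimming exists for
  partial scans (it activates only when the residual tail is heavy,
  above 3.5× the median — the signature of correspondences falling off
  unmatched regions), but in the full-overlap regime this pipeline
  operates in, trimming discards exactly the flare-end correspondences
  that pin the weak modes and stalls convergence, so the default keeps
  every correspondence.

With zero scan noise a known rigid offset is recovered to ~2·10⁻⁵ mm /
3·10⁻⁵ deg; with the default 0.1 mm scanner jitter the converged RMS sits
at the jitter floor and pose error is ~0.03 mm / ~0.3° (the rotational
part concentrated in the weak azimuthal mode).

## Placement errors

The displacement between planned and placed reference box is expressed in
the planned box's local frame, so translations read directly as motion
along the anatomical axes (z proximal, y away from bone, x tangential)
and rotations act about the box centroid — the natural pivot, and without
a pinned pivot the translation components would depend on an arbitrary
lever arm. Rotations use the fixed-axes X-Y-Z Euler convention in
degrees. The convention is a genuine choice: at placement-error
magnitudes (≤ ~7°) all conventions agree with the convention-free
geodesic angle to better than ~0.9 % (worst case over axes at 5°, ~0.17 %
per degree), but a pinned convention makes outputs exactly reproducible;
the geodesic angle is carried along in every record as a supplement. ΔT
and ΔR are root-sum-squares of the components, computed before any
absolute-value step so that summaries of absolute per-axis errors keep
consistent totals. Near gimbal lock (|ϕy| → 90°) the decomposition raises
rather than returning ill-conditioned angles — that regime is three
orders of magnitude beyond real placement errors.

When the placed box is available only as a scanned mesh, its pose is
recovered by PCA with axes assigned by edge length and the sign/
permutation ambiguity resolved toward the planned pose (placement errors
are far smaller than the box's 90°/180° symmetries).

## Observer and scan models

Observer placement error is zero-mean per-axis Gaussian, translations in
the planned box's local frame and rotations about its centroid, sampled
independently per axis. Per-axis independence is an assumption — nothing
in a placement table constrains the correlations — and is stated as such.
Defaults (translation SD 1.0/0.5/2.6 mm, rotation SD 0.8/0.6/4.4° for
x/y/z) were calibrated once by half-normal inversion (σ = mean·√(π/2)) so
that simulated absolute-error summaries land in the range reported for
trained observers placing conforming guides on dissected bones, with the
along-bone components dominant: a half-cylinder guide on a tubular bone
constrains sliding and spinning along/about the bone axis least.

The optical scan model subdivides the mesh to the target vertex density,
jitters vertices isotropically (default SD 0.1 mm, the accuracy class of
a structured-light scanner), and applies an unknown rigid offset (default
5 mm / 5°) that registration must undo; the offset is retained on the
scan object purely as a test oracle. What this model does *not* emulate:
occlusion and partial coverage, surface-dependent reflectance dropouts,
printing tolerances beyond vertex noise, and any physical bone-guide
contact mechanics — the simulated observer error is imposed on the box
pose directly rather than arising from a contact model. Passing tests
therefore demonstrate the correctness of the measurement chain
(segment → register → decompose → statistics), not the clinical accuracy
of any particular guide design.

## Study design and statistics

The default study is 8 specimens × {radius, ulna} × {proximal, distal} ×
{CT, sCT} = 64 guides (32 per modality), each placed once by 6 observers
(384 placements; 768 ΔT/ΔR values), with observer 3 repeating a full
session for the intra-observer arm. Guide presentation order is a seeded
shuffle recorded in the manifest — numerically inert, but it preserves
the protocol's structure. Both modalities share one observer-error model
by default, making the study a *null* design: the correct outcome is
"no modality difference", and the analysis is judged on reproducing it.

- **Summary table**: mean and sample SD of absolute errors per component
  and modality, plus for ΔT/ΔR the per-guide maximum between-observer
  difference averaged over guides ("max diff" columns).
- **rANOVA**: modality as within-subject factor over guide-placements
  (subject = observer × guide), observer as between factor when present
  (pingouin mixed ANOVA). For a two-level within factor and one observer
  the modality F equals the paired-t statistic squared — asserted in the
  tests. Sphericity is trivially satisfied at two levels. Significance is
  flagged at p < 0.025. Type-I calibration over 1000 null simulations
  lands at 1.6–2.6 %.
- **Bland-Altman**: per-guide CT−sCT differences of |ΔT| and |ΔR|,
  averaged over observers first (32 points); standard LoA mean ± 1.96·SD.
  Intra-observer LoA: ±1.96·SD of the repeat-session differences of the
  repeating observer. Inter-observer LoA: ±1.96·SD of per-placement
  deviations from the per-guide observer mean (the SD reading; a
  max-deviation reading is available behind `inter_rule="max"`, the
  SD reading is the default because a maximum does not scale to a 95 %
  band). Both variability LoA are centred at zero, being variability
  bands rather than bias estimates. Equivalence requires ≥ 95 % of the
  differences within the inter-observer LoA.
- **Outliers**: per observer group, outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR]
  with type-7 (linear-interpolation) quantiles and a 1e-9 relative
  tolerance at the fences; groups under 4 values are refused.
- **Sample size**: `n = ceil(2·(z₁₋α/₂ + z_power)²·σ²/δ²)` per group —
  the normal approximation, which gives n = 16 for δ = σ, 80 % power,
  α = 0.05 two-sided; a t-quantile iteration (n = 17) is available via
  `use_t=True`.

## Problem sizes and determinism

Default phantom volumes are ~61 × 61 × 218 voxels at 0.6 mm; ground-truth
meshes ~8k vertices; study-grade ICP uses 400-point subsamples with a
1e-4 mm RMS tolerance (precision-grade default: 600 points, 1e-7 mm).
These sizes keep the full 448-registration study to a few minutes on one
core while leaving every acceptance margin an order of magnitude of
headroom. Two runs with the same config are byte-identical at the CSV
level; the manifest records the seed, the full config and its hash.

## Known limitations

- The sCT emulation is an intensity-level caricature (noise scale, end
  bias, one blob); it does not model a learned MRI→CT mapping, MR
  physics, or spatially correlated reconstruction error.
- ICP capture range is limited by the principal-axes initialization;
  grossly partial scans additionally need an initial transform supplied.
- The guide's half-cylinder geometry conforms radially to the design
  surface but does not model mechanical press-fit or anchor points, so
  modality differences in *physical* fit quality are outside the model:
  the modality effect enters only through segmentation-dependent planned
  poses and the (shared) observer error.
- Euler-based ΔR is convention-dependent by construction; the geodesic
  angle column is the convention-free alternative.
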