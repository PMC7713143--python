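# Methods

This note documents the models, conventions and design choices behind
`callusqct`, and what validation on synthetic phantoms does and does not
establish about real specimens.

## Coordinate and unit conventions

The bone long axis is the third image axis; cross-sections are the
planes perpendicular to it. Axial intervals are half-open `[start, end)`
in mm; a slice belongs to an interval if its centre does, which prevents
double-counting boundary slices between nested regions. All internal
lengths are mm (areas mm², pMOI mm⁴); volumes are reported in ccm
(cm³); densities are calibrated mineral densities in mgHA/ccm. Voxel
indices are 0-based.

## Phantom model

The phantom emulates a plated transverse osteotomy of a long-bone shaft:

- a hollow cortical cylinder (defaults: outer Ø 20 mm, inner Ø 12 mm,
  cortical density 1200 mgHA/ccm, marrow 100 mgHA/ccm — representative
  mid-shaft values for an adult sheep tibia) interrupted by a parallel
  gap (default 3 mm, the standardized osteotomy width);
- six screw positions, three per fragment (metal cylinders of density
  3000 mgHA/ccm behind an opt-in flag, since implants are explanted
  before scanning in the modelled protocol);
- periosteal callus compartments per side (*cis* = plate side, the
  positive first axis; *trans* = opposite), each with a target volume,
  a density inside the 250–1000 mgHA/ccm callus band, and an axial
  extent centred on the gap. Voxels are accreted shell-wise — in order
  of radial distance from the shaft axis, ties broken deterministically
  — until the voxelized volume is the closest achievable to the target;
  the truth records the *achieved* volume exactly (voxel count × voxel
  volume), so downstream recovery can be asserted to machine precision.

Noise is additive Gaussian in density units applied after labelling —
the simplest model consistent with a calibrated reconstruction. The
generator does **not** simulate the physics of acquisition: no partial
volume averaging at interfaces, no beam hardening or metal artefacts, no
spatially correlated noise, and endosteal/intramedullary callus is not
modelled (its real extent is only qualitatively known). Passing
recovery tests therefore demonstrates the correctness of the measurement
chain — thresholds, masks, ROI bookkeeping, unit conversions — not the
robustness of density thresholding to scanner physics.

Scan geometry defaults to the protocol voxel pitch of 0.0607 mm, but the
pitch is a free parameter; tests and the acceptance run use 0.2–0.4 mm
and shaft segments of 30–50 mm so that suites run in seconds, since the
per-voxel measurement chain being validated is scale-invariant.

Synthetic torsion curves are piecewise: a quadratic toe-in region (slope
rising linearly from zero), a linear region of the prescribed stiffness,
a post-yield region of reduced slope, and an instantaneous torque drop
at the failure angle (the stop criterion requires the drop to be at
least 3 Nm). Sampling follows the modelled protocol: angular rate
5 degree/min recorded at 20 Hz. All five metrics have closed forms; the
energy integrates the piecewise segments analytically.

Group datasets scale the template's compartment volumes by per-group
effect multipliers (defaults 1.0 / 1.4 / 1.93, the ratios of the
published whole-bone callus group means) and a per-sample lognormal
factor with coefficient of variation 0.25, matching the order of the
between-animal scatter of callus volume in this model (printed SD/mean
ratios ≈ 0.18–0.30); six samples per group by default.

## Segmentation

Denoising (Gaussian, default σ = 0.5 voxel, support 2 voxels) precedes
thresholding, but density statistics are computed on the **raw** volume
within the final masks — filtering only stabilizes the labels, so
reported densities carry no filter-dependent bias. Whether reference
implementations measure density on filtered or raw values is generally
unstated; raw is the conservative choice.

Threshold semantics: callus is the closed band [250, 1000] mgHA/ccm,
bone the open interval above 1000. Ties at 1000 go to callus (the
published bands ">1000" and "250–1000" leave the boundary ambiguous; a
closed callus band keeps the partition exhaustive). An optional metal
cut (default 2000 mgHA/ccm) splits screws out of the bone label.

Mask refinement is one opening then one closing per label with ball
structuring elements (default radius 1 voxel) followed by removal of
connected components below 27 voxels (a 3×3×3 speck) — the smallest
morphological series consistent with "a custom series of opening and
closing transformations" as scanner macro pipelines implement it; the
exact proprietary series is unpublished, so all radii and the component
threshold are configuration knobs, and bone takes precedence over callus
where refined labels overlap.

**Mature callus.** Callus that mineralizes past 1000 mgHA/ccm is
indistinguishable from cortex by thresholding alone. The package
operationalizes the slice-by-slice evaluation as follows: in slices at
least 5 mm away from the gap the *native envelope* is the convex
periosteal contour (convex hull) of the bone label; across the gap
region the envelope is interpolated linearly between the nearest
reliable slices via signed distance fields. Bone voxels outside the
envelope are relabelled callus; bone + callus volume is conserved
exactly and per-slice relabel counts are reported. The convex hull
overshoots a discrete circular boundary by up to one voxel, so a
one-voxel rind of supra-threshold callus directly on the periosteal
surface can survive reassignment — acceptable because mature callus
forms domes well outside the native contour.

## ROI geometry

The *whole bone* ROI is the plate's axial span; the *gap* ROI runs
between the innermost proximal and distal screws and must contain the
gap. Screw and plate geometry come from configuration or phantom truth,
never from image detection (screws are explanted before scanning in the
modelled protocol). The bone axis is the leading principal component of
the bone voxel cloud, oriented positive along the image axis; the
cis/trans cut plane passes through each slice's bone centroid (not a
single global plane) with the configured in-plane normal, which keeps
the partition meaningful for curved shafts. The split conserves voxels
exactly: cis + trans = input mask.

## Morphometry

Volume is voxel count × voxel volume. Density is the arithmetic mean of
raw voxel values in the mask; an empty compartment reports a *missing*
density, never 0 (0 mgHA/ccm is a valid density). The pMOI profile uses
per-slice centroids of the included labels (bone + callus by default; a
parameter, since published profiles do not state the label set — callus
visibly drives between-group pMOI differences, so including it is the
informative choice) and reports positions as % of scan length. The
implementation reduces the double sum to slice-wise moment accumulators;
a brute-force voxel loop serves as the oracle in tests.

## Torsion analysis

Curves are deduplicated to strictly increasing angle (repeated angles
averaged). Failure is the first sample where the running torque maximum
exceeds the current torque by ≥ 3 Nm (the machine's stop criterion);
metrics are computed up to the pre-drop peak. The *linear region* is
located by a sliding-window maximum least-squares slope, window = 20% of
the pre-ultimate angle range (min 5 samples) — a deterministic,
parameter-logged surrogate for the manually chosen linear region of a
test-bench evaluation. The *yield point* uses a linear-fit offset
criterion (default offset 0.5°): the stiffness-window fit is shifted
right and yield is the torque at the first crossing; a curve that never
deviates returns the ultimate torque with a flag. Both criteria are
declared surrogates: published torsion evaluations rarely state their
exact definitions, so synthetic truths — not published absolute values —
are the validation targets. For a bilinear curve with slopes b → b₂ the
offset criterion reads torque b₂·b·offset/(b−b₂) above the knee
(≈ 0.4% for the default synthetic spec), within the 1% recovery
tolerance. Energy integrates torque over angle by the trapezoidal rule
up to failure.

Normalization reports each variable as 100 × operated/contralateral (%)
and requires positive contralateral values.

## Statistics

The summary-statistics one-way ANOVA uses
MS_between = Σ nᵢ(x̄ᵢ−x̄)²/(k−1) and MS_within = Σ (nᵢ−1)sᵢ²/(N−k);
since these are exactly the raw-data sums of squares, the summary and
raw routes agree to machine precision on moment-matched data (a test
asserts this). Zero within-group variance with unequal means is flagged
and reported as p = 0 rather than raising. Tukey HSD uses the
studentized range distribution with the pooled MS_within; the design is
balanced (n = 6), with the Tukey–Kramer harmonic-mean fallback for
unbalanced input. Percent differences are 100·(test/reference − 1)
rounded half away from zero — integer precision for volume/density
comparisons, one decimal for torsion columns, matching printed table
conventions. A Wilcoxon signed-rank wrapper provides the non-parametric
paired branch; it requires raw data and is not applied by default
because which variables used it in the modelled study is unstated.

## Known limitations

- No acquisition physics in the phantom (see above); threshold-boundary
  behaviour under partial-volume effects is untested by construction.
- The native-envelope interpolation assumes the periosteal contour
  varies smoothly across the gap; comminuted geometries would violate
  this.
- The yield and linear-region criteria are surrogates; absolute yield
  values from different criteria can differ by a few percent.
- The cis/trans split is a half-space per slice; it does not follow the
  cortical surface, so endosteal callus (when enabled) is attributed by
  position relative to the centroid only.
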