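# Methods

## Segment frames from markers

Each segment frame is declared as a long-axis marker pair plus a
three-marker plane (see the tables in the README). Per frame:

1. the primary axis `e1` is the unit vector of the long axis, kept exact
   (it is the most reliably measured direction);
2. the plane normal `n` is the unit cross product of the plane triple in
   listed order, `(p2 − p1) × (p3 − p1)`;
3. `n` is Gram-Schmidt-orthogonalised against `e1` to give the secondary
   axis; the third axis completes a right-handed triad.

Anatomical assignment: the long axis maps to +X (anterior) for the foot
segments and +Y (superior) for the shank; the plane normal maps to +Y for a
transverse plane, +Z (lateral) for a sagittal plane and +X for a frontal
plane. The sign of each plane normal is fixed by a per-segment
`flip_normal` boolean stored in the model spec rather than by a runtime
comparison against a lab direction: a lab-frame reference would flip the
frame when a segment rotates past 90°, breaking rigid-motion equivariance.
The stored flags were validated once against the anatomical directions on
the nominal neutral geometry and are test-covered. Frames are right-foot
frames; left-foot trials are mirrored (lab Z negated) by the pipeline, never
silently.

All returned rotations satisfy `RᵀR = I` within 1e-9 with det +1. Plane
triples whose triangle area falls below 1e-6 × (longest side)² are rejected
as degenerate with the offending frame index. Marker gaps are not
interpolated here; upstream I/O must deliver complete series.

## Cardan angles

Joint rotation is `R_rel = Rᵀ_parent R_child`, decomposed with the
intrinsic z–x′–y″ sequence, the standard joint-coordinate-system reading in
which flexion is extracted first:

- θ_x = arcsin(R₃₂), range [−90°, 90°] (Ev/Inv)
- θ_z = atan2(−R₁₂, R₂₂), range (−180°, 180°] (Df/Pf)
- θ_y = atan2(−R₃₁, R₃₃), range (−180°, 180°] (Abd/Add)

An extrinsic z-x-y option is available for sensitivity checks
(`euler_zxy(..., convention="extrinsic")`, also selectable in `RunConfig`).

**Gimbal lock.** When |θ_x| reaches 90° (secondary-axis cosine below 1e-8)
only θ_z ∓ θ_y is observable. The decomposition then sets θ_y = 0, absorbs
the coupled rotation into θ_z = atan2(R₂₁, R₁₁) and flags the frame; it
never returns NaN. Recomposing the reported triple reproduces the input
matrix exactly at the singularity (test-covered).

## Filtering

Marker displacements are low-passed with a zero-phase (forward–backward)
Butterworth filter, default cutoff 6 Hz, order 4. "4th order" refers to
the single-pass filter, the conventional biomechanics reading; the double
pass gives an 8th-order magnitude response and cancels phase. Edges use
reflective padding of 3 × order samples; series must exceed that length.
Filtering is applied to marker trajectories *before* frame construction by
default (avoids filtering through angle wrap-around discontinuities); a
`filter_stage: markers | angles | off` switch selects filtering of the
angle series instead, since the alternative reading of the protocol text is
defensible.

## Baseline and peaks

Dynamic-trial angles are re-expressed relative to the mean angles of a
static standing trial (the whole trial by default; a window can be given —
the 15 s duration in the protocol is a recording choice, not a constraint).
One static trial per session is assumed. Peaks are exact order statistics:
the max and min of each component within the task window.

## The dummy-foot rig

The generator reproduces the validation experiment's conditions: three
rigid box segments — toe 3 × 8 × 5.5 cm, forefoot 5 × 8 × 9.5 cm, rearfoot
5 × 6.5 × 7.5 cm — each resting on a reference plate carrying markers o, x,
z. Plate frames: X = unit(x − o), Y = unit((z − o) × X) pointing up at
neutral, Z = X × Y (X kept exact, the o→z leg not trusted for
orthogonality). Sweeps move one end — plate A with the toe, or plate C with
the rearfoot — through −90°…90° in 5° steps (configurable within ±90°) in a
single anatomical plane; the plate-relative angle (A rel B for Met_Hal,
B rel C for Cal_Met) is the ground truth. When plate C is the mover the rig
imposes the negated rotation so the relative angle still equals the +grid;
an internal check asserts plate-derived truth equals the imposed grid to
1e-9°.

Landmark placement on the boxes was never published; the shipped YAML
fixture (`footkin/data/dummy_geometry.yaml`) places each landmark at a
plausible position on its box face, chosen so every nominal segment frame is
exactly lab-aligned at neutral. Landmarks shared between adjoining segments
are duplicated per segment, as on the physical rig, and sweep trajectories
namespace markers by rigid body (`toe/H1`). Because placement is assumed,
simulated correlations characterise this software pipeline, not the
physical experiment: the rig's published weak cells (e.g. hallux transverse
r ≈ 0.5) arose from physical placement and cannot — and should not — be
reproduced by the ideal fixture, which yields r ≈ 1 everywhere.

Noise model: per-frame isotropic Gaussian marker noise (σ in mm, seeded)
and, separately, rigid placement offsets (one Gaussian offset per marker,
constant over frames). Defaults are noiseless — the validity oracle; a
realistic preset is σ_noise = 0.2 mm, σ_placement = 1 mm. Ground truth never
depends on noise or seed. A continuous mode ramps the angle at a chosen
sampling rate for filter testing; the default sweep is quasi-static (one
frame per position, nominal 1 Hz), matching the stepwise protocol.

**Fixed-bias structure.** If the moving child segment's markers are offset
rigidly (constant misalignment `D` of its frame) while the fixed parent
frame stays aligned with the rotation axis, the relative rotation over a
sweep about the parent's z-axis is `R_rel(θ) = R_z(θ)·D`, whose first
Cardan angle is exactly θ + const. Measured − true is therefore a pure
constant — a fixed bias with zero difference-SD — on the sagittal
(first-axis) sweep; on the other planes the offset enters nonlinearly and
constancy is only approximate. The package demonstrates the exact case.

What the simulator does *not* emulate: soft-tissue/skin artifact, camera
occlusion or measured-true-value error, so passing tests show pipeline
correctness under rigid-body conditions, not in-vivo accuracy.

## Agreement statistics

- **Validity**: sample Pearson r with two-sided p from the t distribution
  (n − 2 df). n is always reported with r, since it is protocol-derived.
- **Bland–Altman**: differences d = measured − truth; bias = mean(d);
  limits of agreement = bias ± 1.96·SD(d) (classical fixed multiplier, not
  a t quantile). Fixed bias is declared when the 95% t-based CI of the mean
  difference excludes zero; proportional bias when the OLS slope of d on
  the pairwise means is significant at 5% (the outcome-level descriptions
  in the source literature name no test; these are the standard choices).
  With proportional bias the plot shows differences relative to the means.
  A difference spread below 1e-10° is treated as exact agreement so machine
  rounding cannot raise bias flags.
- **Peak comparisons**: unpaired two-sample t-test, pooled variance by
  default (Welch selectable), 5% significance. Zero-variance groups with
  equal means give t = 0, p = 1 by convention.
- No multiple-testing correction is applied anywhere, deliberately.

## Problem sizes and defaults

The validity study uses 37 grid positions per plane per joint (−90°…90°,
5° steps), 3 planes × 2 joints × 3 models; it runs in about a second.
Monte-Carlo checks in the test suite use n = 200 difference samples
(parameter recovery), 500 replicates of n = 37 (bias unbiasedness) and
1500-frame static trials — sizes at which the binomial/χ² tolerance bands in
the tests are meaningful. All randomness flows through explicit
`numpy.random.default_rng` seeds.

## Known limitations

- The Rizzoli model is a reconstruction from its published description via
  the marker alias table; its midfoot segment is omitted (the joints
  analysed are Met_Hal, Cal_Met, Sha_Cal) and its frames are configurable
  rather than authoritative.
- Right-foot convention throughout; left feet handled by explicit
  mirroring.
- No gap filling, time normalisation to gait cycle, event detection or
  kinetics.
- C3D reading requires the optional `ezc3d` dependency; TRC and CSV are the
  guaranteed text formats.
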