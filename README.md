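# footkin

Marker-based multi-segment foot kinematics for optical motion capture, with
a built-in rigid dummy-foot rig for validating the models against
plate-derived ground truth.

Single-segment foot models (e.g. plug-in-gait) hide all internal foot
motion. `footkin` implements a transverse-plane three-segment foot model
(hallux, forefoot, rearfoot, plus shank), a variant whose rearfoot frame is
defined in the sagittal plane, and a reconstruction of the Rizzoli foot
model for comparison. It is aimed at movement scientists processing
marker trajectories (TRC/CSV, optionally C3D) from gait, calf-raise or
drop-jump trials, and at anyone who wants to quantify how well a marker set
tracks imposed rigid rotations.

## Model

Each segment frame is built from a long-axis marker pair and a three-marker
plane (right-foot convention: X anterior, Y superior, Z lateral):

| Segment | Long axis | Plane |
|---|---|---|
| Hallux | H1 → P1 | H1, P1, H5 (transverse) |
| Forefoot | MC → H2 | MC, H1, H5 (transverse) |
| Rearfoot | C1 → MC | C1, NV, B5 (transverse) |
| Rearfoot_2 | C2 → MC | C2, MC, C1 (sagittal) |
| Shank | IM → TT | IM, LM, HF (frontal) |

MC and IM are computed midpoints (NV–B5 and MM–LM). Joint rotation is the
distal segment expressed in the proximal frame, `R_rel = Rᵀ_prox R_dist`,
decomposed with the intrinsic z–x′–y″ Cardan sequence

```
R_rel = R_z(θ_z) R_x(θ_x) R_y(θ_y)
```

giving dorsi-/plantar-flexion (θ_z), eversion/inversion (θ_x) and
abduction/adduction (θ_y) in degrees. Marker trajectories are low-passed
with a zero-lag 4th-order Butterworth filter (6 Hz default) and angles are
re-expressed relative to a static standing baseline.

Validity is assessed on a simulated rig: three rigid box segments on
reference plates (markers o, x, z per plate) swept −90°…90° in each
anatomical plane; the plate-relative angle is the true value. Agreement is
quantified by Pearson's r and Bland–Altman bias with 1.96·SD limits of
agreement, including fixed/proportional bias classification.

## Worked example

```python
from footkin import run_validation
table = run_validation(models=("new", "rizzoli"))
print(table[table.model == "new"].head(3).to_string(index=False))
```

```
model   joint      plane  n   r             p          bias      sd_diff     loa_lower    loa_upper bias_class  inside_loa
  new Met_Hal    frontal 37 1.0 2.867697e-270 -1.392280e-15 8.087737e-15 -1.724424e-14 1.445969e-14       none    0.972973
  new Met_Hal transverse 37 1.0 5.315672e-265 -2.952593e-15 1.212770e-14 -2.672288e-14 2.081770e-14       none    0.918919
  new Met_Hal   sagittal 37 1.0 2.867697e-270 -1.200241e-15 1.165816e-14 -2.405023e-14 2.164975e-14       none    0.945946
```

(The bias columns are numerical zero: the ideal noiseless geometry agrees
with the plate truth to machine precision.)

Each row is one (model, joint, plane) cell of the sweep study over 37 grid
positions: `r` is the correlation of the marker-derived joint angle with the
plate truth (ideal noiseless geometry gives r ≈ 1), `bias` and the limits of
agreement are in degrees, and `bias_class` reports the Bland–Altman
systematic-bias classification. The `examples/` directory holds short
narrative scripts: frame construction and joint angles, the sweep study,
fixed bias from deliberate marker-placement error, and the full
static + dynamic trial pipeline with peak extraction.

A thin CLI mirrors the library: `footkin simulate | angles | validate |
peaks | report` (see `footkin --help`).

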