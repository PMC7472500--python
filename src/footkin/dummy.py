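"""Synthetic dummy-foot rig: the package's ground-truth generator.

The rig emulates the physical validation experiment: three rigid box
segments (toe, forefoot, rearfoot) carrying the foot-model markers rest on
reference plates A, B and C, each plate defined by markers o, x, z.  One
end plate (A with the toe, or C with the rearfoot) is swept through known
rotations from -90 to +90 degrees in a single anatomical plane; the
plate-relative angles are the true values against which the marker-based
models are validated:

* plate A relative to plate B  <->  Met_Hal (hallux relative to forefoot)
* plate B relative to plate C  <->  Cal_Met (forefoot relative to rearfoot)

Ground truth is the imposed rotation grid; marker noise never touches it.
When plate C is the mover the rig imposes the negated rotation on the
plate so that the *relative* B-to-C angle still equals the +grid.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .core import TrajectorySet
from .kinematics import (
    COMPONENTS,
    PLANE_COMPONENT,
    JointAngleSeries,
    euler_zxy,
    relative_rotation,
    rotation_matrix,
)
from .models import (
    FootModelSpec,
    RIZZOLI_ALIASES,
    build_segment_pose,
    derive_virtual_markers,
    register_model,
)
from .core import PoseSeries

__all__ = [
    "PlateSpec",
    "DummyGeometry",
    "SweepProtocol",
    "GroundTruth",
    "SweepResult",
    "JOINT_PLATES",
    "PLANE_AXIS",
    "default_geometry",
    "perturb_placement",
    "plate_pose",
    "plate_angles",
    "simulate_sweep",
    "simulate_static",
    "measured_sweep_angles",
]

#: anatomical plane -> lab rotation axis of the sweep
PLANE_AXIS = {"frontal": "x", "transverse": "y", "sagittal": "z"}

#: joint measured by each sweep -> (child plate, parent plate)
JOINT_PLATES = {"Met_Hal": ("A", "B"), "Cal_Met": ("B", "C")}

#: moving plate -> joint whose truth the sweep defines
PLATE_JOINT = {"A": "Met_Hal", "C": "Cal_Met"}

#: model segment name -> rig box carrying its markers
SEGMENT_BOX = {
    "Hallux": "toe",
    "Forefoot": "forefoot",
    "Rearfoot": "rearfoot",
    "Rearfoot_2": "rearfoot",
    "Metatarsus": "forefoot",
    "Calcaneus": "rearfoot",
    "Shank": "shank",
}


@dataclass(frozen=True)
class PlateSpec:
    """Reference plate with markers o, x, z (mm, plate at neutral)."""

    plate_id: str
    o: np.ndarray
    x: np.ndarray
    z: np.ndarray

    def points(self) -> dict[str, np.ndarray]:
        return {"o": self.o, "x": self.x, "z": self.z}


@dataclass(frozen=True)
class DummyGeometry:
    """Nominal rig geometry: boxes, per-segment landmark coordinates, plates."""

    boxes: dict[str, dict[str, float]]
    segment_markers: dict[str, dict[str, np.ndarray]]
    plates: dict[str, PlateSpec]
    plate_segment: dict[str, str]
    canonical_attachment: dict[str, str]

    def canonical_positions(self) -> dict[str, np.ndarray]:
        """One position per landmark, via the canonical segment attachment."""
        return {
            name: self.segment_markers[seg][name]
            for name, seg in self.canonical_attachment.items()
        }


def default_geometry() -> DummyGeometry:
    """Load the shipped nominal rig geometry fixture."""
    text = (
        importlib.resources.files("footkin") / "data" / "dummy_geometry.yaml"
    ).read_text()
    return geometry_from_yaml(text)


def geometry_from_yaml(text: str) -> DummyGeometry:
    doc = yaml.safe_load(text)
    plates = {
        pid: PlateSpec(
            pid,
            np.asarray(spec["o"], dtype=float),
            np.asarray(spec["x"], dtype=float),
            np.asarray(spec["z"], dtype=float),
        )
        for pid, spec in doc["plates"].items()
    }
    markers = {
        seg: {name: np.asarray(p, dtype=float) for name, p in mk.items()}
        for seg, mk in doc["segment_markers"].items()
    }
    return DummyGeometry(
        boxes=doc["boxes"],
        segment_markers=markers,
        plates=plates,
        plate_segment=dict(doc["plate_segment"]),
        canonical_attachment=dict(doc["canonical_attachment"]),
    )


def perturb_placement(
    geom: DummyGeometry,
    sigma_mm: float,
    seed: int | None = None,
    segments: tuple[str, ...] | None = None,
) -> DummyGeometry:
    """Rigidly offset marker placement (one Gaussian offset per marker).

    The offsets are constant across frames -- the markers are still glued to
    rigid bodies, just not where the nominal fixture says.  Plate markers
    are never perturbed: the true values stay exact.
    """
    rng = np.random.default_rng(seed)
    new_markers = {}
    for seg, mk in geom.segment_markers.items():
        if segments is not None and seg not in segments:
            new_markers[seg] = {n: p.copy() for n, p in mk.items()}
        else:
            new_markers[seg] = {
                n: p + rng.normal(0.0, sigma_mm, 3) for n, p in mk.items()
            }
    return replace(geom, segment_markers=new_markers)


@dataclass
class SweepProtocol:
    """One single-plane sweep of a moving end plate.

    ``grid`` is the sequence of true relative plate angles in degrees
    (default -90..90 in 5-degree steps, within [-90, 90]).  ``noise_sigma``
    is per-frame Gaussian marker noise in mm; ``placement_sigma`` rigidly
    offsets segment-marker placement once (both seeded).  By default the
    sweep is quasi-static: one frame per grid position.  With
    ``continuous=True`` the angle ramps linearly from ``grid[0]`` to
    ``grid[-1]`` at ``rate_hz`` over ``duration_s`` (for filter testing).
    """

    moving_plate: str = "A"
    plane: str = "sagittal"
    grid: np.ndarray = field(default_factory=lambda: np.arange(-90.0, 95.0, 5.0))
    noise_sigma: float = 0.0
    placement_sigma: float = 0.0
    seed: int | None = None
    continuous: bool = False
    rate_hz: float = 100.0
    duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.moving_plate not in ("A", "C"):
            raise ValueError("moving_plate must be 'A' (toe end) or 'C' (rearfoot end)")
        if self.plane not in PLANE_AXIS:
            raise ValueError(f"plane must be one of {tuple(PLANE_AXIS)}, got {self.plane!r}")
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.size == 0:
            raise ValueError("empty sweep grid")
        if self.grid.min() < -90.0 or self.grid.max() > 90.0:
            raise ValueError("sweep grid must lie within [-90, 90] degrees")

    @property
    def joint(self) -> str:
        return PLATE_JOINT[self.moving_plate]

    def angle_sequence(self) -> np.ndarray:
        if not self.continuous:
            return self.grid
        n = max(2, int(round(self.duration_s * self.rate_hz)))
        return np.linspace(self.grid[0], self.grid[-1], n)


@dataclass
class GroundTruth:
    """True plate-relative angles per frame; independent of marker noise."""

    joint: str
    plane: str
    grid: np.ndarray  # (n,) swept true angle, degrees
    angles: np.ndarray  # (n, 3) triple in COMPONENTS order (off-plane = 0)


@dataclass
class SweepResult:
    trajectory: TrajectorySet  # namespaced markers: "toe/H1", "plateA/o", ...
    truth: GroundTruth
    protocol: SweepProtocol
    geometry: DummyGeometry


def plate_pose(o: np.ndarray, x: np.ndarray, z: np.ndarray) -> PoseSeries:
    """Plate frame from its three markers: X = o->x, Y = (o->z) x X, Z = X x Y.

    X is kept exact; Z is recomputed from the orthogonal pair rather than
    trusting o->z, and Y points up (+lab Y at the neutral position).
    """
    o = np.atleast_2d(np.asarray(o, dtype=float))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    z = np.atleast_2d(np.asarray(z, dtype=float))
    ox, oz = x - o, z - o
    nx = np.linalg.norm(ox, axis=-1, keepdims=True)
    if np.any(nx < 1e-12):
        raise ValueError("plate markers o and x coincide")
    ex = ox / nx
    ycand = np.cross(oz, ex)
    ny = np.linalg.norm(ycand, axis=-1, keepdims=True)
    if np.any(ny < 1e-9 * nx):
        raise ValueError("plate markers o, x, z are collinear")
    ey = ycand / ny
    ez = np.cross(ex, ey)
    R = np.stack([ex, ey, ez], axis=-1)
    return PoseSeries("plate", R, o, rate=0.0)


def plate_angles(traj: TrajectorySet, child_plate: str, parent_plate: str) -> np.ndarray:
    """Cardan angles (degrees) of one plate relative to another, per frame."""
    def pose(pid: str) -> PoseSeries:
        return plate_pose(
            traj[f"plate{pid}/o"], traj[f"plate{pid}/x"], traj[f"plate{pid}/z"]
        )

    rel = relative_rotation(pose(child_plate), pose(parent_plate))
    ang, _ = euler_zxy(rel)
    return ang


def _rotate_about(points: np.ndarray, R: np.ndarray, pivot: np.ndarray) -> np.ndarray:
    """Apply per-frame rotations ``R (n,3,3)`` about ``pivot`` to one point."""
    return pivot + np.einsum("nij,j->ni", R, points - pivot)


def simulate_sweep(geom: DummyGeometry, protocol: SweepProtocol) -> SweepResult:
    """Simulate one single-plane sweep and return markers plus ground truth.

    The moving segment and its plate rotate rigidly about the plate origin;
    all other markers stay put.  The returned trajectory namespaces marker
    names by rigid body (``"toe/H1"``, ``"plateA/o"``) because shared
    landmarks exist in duplicate on adjoining segments.  An internal check
    asserts that plate-derived relative angles reproduce the imposed grid to
    1e-9 degrees before any noise is applied.
    """
    rng = np.random.default_rng(protocol.seed)
    if protocol.placement_sigma > 0:
        geom = perturb_placement(geom, protocol.placement_sigma, seed=rng.integers(2**31))

    thetas = protocol.angle_sequence()
    n = thetas.shape[0]
    axis = PLANE_AXIS[protocol.plane]
    # plate C is the parent of its pair: impose the negated rotation so that
    # the child-relative-to-parent plate angle equals +grid
    sign = 1.0 if protocol.moving_plate == "A" else -1.0
    R = rotation_matrix(axis, sign * thetas)  # (n, 3, 3)

    moving_seg = geom.plate_segment[protocol.moving_plate]
    pivot = geom.plates[protocol.moving_plate].o

    clean: dict[str, np.ndarray] = {}
    for seg, mk in geom.segment_markers.items():
        for name, p in mk.items():
            if seg == moving_seg:
                clean[f"{seg}/{name}"] = _rotate_about(p, R, pivot)
            else:
                clean[f"{seg}/{name}"] = np.tile(p, (n, 1))
    for pid, plate in geom.plates.items():
        for name, p in plate.points().items():
            if pid == protocol.moving_plate:
                clean[f"plate{pid}/{name}"] = _rotate_about(p, R, pivot)
            else:
                clean[f"plate{pid}/{name}"] = np.tile(p, (n, 1))

    rate = protocol.rate_hz if protocol.continuous else 1.0
    clean_traj = TrajectorySet(clean, rate)

    # truth: imposed grid on the swept component, zero elsewhere
    comp = COMPONENTS.index(PLANE_COMPONENT[protocol.plane])
    truth_angles = np.zeros((n, 3))
    truth_angles[:, comp] = thetas
    truth = GroundTruth(protocol.joint, protocol.plane, thetas.copy(), truth_angles)

    # consistency: noiseless plate-derived angles == imposed angles
    child_p, parent_p = JOINT_PLATES[protocol.joint]
    derived = plate_angles(clean_traj, child_p, parent_p)
    dev = np.abs(derived - truth_angles).max()
    if dev > 1e-9:
        raise AssertionError(
            f"plate-derived truth deviates from imposed grid by {dev:.3e} deg"
        )

    markers = clean.copy() if protocol.noise_sigma > 0 else clean
    if protocol.noise_sigma > 0:
        markers = {
            name: arr + rng.normal(0.0, protocol.noise_sigma, arr.shape)
            for name, arr in clean.items()
        }
    return SweepResult(TrajectorySet(markers, rate), truth, protocol, geom)


def simulate_static(
    geom: DummyGeometry,
    duration_s: float = 15.0,
    rate_hz: float = 100.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> TrajectorySet:
    """Stationary rig trial with one marker per landmark (plain names).

    Emulates the static standing trial: ``duration_s`` seconds at
    ``rate_hz``, optional seeded Gaussian marker noise.  Identical seeds
    give bit-identical output.
    """
    if duration_s <= 0 or rate_hz <= 0:
        raise ValueError("duration_s and rate_hz must be positive")
    n = max(1, int(round(duration_s * rate_hz)))
    rng = np.random.default_rng(seed)
    markers = {}
    for name, p in geom.canonical_positions().items():
        arr = np.tile(p, (n, 1))
        if noise_sigma > 0:
            arr = arr + rng.normal(0.0, noise_sigma, arr.shape)
        markers[name] = arr
    return TrajectorySet(markers, rate_hz)


def segment_view(
    traj: TrajectorySet, box: str, model_id: str | None = None
) -> TrajectorySet:
    """Strip one rigid body's namespace from a sweep trajectory.

    Returns the markers carried by ``box`` under their plain landmark names
    (translated to Rizzoli aliases when ``model_id == "rizzoli"``).
    """
    prefix = f"{box}/"
    picked = {
        name[len(prefix):]: arr for name, arr in traj.markers.items()
        if name.startswith(prefix)
    }
    if not picked:
        raise KeyError(f"no markers for rigid body {box!r} in trajectory")
    view = TrajectorySet(picked, traj.rate)
    if model_id == "rizzoli":
        view = view.renamed(RIZZOLI_ALIASES, keep_unmapped=False)
    return view


def measured_sweep_angles(
    sweep: SweepResult,
    model_id: str,
    joint: str | None = None,
    subtract_neutral: bool = True,
) -> JointAngleSeries:
    """Run the marker-based pipeline on a sweep and return the joint angles.

    Each segment frame is built from the marker copies glued to its own
    rigid box (duplicated shared landmarks resolve to the correct body, as
    on the physical rig).  With ``subtract_neutral`` the angles at the 0-deg
    grid position are subtracted -- the rig analogue of static-baseline
    subtraction.
    """
    spec: FootModelSpec = register_model(model_id)
    joint = joint if joint is not None else sweep.truth.joint
    child_seg, parent_seg = spec.joint(joint)

    def seg_pose(seg_name: str) -> PoseSeries:
        view = segment_view(sweep.trajectory, SEGMENT_BOX[seg_name], model_id)
        view = derive_virtual_markers(view, spec, missing="skip")
        return build_segment_pose(view, spec.segment(seg_name))

    rel = relative_rotation(seg_pose(child_seg), seg_pose(parent_seg))
    ang, gim = euler_zxy(rel)
    series = JointAngleSeries(joint, ang, sweep.trajectory.rate, gimbal=gim)
    if subtract_neutral:
        at_zero = np.flatnonzero(np.isclose(sweep.truth.grid, 0.0))
        if at_zero.size:
            series.angles = series.angles - series.angles[at_zero[0]]
            series.baseline_subtracted = True
    return series
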