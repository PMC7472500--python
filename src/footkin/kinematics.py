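"""Inter-segment rotation and Z-X-Y Cardan angle kinematics.

Joint rotations are expressed as the distal (child) segment relative to the
proximal (parent) segment, ``R_rel = R_parent^T R_child``, and decomposed
with the intrinsic z-x'-y'' Cardan sequence:

    R_rel = Rz(theta_z) Rx(theta_x) Ry(theta_y)

theta_z is dorsi-/plantar-flexion (Df/Pf), theta_x eversion/inversion
(Ev/Inv), theta_y abduction/adduction (Abd/Add).  Angles are degrees at the
API surface.  At the |theta_x| = 90 deg singularity (gimbal lock) theta_y is
set to zero, the coupled rotation is absorbed into theta_z and the frame is
flagged, never silently NaN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy import signal

from .core import PoseSeries, TrajectorySet
from .models import FootModelSpec, build_segment_pose, derive_virtual_markers

__all__ = [
    "COMPONENTS",
    "PLANE_COMPONENT",
    "JointAngleSeries",
    "StaticBaseline",
    "PeakSummary",
    "rotation_matrix",
    "compose_zxy",
    "relative_rotation",
    "euler_zxy",
    "joint_angles",
    "filter_trajectories",
    "filter_angles",
    "compute_baseline",
    "subtract_baseline",
    "extract_peaks",
]

#: Component order of every angle triple: rotation about Z, X, Y.
COMPONENTS = ("DfPf", "EvInv", "AbdAdd")

#: Anatomical plane -> component measured in that plane.
PLANE_COMPONENT = {"sagittal": "DfPf", "frontal": "EvInv", "transverse": "AbdAdd"}


@dataclass
class JointAngleSeries:
    """Per-frame (DfPf, EvInv, AbdAdd) angles for one joint, in degrees."""

    joint: str
    angles: np.ndarray  # (n, 3) degrees, columns in COMPONENTS order
    rate: float
    gimbal: np.ndarray | None = None  # (n,) bool mask of flagged frames
    baseline_subtracted: bool = False

    def __post_init__(self) -> None:
        self.angles = np.atleast_2d(np.asarray(self.angles, dtype=float))
        if self.angles.shape[1] != 3:
            raise ValueError("angles must be (n, 3)")
        if self.gimbal is None:
            self.gimbal = np.zeros(self.angles.shape[0], dtype=bool)
        else:
            self.gimbal = np.asarray(self.gimbal, dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.angles.shape[0]

    def component(self, name: str) -> np.ndarray:
        return self.angles[:, COMPONENTS.index(name)]


#: Static baseline: joint name -> mean (DfPf, EvInv, AbdAdd) triple, degrees.
StaticBaseline = dict[str, np.ndarray]


@dataclass
class PeakSummary:
    """Max/min of each rotation component of one joint within a task window."""

    joint: str
    task: str
    maxima: np.ndarray  # (3,) degrees, COMPONENTS order
    minima: np.ndarray
    window: tuple[int, int]  # [start, stop) frame range


# --- elementary rotations ----------------------------------------------------

def rotation_matrix(axis: str, angle_deg: float | np.ndarray) -> np.ndarray:
    """Rotation matrix (or stack) about a lab axis ``"x" | "y" | "z"``."""
    a = np.deg2rad(np.asarray(angle_deg, dtype=float))
    c, s = np.cos(a), np.sin(a)
    zero, one = np.zeros_like(c), np.ones_like(c)
    if axis == "x":
        rows = [[one, zero, zero], [zero, c, -s], [zero, s, c]]
    elif axis == "y":
        rows = [[c, zero, s], [zero, one, zero], [-s, zero, c]]
    elif axis == "z":
        rows = [[c, -s, zero], [s, c, zero], [zero, zero, one]]
    else:
        raise ValueError(f"axis must be x, y or z, got {axis!r}")
    return np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)


def compose_zxy(dfpf: np.ndarray, evinv: np.ndarray, abdadd: np.ndarray) -> np.ndarray:
    """Compose ``Rz(dfpf) @ Rx(evinv) @ Ry(abdadd)`` (degrees in, matrices out)."""
    return (
        rotation_matrix("z", dfpf)
        @ rotation_matrix("x", evinv)
        @ rotation_matrix("y", abdadd)
    )


def relative_rotation(child: PoseSeries, parent: PoseSeries) -> np.ndarray:
    """Per-frame rotation of the child segment expressed in the parent frame."""
    if child.n_frames != parent.n_frames:
        raise ValueError(
            f"frame count mismatch: child {child.n_frames} vs parent {parent.n_frames}"
        )
    return np.einsum("nji,njk->nik", parent.rotations, child.rotations)


def euler_zxy(
    R: np.ndarray,
    convention: str = "intrinsic",
    ortho_tol: float = 1e-6,
    gimbal_tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose rotation matrices into Z-X-Y Cardan angles (degrees).

    Parameters
    ----------
    R
        ``(..., 3, 3)`` proper rotation matrices.
    convention
        ``"intrinsic"`` (default): ``R = Rz(a) Rx(b) Ry(c)`` about moving
        axes.  ``"extrinsic"``: rotations about fixed lab axes in z, x, y
        order, i.e. ``R = Ry(c) Rx(b) Rz(a)``.
    Returns
    -------
    angles, gimbal
        ``angles`` has shape ``(..., 3)`` in (theta_z, theta_x, theta_y)
        order; ``gimbal`` is a boolean mask of frames at the
        |theta_x| = 90 deg singularity, where theta_y is forced to 0.
    """
    R = np.asarray(R, dtype=float)
    if R.shape[-2:] != (3, 3):
        raise ValueError(f"expected (..., 3, 3) matrices, got {R.shape}")
    err = np.abs(np.swapaxes(R, -1, -2) @ R - np.eye(3)).max()
    if err > ortho_tol:
        raise ValueError(f"input not orthonormal within {ortho_tol:g} (err={err:.2e})")

    if convention == "intrinsic":
        sx = np.clip(R[..., 2, 1], -1.0, 1.0)
        cx = np.hypot(R[..., 2, 0], R[..., 2, 2])
        tz = np.arctan2(-R[..., 0, 1], R[..., 1, 1])
        ty = np.arctan2(-R[..., 2, 0], R[..., 2, 2])
        tz_g = np.arctan2(R[..., 1, 0], R[..., 0, 0])
    elif convention == "extrinsic":
        sx = np.clip(-R[..., 1, 2], -1.0, 1.0)
        cx = np.hypot(R[..., 1, 0], R[..., 1, 1])
        tz = np.arctan2(R[..., 1, 0], R[..., 1, 1])
        ty = np.arctan2(R[..., 0, 2], R[..., 2, 2])
        tz_g = np.arctan2(-R[..., 0, 1], R[..., 0, 0])
    else:
        raise ValueError(f"convention must be 'intrinsic' or 'extrinsic', got {convention!r}")

    tx = np.arcsin(sx)
    gimbal = cx < gimbal_tol
    tz = np.where(gimbal, tz_g, tz)
    ty = np.where(gimbal, 0.0, ty)
    angles = np.degrees(np.stack([tz, tx, ty], axis=-1))
    return angles, gimbal


def joint_angles(
    traj: TrajectorySet,
    spec: FootModelSpec,
    joints: tuple[str, ...] | None = None,
    convention: str = "intrinsic",
) -> dict[str, JointAngleSeries]:
    """Compute every requested joint's Cardan angle series from raw markers.

    Virtual midpoint markers are derived first; each joint needs only its
    own two segments' markers, so trials missing e.g. the shank markers can
    still yield the foot joints by passing ``joints`` explicitly.
    """
    traj = derive_virtual_markers(traj, spec, missing="skip")
    wanted = joints if joints is not None else spec.joint_names
    out: dict[str, JointAngleSeries] = {}
    poses: dict[str, PoseSeries] = {}

    def pose(seg_name: str) -> PoseSeries:
        if seg_name not in poses:
            poses[seg_name] = build_segment_pose(traj, spec.segment(seg_name))
        return poses[seg_name]

    for joint in wanted:
        child, parent = spec.joint(joint)
        rel = relative_rotation(pose(child), pose(parent))
        ang, gim = euler_zxy(rel, convention=convention)
        out[joint] = JointAngleSeries(joint, ang, traj.rate, gimbal=gim)
    return out


# --- zero-lag Butterworth filtering ------------------------------------------

def _butter_ba(cutoff_hz: float, order: int, rate: float):
    nyq = rate / 2.0
    if cutoff_hz <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff_hz}")
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyq} Hz)")
    if order < 1:
        raise ValueError(f"filter order must be >= 1, got {order}")
    return signal.butter(order, cutoff_hz / nyq, btype="low")


def _filtfilt(x: np.ndarray, b, a, order: int) -> np.ndarray:
    # forward-backward pass with reflective padding of 3 x order samples
    padlen = 3 * order
    if x.shape[0] <= padlen:
        raise ValueError(
            f"series of {x.shape[0]} frames too short for zero-lag filtering "
            f"(needs > {padlen})"
        )
    return signal.filtfilt(b, a, x, axis=0, padtype="even", padlen=padlen)


def filter_trajectories(
    traj: TrajectorySet, cutoff_hz: float = 6.0, order: int = 4
) -> TrajectorySet:
    """Low-pass each marker coordinate with a zero-phase Butterworth filter.

    ``order`` is the order of the single-pass filter; the forward-backward
    pass doubles the effective magnitude order and cancels the phase.
    Defaults: 6 Hz cutoff, 4th order.
    """
    b, a = _butter_ba(cutoff_hz, order, traj.rate)
    return TrajectorySet(
        {name: _filtfilt(arr, b, a, order) for name, arr in traj.markers.items()},
        traj.rate,
    )


def filter_angles(
    series: JointAngleSeries, cutoff_hz: float = 6.0, order: int = 4
) -> JointAngleSeries:
    """Zero-phase low-pass of an angle series (alternative filter stage)."""
    b, a = _butter_ba(cutoff_hz, order, series.rate)
    return _dc_replace(series, angles=_filtfilt(series.angles, b, a, order))


# --- static baseline and peaks -----------------------------------------------

def compute_baseline(
    angles: dict[str, JointAngleSeries], window: tuple[int, int] | None = None
) -> StaticBaseline:
    """Mean angle triple per joint over a static standing trial (or window)."""
    out: StaticBaseline = {}
    for joint, series in angles.items():
        sl = slice(*window) if window else slice(None)
        chunk = series.angles[sl]
        if chunk.shape[0] < 1:
            raise ValueError(f"baseline window for joint {joint!r} is empty")
        out[joint] = chunk.mean(axis=0)
    return out


def subtract_baseline(series: JointAngleSeries, baseline: StaticBaseline) -> JointAngleSeries:
    """Re-express angles relative to the static standing posture."""
    if series.joint not in baseline:
        raise KeyError(f"baseline has no entry for joint {series.joint!r}")
    return _dc_replace(
        series,
        angles=series.angles - np.asarray(baseline[series.joint], dtype=float),
        baseline_subtracted=True,
    )


def extract_peaks(
    series: JointAngleSeries, window: tuple[int, int] | None = None, task: str = ""
) -> PeakSummary:
    """Maximum and minimum of each rotation component within a task window."""
    start, stop = window if window is not None else (0, series.n_frames)
    if not (0 <= start < stop <= series.n_frames):
        raise ValueError(
            f"window [{start}, {stop}) invalid for series of {series.n_frames} frames"
        )
    chunk = series.angles[start:stop]
    return PeakSummary(
        joint=series.joint,
        task=task,
        maxima=chunk.max(axis=0),
        minima=chunk.min(axis=0),
        window=(start, stop),
    )
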