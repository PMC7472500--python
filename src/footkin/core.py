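"""Core in-memory containers: labelled marker trajectories and rigid-segment poses.

Coordinates follow the laboratory convention used throughout the package
(right foot): X anterior, Y superior, Z toward the right (lateral).
Positions are millimetres; orientations are proper rotation matrices whose
columns are the segment axes expressed in the lab frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrajectorySet", "PoseSeries"]


@dataclass
class TrajectorySet:
    """Labelled 3D marker trajectories sampled at a fixed rate.

    Parameters
    ----------
    markers
        Mapping of marker name to an ``(n_frames, 3)`` array of positions in
        millimetres, lab frame.
    rate
        Sampling rate in Hz (must be positive).
    """

    markers: dict[str, np.ndarray]
    rate: float

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.rate}")
        clean: dict[str, np.ndarray] = {}
        n = None
        for name, xyz in self.markers.items():
            arr = np.asarray(xyz, dtype=float)
            if arr.ndim == 1:
                arr = arr.reshape(1, 3)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError(f"marker {name!r}: expected (n, 3) array, got {arr.shape}")
            if n is None:
                n = arr.shape[0]
            elif arr.shape[0] != n:
                raise ValueError(
                    f"marker {name!r} has {arr.shape[0]} frames, expected {n}"
                )
            clean[name] = arr
        if n is None:
            raise ValueError("TrajectorySet needs at least one marker")
        self.markers = clean

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def names(self) -> list[str]:
        return list(self.markers)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.rate

    def __contains__(self, name: str) -> bool:
        return name in self.markers

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.markers[name]
        except KeyError:
            raise KeyError(
                f"marker {name!r} not present (have: {', '.join(sorted(self.markers))})"
            ) from None

    def require(self, *names: str) -> None:
        """Raise a ``KeyError`` naming the first missing marker, if any."""
        for name in names:
            if name not in self.markers:
                raise KeyError(f"marker {name!r} required but not present")

    def check_finite(self) -> None:
        for name, arr in self.markers.items():
            if not np.all(np.isfinite(arr)):
                bad = int(np.argwhere(~np.isfinite(arr).all(axis=1))[0, 0])
                raise ValueError(f"marker {name!r} has non-finite position at frame {bad}")

    def subset(self, names) -> "TrajectorySet":
        self.require(*names)
        return TrajectorySet({n: self.markers[n].copy() for n in names}, self.rate)

    def renamed(self, mapping: dict[str, str], keep_unmapped: bool = True) -> "TrajectorySet":
        """Return a copy with marker names translated through ``mapping``."""
        out: dict[str, np.ndarray] = {}
        for name, arr in self.markers.items():
            if name in mapping:
                out[mapping[name]] = arr.copy()
            elif keep_unmapped:
                out[name] = arr.copy()
        return TrajectorySet(out, self.rate)

    def with_markers(self, extra: dict[str, np.ndarray]) -> "TrajectorySet":
        merged = {n: a.copy() for n, a in self.markers.items()}
        for name, arr in extra.items():
            merged[name] = np.asarray(arr, dtype=float)
        return TrajectorySet(merged, self.rate)

    def to_dataframe(self) -> pd.DataFrame:
        """Wide-format frame table: ``frame, time_s, <marker>_x, _y, _z``."""
        data: dict[str, np.ndarray] = {
            "frame": np.arange(self.n_frames),
            "time_s": self.times,
        }
        for name in self.names:
            arr = self.markers[name]
            for i, ax in enumerate("xyz"):
                data[f"{name}_{ax}"] = arr[:, i]
        return pd.DataFrame(data)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, rate: float) -> "TrajectorySet":
        names: list[str] = []
        for col in df.columns:
            if col.endswith("_x"):
                names.append(col[:-2])
        markers = {}
        for name in names:
            cols = [f"{name}_{ax}" for ax in "xyz"]
            markers[name] = df[cols].to_numpy(dtype=float)
        return cls(markers, rate)


@dataclass
class PoseSeries:
    """Per-frame orientation and origin of one rigid segment.

    ``rotations`` is ``(n, 3, 3)``; column ``j`` of each matrix is the
    segment's j-th anatomical axis (X anterior, Y superior, Z lateral)
    expressed in the lab frame.  ``origins`` is ``(n, 3)`` in millimetres.
    """

    segment: str
    rotations: np.ndarray
    origins: np.ndarray
    rate: float = 0.0

    def __post_init__(self) -> None:
        self.rotations = np.asarray(self.rotations, dtype=float)
        self.origins = np.asarray(self.origins, dtype=float)
        if self.rotations.ndim == 2:
            self.rotations = self.rotations[None]
        if self.origins.ndim == 1:
            self.origins = self.origins[None]
        if self.rotations.shape[1:] != (3, 3):
            raise ValueError(f"rotations must be (n, 3, 3), got {self.rotations.shape}")
        if self.origins.shape != (self.rotations.shape[0], 3):
            raise ValueError("origins must be (n, 3) matching rotations")

    @property
    def n_frames(self) -> int:
        return self.rotations.shape[0]

    def check_orthonormal(self, tol: float = 1e-9) -> None:
        R = self.rotations
        err = np.abs(np.einsum("nij,nik->njk", R, R) - np.eye(3)).max()
        if err > tol:
            raise ValueError(f"segment {self.segment!r}: orientation not orthonormal (err={err:.2e})")
        det = np.linalg.det(R)
        if np.any(det < 0):
            raise ValueError(f"segment {self.segment!r}: left-handed orientation (det<0)")
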