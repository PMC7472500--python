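"""Motion-capture file I/O: TRC (OpenSim dialect), wide CSV, optional C3D.

TRC and CSV are the guaranteed text baseline; C3D reading is available only
when ``ezc3d`` is importable (feature-detected at call time).  Marker labels
are normalised to the canonical landmark codes through an alias table that
covers the Rizzoli names and common ``Subject:Label`` prefixes.

CSV dialect: wide format, header ``frame,time_s,<marker>_x,...``, millimetre
units, comma separator.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .core import TrajectorySet
from .kinematics import COMPONENTS, JointAngleSeries
from .models import LANDMARKS, RIZZOLI_ALIASES

__all__ = [
    "DEFAULT_ALIASES",
    "read_trajectories",
    "write_trajectories",
    "read_trc",
    "write_trc",
    "read_csv",
    "write_csv",
    "read_c3d",
    "angles_to_frame",
    "write_angles_csv",
]

#: foreign label -> canonical code (Rizzoli names map back onto Table-1 codes)
DEFAULT_ALIASES: dict[str, str] = {alias: name for name, alias in RIZZOLI_ALIASES.items()}

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


def _apply_aliases(
    markers: dict[str, np.ndarray], aliases: dict[str, str] | None, strict: bool
) -> dict[str, np.ndarray]:
    table = dict(DEFAULT_ALIASES)
    if aliases:
        table.update(aliases)
    out: dict[str, np.ndarray] = {}
    unmapped: list[str] = []
    for label, arr in markers.items():
        # tolerate Vicon-style "Subject:Label" prefixes
        short = label.split(":")[-1]
        name = table.get(label, table.get(short, short))
        if strict and name not in LANDMARKS:
            unmapped.append(label)
        if name in out:
            raise ValueError(f"marker label collision: {label!r} also maps to {name!r}")
        out[name] = arr
    if strict and unmapped:
        raise ValueError(f"unmapped marker labels: {', '.join(sorted(unmapped))}")
    return out


def read_trajectories(
    path: str | Path,
    format: str | None = None,
    aliases: dict[str, str] | None = None,
    strict: bool = False,
    rate: float | None = None,
) -> TrajectorySet:
    """Read a trajectory file, dispatching on ``format`` or file extension."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "trc":
        traj = read_trc(path)
    elif fmt == "csv":
        if rate is None:
            raise ValueError("CSV input needs an explicit sampling rate")
        traj = read_csv(path, rate)
    elif fmt == "c3d":
        traj = read_c3d(path)
    else:
        raise ValueError(f"unknown trajectory format {fmt!r} (use trc, csv or c3d)")
    return TrajectorySet(_apply_aliases(traj.markers, aliases, strict), traj.rate)


def write_trajectories(traj: TrajectorySet, path: str | Path) -> Path:
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "trc":
        return write_trc(traj, path)
    if fmt == "csv":
        return write_csv(traj, path)
    raise ValueError(f"cannot write format {fmt!r} (use .trc or .csv)")


# --- TRC ---------------------------------------------------------------------

def read_trc(path: str | Path) -> TrajectorySet:
    """Parse an OpenSim-dialect TRC file (tab-separated text)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 6:
        raise ValueError(f"{path}: not a TRC file (fewer than 6 header+data lines)")
    header_keys = lines[1].split("\t")
    header_vals = lines[2].split("\t")
    header = dict(zip(header_keys, header_vals))
    try:
        rate = float(header["DataRate"])
        n_markers = int(header["NumMarkers"])
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: malformed TRC header line 3: {exc}") from exc
    unit = header.get("Units", "mm").strip().lower()
    scale = _UNIT_TO_MM.get(unit)
    if scale is None:
        raise ValueError(f"{path}: unsupported TRC units {unit!r}")

    labels = [s for s in lines[3].split("\t")[2:] if s.strip()]
    if len(labels) != n_markers:
        raise ValueError(
            f"{path}: header says {n_markers} markers but {len(labels)} labels found"
        )
    data_rows = []
    for idx, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        cells = line.split("\t")
        vals = cells[2 : 2 + 3 * n_markers]
        if len(vals) < 3 * n_markers:
            raise ValueError(f"{path}: truncated data row at line {idx}")
        try:
            data_rows.append([float(v) if v.strip() else np.nan for v in vals])
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable number at line {idx}: {exc}") from exc
    if not data_rows:
        raise ValueError(f"{path}: TRC file contains no data rows")
    data = np.asarray(data_rows) * scale
    markers = {
        label: data[:, 3 * i : 3 * i + 3] for i, label in enumerate(labels)
    }
    return TrajectorySet(markers, rate)


def write_trc(traj: TrajectorySet, path: str | Path) -> Path:
    path = Path(path)
    names = traj.names
    n = traj.n_frames
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{path.name}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\tOrigDataStartFrame\tOrigNumFrames",
        f"{traj.rate:g}\t{traj.rate:g}\t{n}\t{len(names)}\tmm\t{traj.rate:g}\t1\t{n}",
        "Frame#\tTime\t" + "\t\t\t".join(names) + "\t\t",
        "\t\t" + "\t".join(f"X{i}\tY{i}\tZ{i}" for i in range(1, len(names) + 1)),
    ]
    times = traj.times
    for i in range(n):
        cells = [str(i + 1), f"{times[i]:.6f}"]
        for name in names:
            cells.extend(f"{v:.8f}" for v in traj.markers[name][i])
        lines.append("\t".join(cells))
    path.write_text("\n".join(lines) + "\n")
    return path


# --- CSV ---------------------------------------------------------------------

def read_csv(path: str | Path, rate: float) -> TrajectorySet:
    path = Path(path)
    df = pd.read_csv(path)
    if "frame" in df.columns:
        frames = df["frame"].to_numpy()
        expected = np.arange(frames[0], frames[0] + len(frames))
        missing = np.setdiff1d(np.arange(frames[0], frames[-1] + 1), frames)
        if missing.size:
            raise ValueError(f"{path}: missing frame row(s): {missing[:5].tolist()}")
        if not np.array_equal(frames, expected):
            raise ValueError(f"{path}: frame column is not contiguous")
    return TrajectorySet.from_dataframe(df, rate)


def write_csv(traj: TrajectorySet, path: str | Path) -> Path:
    path = Path(path)
    traj.to_dataframe().to_csv(path, index=False, float_format="%.8f")
    return path


# --- C3D (optional) ----------------------------------------------------------

def read_c3d(path: str | Path) -> TrajectorySet:
    """Read a C3D file; requires the optional ``ezc3d`` dependency."""
    try:
        import ezc3d
    except ImportError as exc:
        raise ImportError(
            "C3D support requires the optional 'ezc3d' package "
            "(pip install footkin[c3d]); TRC and CSV need no extras"
        ) from exc
    c3d = ezc3d.c3d(str(Path(path)))
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    unit = str(c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])[0]).lower()
    scale = _UNIT_TO_MM.get(unit, 1.0)
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    markers = {
        label: np.ascontiguousarray(pts[:3, i, :].T) * scale
        for i, label in enumerate(labels)
    }
    return TrajectorySet(markers, rate)


# --- angle export ------------------------------------------------------------

def angles_to_frame(
    angles: dict[str, JointAngleSeries], trial: str = ""
) -> pd.DataFrame:
    """Tidy angle table: trial, joint, component, frame, time_s, angle_deg, gimbal_flag."""
    rows = []
    for joint, series in angles.items():
        times = np.arange(series.n_frames) / series.rate if series.rate > 0 else np.arange(series.n_frames, dtype=float)
        for ci, comp in enumerate(COMPONENTS):
            rows.append(
                pd.DataFrame(
                    {
                        "trial": trial,
                        "joint": joint,
                        "component": comp,
                        "frame": np.arange(series.n_frames),
                        "time_s": times,
                        "angle_deg": series.angles[:, ci],
                        "gimbal_flag": series.gimbal,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def write_angles_csv(
    angles: dict[str, JointAngleSeries], path: str | Path, trial: str = ""
) -> Path:
    path = Path(path)
    angles_to_frame(angles, trial).to_csv(path, index=False, float_format="%.6f")
    return path
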