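"""Multi-segment foot model registry and segment-frame construction.

Three models are registered:

``new``
    Shank + three foot segments (hallux, forefoot, rearfoot), each frame
    defined by a long-axis marker pair and a three-marker plane.
``new_2``
    Identical to ``new`` except the rearfoot frame, which is built in the
    sagittal plane (C2 to MC, plane C2-MC-C1) instead of the transverse one.
``rizzoli``
    The Rizzoli foot model, reconstructed from its published description and
    the marker alias table (PM, FMH, ..., IM); segment frames here are a
    configurable reconstruction, not a verbatim transcription, and the
    midfoot segment of the full published model is omitted (the joints
    analysed are Met_Hal, Cal_Met and Sha_Cal only).

Frames are right-foot frames: X anterior, Y superior, Z lateral.  Left-foot
data must be pre-mirrored (negate lab Z) by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import yaml

from .core import PoseSeries, TrajectorySet

__all__ = [
    "MarkerLandmark",
    "SegmentDefinition",
    "FootModelSpec",
    "LANDMARKS",
    "RIZZOLI_ALIASES",
    "MODEL_IDS",
    "register_model",
    "derive_virtual_markers",
    "build_segment_pose",
    "model_to_yaml",
    "model_from_yaml",
]


@dataclass(frozen=True)
class MarkerLandmark:
    """One anatomical landmark of the marker set."""

    name: str
    description: str
    rizzoli_alias: str | None = None
    computed_from: tuple[str, str] | None = None  # midpoint parents, if virtual

    @property
    def is_virtual(self) -> bool:
        return self.computed_from is not None


#: Table of landmarks: short code, anatomical description, Rizzoli alias.
#: MC and IM are computed midpoints, never measured.
LANDMARKS: dict[str, MarkerLandmark] = {
    lm.name: lm
    for lm in [
        MarkerLandmark("P1", "Dorso-medial aspect of the first proximal phalanx head", "PM"),
        MarkerLandmark("H1", "Dorso-medial aspect of the first metatarsal head", "FMH"),
        MarkerLandmark("H2", "Dorso-medial aspect of the second metatarsal head", "SMH"),
        MarkerLandmark("H5", "Dorso-lateral aspect of the fifth metatarsal head", "VMH"),
        MarkerLandmark("B1", "Dorso-medial aspect of the first metatarsal base", "FMB"),
        MarkerLandmark("B2", "Dorso-medial aspect of the second metatarsal base", "SMB"),
        MarkerLandmark("B5", "Dorso-lateral aspect of the fifth metatarsal base", "VMB"),
        MarkerLandmark("NV", "Most medial apex of the navicular bone", "TN"),
        MarkerLandmark("ST", "Most medial apex of the sustentaculum tali", "ST"),
        MarkerLandmark("PT", "Lateral apex of the peroneal tubercle", "PT"),
        MarkerLandmark("C1", "Superior apex of calcaneus", "CA"),
        MarkerLandmark("C2", "Apex of calcaneal tuberosity", "HL"),
        MarkerLandmark("LM", "Distal apex of the lateral malleolus", "LM"),
        MarkerLandmark("MM", "Distal apex of the medial malleolus", "MM"),
        MarkerLandmark("TT", "Most anterior prominence of the tibial tuberosity", "TT"),
        MarkerLandmark("HF", "Most proximal apex of the head of the fibula", "HF"),
        MarkerLandmark("MC", "Midpoint between NV and B5", "ID", computed_from=("NV", "B5")),
        MarkerLandmark("IM", "Midpoint between MM and LM", "IM", computed_from=("MM", "LM")),
    ]
}

#: Canonical code -> Rizzoli code (both directions are used by the I/O layer).
RIZZOLI_ALIASES: dict[str, str] = {
    lm.name: lm.rizzoli_alias for lm in LANDMARKS.values() if lm.rizzoli_alias
}

PLANE_LABELS = ("transverse", "sagittal", "frontal")
# Anatomical axis each plane normal maps to (column index: 0=X ant, 1=Y sup, 2=Z lat).
_PLANE_NORMAL_AXIS = {"transverse": 1, "sagittal": 2, "frontal": 0}
_PRIMARY_AXIS = {"anterior": 0, "superior": 1}
_EVEN_PERMS = {(0, 1, 2), (1, 2, 0), (2, 0, 1)}


@dataclass(frozen=True)
class SegmentDefinition:
    """Declarative recipe for one segment-fixed reference frame.

    The long axis runs ``axis_from -> axis_to`` and is mapped to the
    anatomical axis named by ``primary`` (anterior = +X, superior = +Y).
    The unit normal of the ``plane`` marker triple supplies the second axis
    (transverse plane -> +Y, sagittal -> +Z, frontal -> +X); the third axis
    completes a right-handed triad.  ``flip_normal`` fixes the sign of the
    triple's cross product so the normal points in the anatomical direction
    for a right foot; it is part of the model definition, making the frame
    strictly equivariant under rigid motions of the markers.
    """

    name: str
    axis_from: str
    axis_to: str
    plane: tuple[str, str, str]
    plane_label: str
    primary: str = "anterior"
    flip_normal: bool = False

    def __post_init__(self) -> None:
        if self.plane_label not in PLANE_LABELS:
            raise ValueError(f"unknown plane label {self.plane_label!r}")
        if self.primary not in _PRIMARY_AXIS:
            raise ValueError(f"unknown primary-axis mapping {self.primary!r}")
        if len(self.plane) != 3:
            raise ValueError("plane must name exactly three markers")
        if _PRIMARY_AXIS[self.primary] == _PLANE_NORMAL_AXIS[self.plane_label]:
            raise ValueError(
                f"segment {self.name!r}: primary axis and plane normal map to the same anatomical axis"
            )

    @property
    def markers(self) -> tuple[str, ...]:
        seen: list[str] = []
        for m in (self.axis_from, self.axis_to, *self.plane):
            if m not in seen:
                seen.append(m)
        return tuple(seen)


@dataclass(frozen=True)
class FootModelSpec:
    """A full foot model: segments, joints and virtual-marker recipes."""

    model_id: str
    segments: tuple[SegmentDefinition, ...]
    #: (joint name, distal/child segment, proximal/parent segment)
    joints: tuple[tuple[str, str, str], ...]
    #: virtual marker name -> midpoint parent pair
    virtual_markers: tuple[tuple[str, tuple[str, str]], ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        names = [s.name for s in self.segments]
        if len(set(names)) != len(names):
            raise ValueError("duplicate segment names")
        for joint, child, parent in self.joints:
            for seg in (child, parent):
                if seg not in names:
                    raise ValueError(f"joint {joint!r} references undefined segment {seg!r}")

    def segment(self, name: str) -> SegmentDefinition:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(f"model {self.model_id!r} has no segment {name!r}")

    def joint(self, name: str) -> tuple[str, str]:
        """Return (child segment, parent segment) for a joint name."""
        for joint, child, parent in self.joints:
            if joint == name:
                return child, parent
        raise KeyError(f"model {self.model_id!r} has no joint {name!r}")

    @property
    def joint_names(self) -> tuple[str, ...]:
        return tuple(j for j, _, _ in self.joints)

    @property
    def marker_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for seg in self.segments:
            for m in seg.markers:
                if m not in seen:
                    seen.append(m)
        return tuple(seen)


# --- registered models -------------------------------------------------------

_HALLUX = SegmentDefinition(
    "Hallux", "H1", "P1", ("H1", "P1", "H5"), "transverse", flip_normal=True
)
_FOREFOOT = SegmentDefinition(
    "Forefoot", "MC", "H2", ("MC", "H1", "H5"), "transverse", flip_normal=True
)
_REARFOOT = SegmentDefinition(
    "Rearfoot", "C1", "MC", ("C1", "NV", "B5"), "transverse", flip_normal=True
)
_REARFOOT_2 = SegmentDefinition(
    "Rearfoot_2", "C2", "MC", ("C2", "MC", "C1"), "sagittal", flip_normal=False
)
_SHANK = SegmentDefinition(
    "Shank", "IM", "TT", ("IM", "LM", "HF"), "frontal", primary="superior", flip_normal=True
)

_NEW_VIRTUAL = (("MC", ("NV", "B5")), ("IM", ("MM", "LM")))

_NEW = FootModelSpec(
    model_id="new",
    segments=(_HALLUX, _FOREFOOT, _REARFOOT, _SHANK),
    joints=(
        ("Met_Hal", "Hallux", "Forefoot"),
        ("Cal_Met", "Forefoot", "Rearfoot"),
        ("Sha_Cal", "Rearfoot", "Shank"),
    ),
    virtual_markers=_NEW_VIRTUAL,
    notes="Transverse-plane three-segment foot model plus shank.",
)

_NEW_2 = FootModelSpec(
    model_id="new_2",
    segments=(_HALLUX, _FOREFOOT, _REARFOOT_2, _SHANK),
    joints=(
        ("Met_Hal", "Hallux", "Forefoot"),
        ("Cal_Met_2", "Forefoot", "Rearfoot_2"),
        ("Sha_Cal_2", "Rearfoot_2", "Shank"),
    ),
    virtual_markers=_NEW_VIRTUAL,
    notes="Same as 'new' except the rearfoot frame is defined in the sagittal plane.",
)

_RIZZOLI = FootModelSpec(
    model_id="rizzoli",
    segments=(
        SegmentDefinition("Hallux", "FMH", "PM", ("FMH", "PM", "VMH"), "transverse", flip_normal=True),
        SegmentDefinition("Metatarsus", "MB_", "MH_", ("FMB", "VMB", "SMH"), "transverse", flip_normal=False),
        SegmentDefinition("Calcaneus", "CA", "SP_", ("CA", "PT", "ST"), "transverse", flip_normal=False),
        SegmentDefinition("Shank", "IM", "TT", ("IM", "LM", "HF"), "frontal", primary="superior", flip_normal=True),
    ),
    joints=(
        ("Met_Hal", "Hallux", "Metatarsus"),
        ("Cal_Met", "Metatarsus", "Calcaneus"),
        ("Sha_Cal", "Calcaneus", "Shank"),
    ),
    virtual_markers=(
        ("MB_", ("FMB", "VMB")),  # metatarsal base midpoint
        ("MH_", ("FMH", "VMH")),  # metatarsal head midpoint
        ("SP_", ("ST", "PT")),    # sustentaculum tali / peroneal tubercle midpoint
        ("IM", ("MM", "LM")),
    ),
    notes=(
        "Reconstructed from the published Rizzoli description via the marker alias table; "
        "segment frames are a declared reconstruction, midfoot segment omitted."
    ),
)

_REGISTRY = {m.model_id: m for m in (_NEW, _NEW_2, _RIZZOLI)}
MODEL_IDS = tuple(_REGISTRY)


def register_model(model_id: str) -> FootModelSpec:
    """Return the declarative spec of a registered foot model.

    Raises
    ------
    KeyError
        If ``model_id`` is not one of ``new``, ``new_2``, ``rizzoli``.
    """
    try:
        return _REGISTRY[model_id]
    except KeyError:
        raise KeyError(
            f"unknown foot model {model_id!r}; available: {', '.join(MODEL_IDS)}"
        ) from None


def derive_virtual_markers(
    traj: TrajectorySet, spec: FootModelSpec, missing: str = "error"
) -> TrajectorySet:
    """Append the model's computed midpoint markers (e.g. MC, IM) to ``traj``.

    Parameters
    ----------
    missing
        ``"error"`` (default) raises when a midpoint's parent marker is
        absent; ``"skip"`` silently omits that midpoint (used when operating
        on a partial, single-segment view of a trial).
    """
    extra: dict[str, np.ndarray] = {}
    for name, (pa, pb) in spec.virtual_markers:
        if pa not in traj or pb not in traj:
            if missing == "skip":
                continue
            absent = pa if pa not in traj else pb
            raise KeyError(f"marker {absent!r} required for midpoint {name!r}")
        extra[name] = 0.5 * (traj[pa] + traj[pb])
    return traj.with_markers(extra)


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    norm = np.linalg.norm(v, axis=-1, keepdims=True)
    if np.any(norm < 1e-12):
        bad = int(np.argwhere(norm[..., 0] < 1e-12)[0, 0])
        raise ValueError(f"{what}: zero-length vector at frame {bad}")
    return v / norm


def build_segment_pose(
    traj: TrajectorySet,
    segdef: SegmentDefinition,
    collinearity_tol: float = 1e-6,
) -> PoseSeries:
    """Construct the per-frame orthonormal frame of one segment.

    The long axis is kept exact; the plane normal is re-orthogonalised
    against it (Gram-Schmidt) and the third axis completes a right-handed
    triad.  The returned rotation has det +1 and ``R^T R = I`` to 1e-9.

    Raises
    ------
    KeyError
        If a required marker is absent.
    ValueError
        If the plane markers are collinear (triangle area below
        ``collinearity_tol`` x longest-side squared) at any frame.
    """
    traj.require(*segdef.markers)
    for m in segdef.markers:
        if not np.all(np.isfinite(traj[m])):
            raise ValueError(f"segment {segdef.name!r}: marker {m!r} has non-finite samples")

    frm, to = traj[segdef.axis_from], traj[segdef.axis_to]
    p1, p2, p3 = (traj[m] for m in segdef.plane)

    e1 = _unit(to - frm, f"segment {segdef.name!r} long axis")

    v1, v2 = p2 - p1, p3 - p1
    normal = np.cross(v1, v2)
    # degenerate-plane check: triangle area vs longest side squared
    area = 0.5 * np.linalg.norm(normal, axis=-1)
    sides = np.stack(
        [np.linalg.norm(v1, axis=-1), np.linalg.norm(v2, axis=-1), np.linalg.norm(p3 - p2, axis=-1)]
    )
    longest = sides.max(axis=0)
    degen = area < collinearity_tol * longest**2
    if np.any(degen):
        bad = int(np.argwhere(degen)[0, 0])
        raise ValueError(
            f"segment {segdef.name!r}: plane markers {segdef.plane} collinear at frame {bad}"
        )
    if segdef.flip_normal:
        normal = -normal
    n = _unit(normal, f"segment {segdef.name!r} plane normal")

    # Gram-Schmidt: keep the long axis exact, orthogonalise the normal to it.
    e2 = n - np.sum(n * e1, axis=-1, keepdims=True) * e1
    e2 = _unit(e2, f"segment {segdef.name!r} orthogonalised normal (normal parallel to long axis?)")

    i = _PRIMARY_AXIS[segdef.primary]
    j = _PLANE_NORMAL_AXIS[segdef.plane_label]
    k = 3 - i - j
    cols = [None, None, None]
    cols[i], cols[j] = e1, e2
    cols[k] = np.cross(e1, e2) if (i, j, k) in _EVEN_PERMS else np.cross(e2, e1)

    R = np.stack(cols, axis=-1)  # (n, 3, 3); columns are segment axes
    pose = PoseSeries(segdef.name, R, frm.copy(), rate=traj.rate)
    pose.check_orthonormal(1e-9)
    return pose


# --- YAML (de)serialisation so users can add custom models -------------------

def model_to_yaml(spec: FootModelSpec) -> str:
    doc = {
        "model_id": spec.model_id,
        "notes": spec.notes,
        "virtual_markers": {name: list(pair) for name, pair in spec.virtual_markers},
        "segments": [
            {
                "name": s.name,
                "long_axis": [s.axis_from, s.axis_to],
                "plane": list(s.plane),
                "plane_label": s.plane_label,
                "primary": s.primary,
                "flip_normal": s.flip_normal,
            }
            for s in spec.segments
        ],
        "joints": [
            {"name": j, "child": c, "parent": p} for j, c, p in spec.joints
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def model_from_yaml(text: str) -> FootModelSpec:
    doc = yaml.safe_load(text)
    segments = tuple(
        SegmentDefinition(
            name=s["name"],
            axis_from=s["long_axis"][0],
            axis_to=s["long_axis"][1],
            plane=tuple(s["plane"]),
            plane_label=s["plane_label"],
            primary=s.get("primary", "anterior"),
            flip_normal=bool(s.get("flip_normal", False)),
        )
        for s in doc["segments"]
    )
    joints = tuple((j["name"], j["child"], j["parent"]) for j in doc["joints"])
    virtual = tuple(
        (name, tuple(pair)) for name, pair in doc.get("virtual_markers", {}).items()
    )
    return FootModelSpec(
        model_id=doc["model_id"],
        segments=segments,
        joints=joints,
        virtual_markers=virtual,
        notes=doc.get("notes", ""),
    )
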