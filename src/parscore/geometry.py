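"""Occlusal-trait measurement on landmarked dental arches.

The PAR (Peer Assessment Rating) index scores a dentition from a handful of
linear occlusal traits: contact-point displacement in the anterior segments,
overjet, overbite / open bite, centerline deviation and posterior occlusion.
On a digital model those traits are distances between anatomical landmarks,
decomposed relative to the occlusal plane: displacement and overjet are
measured *parallel* to the plane, overbite *perpendicular* to it.

This module defines the landmark containers, fits the occlusal reference
frame, and derives a :class:`TraitMeasurements` record from a pair of
landmarked arches.  All quantities are millimetres; tooth identity uses FDI
two-digit notation (quadrant digit 1-4, tooth digit 1-8).

Conventions
-----------
* The occlusal-plane normal points toward the upper arch.
* ``anterior_axis`` points sagittally toward the incisors, derived from
  lower-arch anchors so it does not rotate with upper-midline deviation.
* Overbite is the normal-axis component of (lower edge - upper edge):
  positive = vertical overlap, negative = open bite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import DegenerateFrameError, DomainError, MissingLandmarkError

LANDMARK_NAMES = frozenset(
    {
        "mesial_contact",
        "distal_contact",
        "incisal_edge",
        "labial_surface",
        "buccal_cusp",
        "midline",
    }
)

CASE_FLAGS = frozenset({"impacted", "missing", "extracted", "prosthetic_planned"})

#: FDI codes of permanent teeth, 11-18, 21-28, 31-38, 41-48.
VALID_FDI = frozenset(10 * q + t for q in (1, 2, 3, 4) for t in range(1, 9))

RIGHT_QUADRANTS = (1, 4)  # mesial direction runs toward increasing arch index


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateFrameError(f"cannot normalise near-zero {what} vector")
    return v / n


@dataclass(frozen=True)
class Landmark:
    """A named anatomical point on one tooth (mm coordinates)."""

    tooth_id: int
    name: str
    position: np.ndarray

    def __post_init__(self):
        if self.tooth_id not in VALID_FDI:
            raise DomainError(f"invalid FDI tooth code {self.tooth_id}")
        if self.name not in LANDMARK_NAMES:
            raise DomainError(f"unknown landmark name {self.name!r}")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise DomainError(f"landmark position must be a finite 3-vector, got {self.position!r}")
        object.__setattr__(self, "position", pos)

    @property
    def quadrant(self) -> int:
        return self.tooth_id // 10


@dataclass
class ArchLandmarks:
    """All landmarks of one arch plus per-tooth case flags.

    ``case_flags`` maps FDI code -> set of flags from :data:`CASE_FLAGS`
    (impacted / missing / extracted / prosthetic_planned).  A tooth flagged
    missing or extracted may still appear in ``present_teeth`` bookkeeping of
    the original dentition but carries no landmarks.
    """

    arch: str
    landmarks: list[Landmark] = field(default_factory=list)
    present_teeth: set[int] = field(default_factory=set)
    case_flags: dict[int, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if self.arch not in ("upper", "lower"):
            raise DomainError(f"arch must be 'upper' or 'lower', got {self.arch!r}")
        seen = set()
        for lm in self.landmarks:
            key = (lm.tooth_id, lm.name)
            if key in seen:
                raise DomainError(f"duplicate landmark {key} in {self.arch} arch")
            seen.add(key)
            if lm.tooth_id not in self.present_teeth:
                raise DomainError(
                    f"landmark on tooth {lm.tooth_id} not listed in present_teeth"
                )
        for fdi, flags in self.case_flags.items():
            bad = set(flags) - CASE_FLAGS
            if bad:
                raise DomainError(f"unknown case flags {bad} on tooth {fdi}")
        self._index = {(lm.tooth_id, lm.name): lm for lm in self.landmarks}

    def get(self, tooth_id: int, name: str) -> Landmark | None:
        return self._index.get((tooth_id, name))

    def require(self, tooth_id: int, name: str) -> Landmark:
        lm = self.get(tooth_id, name)
        if lm is None:
            raise MissingLandmarkError(
                f"{self.arch} arch lacks landmark {name!r} on tooth {tooth_id}"
            )
        return lm

    def has_flag(self, tooth_id: int, flag: str) -> bool:
        return flag in self.case_flags.get(tooth_id, set())

    def is_absent(self, tooth_id: int) -> bool:
        """True when the tooth cannot carry landmarks (missing/extracted/impacted)."""
        flags = self.case_flags.get(tooth_id, set())
        return bool(flags & {"missing", "extracted", "impacted"})

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "ArchLandmarks":
        """Return a rigidly transformed copy (x -> R x + t)."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new = [replace(lm, position=R @ lm.position + t) for lm in self.landmarks]
        return ArchLandmarks(self.arch, new, set(self.present_teeth), {k: set(v) for k, v in self.case_flags.items()})


@dataclass(frozen=True)
class OcclusalFrame:
    """Orthonormal reference frame anchored to the occlusal plane."""

    origin: np.ndarray
    normal: np.ndarray
    anterior_axis: np.ndarray
    transverse_axis: np.ndarray

    def __post_init__(self):
        for name in ("origin", "normal", "anterior_axis", "transverse_axis"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float))
        axes = (self.normal, self.anterior_axis, self.transverse_axis)
        for a in axes:
            if abs(np.linalg.norm(a) - 1.0) > 1e-8:
                raise DomainError("frame axes must be unit vectors")
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(float(axes[i] @ axes[j])) > 1e-8:
                    raise DomainError("frame axes must be mutually orthogonal")

    def in_plane(self, v: np.ndarray) -> np.ndarray:
        """Component of ``v`` parallel to the occlusal plane."""
        v = np.asarray(v, float)
        return v - (v @ self.normal) * self.normal


# ---------------------------------------------------------------------------
# configuration

# (arch, fdi, landmark-name) triplets.  Posterior buccal cusps only: the
# reference plane must not move with incisor-level traits (overbite, overjet),
# otherwise severity would leak into the frame itself.
DEFAULT_PLANE_ANCHORS: tuple[tuple[str, int, str], ...] = tuple(
    (arch, fdi, "buccal_cusp")
    for arch, quads in (("upper", (1, 2)), ("lower", (3, 4)))
    for q in quads
    for fdi in (10 * q + 4, 10 * q + 6)
)

DEFAULT_AXIS_POSTERIOR = (("lower", 36, "buccal_cusp"), ("lower", 46, "buccal_cusp"))
DEFAULT_AXIS_ANTERIOR = (("lower", 31, "incisal_edge"), ("lower", 41, "incisal_edge"))

UPPER_ANTERIOR_SEQUENCE = (13, 12, 11, 21, 22, 23)
LOWER_ANTERIOR_SEQUENCE = (43, 42, 41, 31, 32, 33)

#: (upper incisor, lower incisor) pairs for overjet/overbite/crossbite.
DEFAULT_INCISOR_PAIRS = ((11, 41), (21, 31), (12, 42), (22, 32))

#: posterior teeth examined for transverse relation, per quadrant digit.
POSTERIOR_TOOTH_DIGITS = (4, 5, 6, 7)


@dataclass
class GeometryConfig:
    """Anchor sets and thresholds for trait extraction.

    ``lower_incisor_width_mm`` converts the transverse midline offset into the
    fraction of a lower central incisor the PAR centerline rule asks for.
    The transverse thresholds govern the geometric posterior classification:
    relative buccal overjet below ``crossbite_below_mm`` is a crossbite, below
    ``tendency_below_mm`` a crossbite tendency, above ``scissor_above_mm`` a
    scissor bite.
    """

    plane_anchors: tuple = DEFAULT_PLANE_ANCHORS
    axis_posterior: tuple = DEFAULT_AXIS_POSTERIOR
    axis_anterior: tuple = DEFAULT_AXIS_ANTERIOR
    incisor_pairs: tuple = DEFAULT_INCISOR_PAIRS
    lower_incisor_width_mm: float = 5.5
    crossbite_below_mm: float = 0.0
    tendency_below_mm: float = 0.5
    scissor_above_mm: float = 6.0


@dataclass(frozen=True)
class ContactDisplacement:
    """In-plane distance between facing contact points of one adjacent pair."""

    segment: str  # "upper_anterior" | "lower_anterior"
    teeth: tuple[int, int]
    value_mm: float


@dataclass(frozen=True)
class PosteriorCategories:
    """Per-side posterior occlusion category codes (PAR vocabulary)."""

    sagittal: int = 0  # 0 good interdigitation, 1 < half-unit discrepancy, 2 cusp-to-cusp
    vertical: int = 0  # 0 none, 1 lateral open bite
    transverse: int = 0  # 0 none, 1 tendency, 2 one tooth xbite, 3 >1 tooth, 4 scissor

    def __post_init__(self):
        if not (0 <= self.sagittal <= 2 and 0 <= self.vertical <= 1 and 0 <= self.transverse <= 4):
            raise DomainError(f"posterior category out of range: {self}")


@dataclass
class TraitMeasurements:
    """Raw occlusal trait values for one dentition at one timepoint."""

    contact_displacements: list[ContactDisplacement] = field(default_factory=list)
    impacted_teeth: dict[str, int] = field(default_factory=dict)
    overjet_mm: float = 0.0
    anterior_crossbite_teeth: int = 0
    overbite_overlap_mm: float = 0.0  # signed; negative = open bite
    centerline_fraction: float = 0.0
    posterior: dict[str, PosteriorCategories] = field(
        default_factory=lambda: {"left": PosteriorCategories(), "right": PosteriorCategories()}
    )
    skipped_segments: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.overjet_mm < 0 or self.centerline_fraction < 0:
            raise DomainError("overjet and centerline fraction must be non-negative")
        for cd in self.contact_displacements:
            if cd.value_mm < 0:
                raise DomainError("contact displacement must be non-negative")


# ---------------------------------------------------------------------------
# frame fitting


def _anchor_points(upper: ArchLandmarks, lower: ArchLandmarks, spec) -> list[np.ndarray]:
    arches = {"upper": upper, "lower": lower}
    pts = []
    for arch, fdi, name in spec:
        lm = arches[arch].get(fdi, name)
        if lm is not None:
            pts.append(lm.position)
    return pts


def fit_occlusal_frame(
    upper: ArchLandmarks,
    lower: ArchLandmarks,
    config: GeometryConfig | None = None,
) -> OcclusalFrame:
    """Least-squares occlusal plane plus sagittal/transverse axes.

    The plane is the total-least-squares fit (SVD) through the configured
    anchor landmarks.  The anterior axis is the in-plane projection of the
    vector from the inter-molar midpoint to the inter-incisal midpoint of the
    lower arch, so the frame is covariant under rigid motion of the dentition
    and independent of upper-arch trait severity.
    """
    cfg = config or GeometryConfig()
    pts = _anchor_points(upper, lower, cfg.plane_anchors)
    if len(pts) < 3:
        raise DegenerateFrameError(
            f"need >= 3 plane anchors, found {len(pts)} of {len(cfg.plane_anchors)}"
        )
    P = np.asarray(pts, float)
    origin = P.mean(axis=0)
    _, s, vh = np.linalg.svd(P - origin)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateFrameError("plane anchors are collinear")
    normal = vh[2]

    # orient the normal toward the upper arch; the upper-minus-lower centroid
    # difference is robust to severe traits dragging single landmarks across
    # the plane
    upper_centroid = np.mean([lm.position for lm in upper.landmarks], axis=0)
    lower_centroid = np.mean([lm.position for lm in lower.landmarks], axis=0)
    if float(normal @ (upper_centroid - lower_centroid)) < 0:
        normal = -normal

    post = _anchor_points(upper, lower, cfg.axis_posterior)
    ant = _anchor_points(upper, lower, cfg.axis_anterior)
    if not post or not ant:
        raise MissingLandmarkError("axis anchor landmarks missing; cannot orient frame")
    sagittal = np.mean(ant, axis=0) - np.mean(post, axis=0)
    sagittal = sagittal - (sagittal @ normal) * normal
    anterior_axis = _unit(sagittal, "anterior-axis")
    transverse_axis = np.cross(anterior_axis, normal)
    return OcclusalFrame(origin, normal, anterior_axis, transverse_axis)


# ---------------------------------------------------------------------------
# elementary trait measurements


def contact_displacement(a: Landmark, b: Landmark, frame: OcclusalFrame) -> float:
    """Shortest distance between two contact points parallel to the occlusal plane."""
    return float(np.linalg.norm(frame.in_plane(a.position - b.position)))


def measure_overjet(
    upper_incisor_edges: list[Landmark],
    lower_labial_points: list[Landmark],
    frame: OcclusalFrame,
) -> float:
    """Largest sagittal (anterior-axis) separation over matched incisor pairs.

    Reverse overjet clamps to 0; anterior crossbite is counted separately.
    """
    if not upper_incisor_edges or not lower_labial_points:
        raise MissingLandmarkError("overjet needs at least one upper/lower incisor pair")
    if len(upper_incisor_edges) != len(lower_labial_points):
        raise MissingLandmarkError("overjet landmark lists must be matched pairs")
    best = 0.0
    for u, l in zip(upper_incisor_edges, lower_labial_points):
        best = max(best, float((u.position - l.position) @ frame.anterior_axis))
    return best


def measure_overbite(upper_edge: Landmark, lower_edge: Landmark, frame: OcclusalFrame) -> float:
    """Signed vertical incisor relation: positive overlap, negative open bite."""
    if upper_edge is None or lower_edge is None:
        raise MissingLandmarkError("overbite needs an upper/lower incisal-edge pair")
    return float((lower_edge.position - upper_edge.position) @ frame.normal)


def measure_centerline(
    upper_midline: Landmark,
    lower_midline: Landmark,
    lower_incisor_width_mm: float,
    frame: OcclusalFrame,
) -> float:
    """Transverse midline offset as a fraction of lower central incisor width."""
    if lower_incisor_width_mm <= 0:
        raise DomainError("lower incisor width must be positive")
    d = upper_midline.position - lower_midline.position
    return abs(float(d @ frame.transverse_axis)) / lower_incisor_width_mm


# ---------------------------------------------------------------------------
# segment walking


def _facing_contacts(a: int, b: int) -> tuple[str, str]:
    """Landmark names of the contact surfaces of ``a`` and ``b`` that face
    each other, for consecutive teeth ``a`` then ``b`` in right-to-left arch
    order (mesial runs toward the midline)."""
    name_a = "mesial_contact" if a // 10 in RIGHT_QUADRANTS else "distal_contact"
    name_b = "distal_contact" if b // 10 in RIGHT_QUADRANTS else "mesial_contact"
    return name_a, name_b


def _segment_pairs(arch: ArchLandmarks, sequence: tuple[int, ...]):
    """Yield (tooth_a, name_a, tooth_b, name_b) contact pairs for a segment,
    skipping pairs that bridge an unreplaced extraction/missing space.

    A missing tooth flagged ``prosthetic_planned`` keeps the space scoreable:
    the flanking teeth's facing contacts form a bridging pair.
    """
    present = [t for t in sequence if not arch.is_absent(t)]
    for a, b in zip(present, present[1:]):
        ia, ib = sequence.index(a), sequence.index(b)
        gap = sequence[ia + 1 : ib]
        if gap and not any(arch.has_flag(t, "prosthetic_planned") for t in gap):
            continue  # unreplaced space: pair excluded from displacement scoring
        name_a, name_b = _facing_contacts(a, b)
        yield a, name_a, b, name_b


def _segment_displacements(
    arch: ArchLandmarks,
    sequence: tuple[int, ...],
    segment: str,
    frame: OcclusalFrame,
    out: TraitMeasurements,
) -> None:
    n_impacted = sum(1 for t in sequence if arch.has_flag(t, "impacted"))
    out.impacted_teeth[segment] = n_impacted
    present = [t for t in sequence if not arch.is_absent(t)]
    if len(present) < 2:
        out.skipped_segments.append(segment)
        return
    for a, name_a, b, name_b in _segment_pairs(arch, sequence):
        la, lb = arch.get(a, name_a), arch.get(b, name_b)
        if la is None or lb is None:
            continue
        out.contact_displacements.append(
            ContactDisplacement(segment, (a, b), contact_displacement(la, lb, frame))
        )


def _posterior_transverse(
    upper: ArchLandmarks, lower: ArchLandmarks, frame: OcclusalFrame, cfg: GeometryConfig
) -> dict[str, int]:
    """Classify the transverse posterior relation per side from buccal cusps.

    For each opposing premolar/molar pair the *buccal overjet* is the signed
    transverse margin by which the upper buccal cusp sits buccal to the lower
    one (positive in normal occlusion, measured away from the midline)."""
    cats: dict[str, int] = {}
    for side, quads in (("right", (1, 4)), ("left", (2, 3))):
        margins = []
        qu, ql = quads
        for digit in POSTERIOR_TOOTH_DIGITS:
            lu = upper.get(10 * qu + digit, "buccal_cusp")
            ll = lower.get(10 * ql + digit, "buccal_cusp")
            if lu is None or ll is None:
                continue
            tu = float((lu.position - frame.origin) @ frame.transverse_axis)
            tl = float((ll.position - frame.origin) @ frame.transverse_axis)
            margins.append(abs(tu) - abs(tl))
        if not margins:
            cats[side] = 0
            continue
        m = np.asarray(margins)
        n_cross = int(np.sum(m < cfg.crossbite_below_mm))
        n_scissor = int(np.sum(m > cfg.scissor_above_mm))
        if n_scissor > 1:
            cats[side] = 4
        elif n_cross > 1:
            cats[side] = 3
        elif n_cross == 1:
            cats[side] = 2
        elif np.any(m < cfg.tendency_below_mm):
            cats[side] = 1
        else:
            cats[side] = 0
    return cats


def extract_traits(
    upper: ArchLandmarks,
    lower: ArchLandmarks,
    config: GeometryConfig | None = None,
    posterior_input: dict[str, dict[str, int]] | None = None,
    frame: OcclusalFrame | None = None,
) -> TraitMeasurements:
    """Derive every PAR trait from a landmarked upper/lower arch pair.

    ``posterior_input`` optionally supplies rater-recorded posterior category
    codes per side (keys ``sagittal``/``vertical``/``transverse``); categories
    not supplied fall back to the geometric classification (transverse) or 0
    (sagittal/vertical, which need occlusal-surface information beyond the
    landmark vocabulary).
    """
    cfg = config or GeometryConfig()
    frm = frame or fit_occlusal_frame(upper, lower, cfg)
    out = TraitMeasurements()
    out.posterior = {}

    _segment_displacements(upper, UPPER_ANTERIOR_SEQUENCE, "upper_anterior", frm, out)
    _segment_displacements(lower, LOWER_ANTERIOR_SEQUENCE, "lower_anterior", frm, out)

    # overjet + anterior crossbite over matched incisor pairs
    uppers, lowers, edges = [], [], []
    n_crossbite = 0
    for fu, fl in cfg.incisor_pairs:
        ue = upper.get(fu, "incisal_edge")
        ll = lower.get(fl, "labial_surface")
        if ue is not None and ll is not None:
            uppers.append(ue)
            lowers.append(ll)
            if float((ue.position - ll.position) @ frm.anterior_axis) < -1e-9:
                n_crossbite += 1
        le = lower.get(fl, "incisal_edge")
        if ue is not None and le is not None:
            edges.append((ue, le))
    if uppers:
        out.overjet_mm = measure_overjet(uppers, lowers, frm)
    else:
        out.skipped_segments.append("overjet")
    out.anterior_crossbite_teeth = n_crossbite

    if edges:
        vals = [measure_overbite(ue, le, frm) for ue, le in edges]
        out.overbite_overlap_mm = float(max(vals, key=abs))
    else:
        out.skipped_segments.append("overbite")

    um, lm = upper.get(11, "midline"), lower.get(41, "midline")
    if um is not None and lm is not None:
        out.centerline_fraction = measure_centerline(um, lm, cfg.lower_incisor_width_mm, frm)
    else:
        out.skipped_segments.append("centerline")

    transverse = _posterior_transverse(upper, lower, frm, cfg)
    for side in ("left", "right"):
        given = (posterior_input or {}).get(side, {})
        out.posterior[side] = PosteriorCategories(
            sagittal=int(given.get("sagittal", 0)),
            vertical=int(given.get("vertical", 0)),
            transverse=int(
                given["transverse"]
                if given.get("transverse") is not None
                else transverse.get(side, 0)
            ),
        )
    return out
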