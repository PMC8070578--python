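"""Synthetic dentitions and rating datasets with the structure of a
reproducibility study.

Two generators live here:

* :func:`generate_dentition` builds a landmarked upper/lower arch pair on a
  parametric (semi-elliptical) arch form and *encodes* a sampled set of true
  occlusal traits into the landmark coordinates, such that
  :func:`parscore.geometry.extract_traits` recovers the sampled truth to
  numerical precision on noiseless landmarks.
* :func:`simulate_ratings` emulates the crossed measurement protocol of a
  validity study — subjects x timepoints (T0 severe, T1 treated) x methods
  (digital, manual) x raters x duplicate sessions — by adding method, rater
  and session error components to the true traits *in millimetres* and then
  scoring each noisy measurement through the PAR machinery.  The resulting
  tidy table feeds :func:`parscore.agreement.build_agreement_report`.

The default study emulates 15 subjects whose pre-treatment weighted totals
centre near 30 (SD ~ 10) and whose post-treatment totals centre near 1:
severe initial malocclusions, well-finished outcomes.  Post-treatment
overjet and centerline scores are essentially always zero, which exercises
the undefined-ICC path a real study reports for those strata.

Randomness: a single integer seed feeds a ``numpy`` ``SeedSequence``; each
subject (and the study-level bias draws) gets its own spawned substream, so
adding subjects does not reshuffle existing ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DomainError
from .geometry import (
    ArchLandmarks,
    ContactDisplacement,
    GeometryConfig,
    Landmark,
    PosteriorCategories,
    TraitMeasurements,
    LOWER_ANTERIOR_SEQUENCE,
    UPPER_ANTERIOR_SEQUENCE,
)
from .scoring import COMPONENT_FIELDS, ThresholdTable, UK_WEIGHTS, WeightScheme, score_traits

# ---------------------------------------------------------------------------
# study design and noise


@dataclass(frozen=True)
class StudyDesign:
    """The crossed measurement protocol: every subject is scored at every
    timepoint by every method and rater in duplicate sessions."""

    n_subjects: int = 15
    timepoints: tuple[str, ...] = ("T0", "T1")
    methods: tuple[str, ...] = ("digital", "manual")
    raters: tuple[str, ...] = ("I", "II")
    n_sessions: int = 2

    def __post_init__(self):
        if self.n_subjects < 1 or self.n_sessions < 1 or not self.timepoints:
            raise DomainError("all design counts must be >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Additive error components, in millimetres, applied to the true traits.

    ``sigma_method_mm``/``sigma_rater_mm`` are SDs of systematic offsets drawn
    once per study per method/rater; ``sigma_session_mm`` is the residual
    landmark-placement error of every individual measurement.  The manual
    (caliper) method may carry extra residual noise via ``manual_extra_mm``;
    by default the two methods are equally noisy.  ``posterior_flip_prob`` is
    the chance a posterior category is mis-recorded one step off per
    measurement.
    """

    sigma_method_mm: float = 0.05
    sigma_rater_mm: float = 0.05
    sigma_session_mm: float = 0.10
    manual_extra_mm: float = 0.0
    posterior_flip_prob: float = 0.02

    def __post_init__(self):
        for name in ("sigma_method_mm", "sigma_rater_mm", "sigma_session_mm", "manual_extra_mm"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")
        if not 0 <= self.posterior_flip_prob <= 1:
            raise DomainError("posterior_flip_prob must be a probability")

    def session_sd(self, method: str) -> float:
        return self.sigma_session_mm + (self.manual_extra_mm if method == "manual" else 0.0)


@dataclass(frozen=True)
class TraitProfile:
    """Sampling distributions for the true traits at one treatment stage.

    Displacements are per contact pair: a subject-level severity factor
    (log-normal, ``severity_sigma``) multiplies i.i.d. gamma draws, giving
    between-subject spread beyond the pair-level noise.  Probabilities govern
    the categorical traits.  All magnitudes in mm.
    """

    displacement_shape: float = 1.5
    displacement_scale_mm: float = 1.5
    severity_sigma: float = 0.35
    overjet_mean_mm: float = 6.0
    overjet_sd_mm: float = 2.0
    overbite_mean_mm: float = 5.0
    overbite_sd_mm: float = 2.5
    open_bite_prob: float = 0.10
    open_bite_mean_mm: float = 1.5
    open_bite_sd_mm: float = 1.0
    centerline_scale_mm: float = 1.2
    posterior_sagittal_p: float = 0.25
    posterior_vertical_p: float = 0.05
    posterior_crossbite_p: float = 0.20
    posterior_scissor_p: float = 0.01
    anterior_crossbite_p: float = 0.05
    impaction_p: float = 0.0


#: treated (T1) stage: near-ideal residuals, stochastically below T0 per trait
T1_PROFILE = TraitProfile(
    displacement_shape=1.0,
    displacement_scale_mm=0.35,
    severity_sigma=0.2,
    overjet_mean_mm=2.0,
    overjet_sd_mm=0.3,
    overbite_mean_mm=2.2,
    overbite_sd_mm=0.8,
    open_bite_prob=0.02,
    open_bite_mean_mm=0.5,
    open_bite_sd_mm=0.3,
    centerline_scale_mm=0.15,
    posterior_sagittal_p=0.05,
    posterior_vertical_p=0.0,
    posterior_crossbite_p=0.03,
    posterior_scissor_p=0.0,
    anterior_crossbite_p=0.0,
    impaction_p=0.0,
)

#: an ideal occlusion: every trait identically zero/ideal (for fixtures)
ZERO_SEVERITY = TraitProfile(
    displacement_shape=1.0,
    displacement_scale_mm=0.0,
    severity_sigma=0.0,
    overjet_mean_mm=2.0,
    overjet_sd_mm=0.0,
    overbite_mean_mm=2.0,
    overbite_sd_mm=0.0,
    open_bite_prob=0.0,
    centerline_scale_mm=0.0,
    posterior_sagittal_p=0.0,
    posterior_vertical_p=0.0,
    posterior_crossbite_p=0.0,
    posterior_scissor_p=0.0,
    anterior_crossbite_p=0.0,
    impaction_p=0.0,
)


@dataclass(frozen=True)
class SeverityProfile:
    """Per-stage trait distributions: T0 pre-treatment, T1 post-treatment."""

    t0: TraitProfile = field(default_factory=TraitProfile)
    t1: TraitProfile = field(default_factory=lambda: T1_PROFILE)

    def for_timepoint(self, tp: str) -> TraitProfile:
        if tp == "T0":
            return self.t0
        if tp == "T1":
            return self.t1
        raise DomainError(f"unknown timepoint {tp!r}")


_UPPER_PAIRS = tuple(zip(UPPER_ANTERIOR_SEQUENCE, UPPER_ANTERIOR_SEQUENCE[1:]))
_LOWER_PAIRS = tuple(zip(LOWER_ANTERIOR_SEQUENCE, LOWER_ANTERIOR_SEQUENCE[1:]))


def sample_traits(profile: TraitProfile, rng: np.random.Generator) -> TraitMeasurements:
    """Draw one subject-stage's true occlusal traits from the profile."""
    g = float(np.exp(rng.normal(0.0, profile.severity_sigma))) if profile.severity_sigma else 1.0

    def _displacements(pairs, segment):
        out = []
        for teeth in pairs:
            if profile.displacement_scale_mm > 0:
                d = g * float(rng.gamma(profile.displacement_shape, profile.displacement_scale_mm))
            else:
                d = 0.0
            out.append(ContactDisplacement(segment, teeth, d))
        return out

    displacements = _displacements(_UPPER_PAIRS, "upper_anterior") + _displacements(
        _LOWER_PAIRS, "lower_anterior"
    )

    overjet = max(0.0, float(rng.normal(profile.overjet_mean_mm, profile.overjet_sd_mm)))
    if rng.random() < profile.open_bite_prob:
        overbite = -abs(float(rng.normal(profile.open_bite_mean_mm, profile.open_bite_sd_mm)))
    else:
        overbite = max(0.0, float(rng.normal(profile.overbite_mean_mm, profile.overbite_sd_mm)))
    centerline_mm = (
        float(rng.exponential(profile.centerline_scale_mm)) if profile.centerline_scale_mm else 0.0
    )

    posterior = {}
    for side in ("left", "right"):
        u = rng.random()
        if u < profile.posterior_scissor_p:
            transverse = 4
        elif u < profile.posterior_scissor_p + profile.posterior_crossbite_p:
            transverse = 2
        else:
            transverse = 0
        posterior[side] = PosteriorCategories(
            sagittal=int(rng.random() < profile.posterior_sagittal_p),
            vertical=int(rng.random() < profile.posterior_vertical_p),
            transverse=transverse,
        )

    n_crossbite = int(rng.random() < profile.anterior_crossbite_p)
    impacted = {"upper_anterior": 0, "lower_anterior": 0}
    if profile.impaction_p and rng.random() < profile.impaction_p:
        impacted["upper_anterior"] = 1

    cfg = GeometryConfig()
    return TraitMeasurements(
        contact_displacements=displacements,
        impacted_teeth=impacted,
        overjet_mm=overjet,
        anterior_crossbite_teeth=n_crossbite,
        overbite_overlap_mm=overbite,
        centerline_fraction=centerline_mm / cfg.lower_incisor_width_mm,
        posterior=posterior,
    )


# ---------------------------------------------------------------------------
# parametric dentition (landmark) generator

#: mesiodistal crown widths (mm), tooth digit 1..7, per arch
_WIDTHS = {
    "upper": {1: 8.5, 2: 6.5, 3: 7.5, 4: 7.0, 5: 6.5, 6: 10.0, 7: 9.5},
    "lower": {1: 5.5, 2: 6.0, 3: 7.0, 4: 7.0, 5: 7.0, 6: 11.0, 7: 10.5},
}

#: semi-axes of the elliptical arch form (transverse, sagittal), mm
_ARCH_AXES = {"upper": (29.0, 43.0), "lower": (27.0, 41.0)}

#: z of contact-point landmarks relative to the occlusal plane
_CONTACT_Z = {"upper": 1.0, "lower": -1.0}

_POSTERIOR_ENCODE_DIGITS = (5, 7)  # crossbite offsets applied off the anchor teeth
_XBITE_INWARD_MM = 6.0
_SCISSOR_OUTWARD_MM = 8.0


class _ArchCurve:
    """Semi-elliptical arch form parameterised by arc length from the midline."""

    def __init__(self, a: float, b: float):
        self.a, self.b = a, b
        phi = np.linspace(0.0, math.pi / 2, 2001)
        pts = np.column_stack([a * np.sin(phi), b * np.cos(phi)])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        self._phi = phi
        self._arc = np.concatenate([[0.0], np.cumsum(seg)])

    def point(self, s: float, side: int) -> np.ndarray:
        """xy point at arc distance ``s`` from the midline; side +1 = left."""
        phi = float(np.interp(s, self._arc, self._phi))
        return np.array([side * self.a * math.sin(phi), self.b * math.cos(phi)])

    @staticmethod
    def radial(xy: np.ndarray) -> np.ndarray:
        """In-plane unit vector pointing buccally (away from the arch centre)."""
        n = np.linalg.norm(xy)
        return xy / n if n > 0 else np.array([0.0, 1.0])


def _build_arch(arch: str, rng_unused=None) -> dict:
    """Tooth centre/boundary geometry for one ideal arch."""
    widths = _WIDTHS[arch]
    curve = _ArchCurve(*_ARCH_AXES[arch])
    quads = {"upper": {+1: 2, -1: 1}, "lower": {+1: 3, -1: 4}}[arch]
    teeth = {}
    for side, quad in quads.items():
        s = 0.0
        for digit in range(1, 8):
            w = widths[digit]
            fdi = 10 * quad + digit
            teeth[fdi] = {
                "mesial_s": s,
                "distal_s": s + w,
                "center": curve.point(s + w / 2, side),
                "mesial": curve.point(s, side),
                "distal": curve.point(s + w, side),
                "side": side,
            }
            s += w
    return {"curve": curve, "teeth": teeth}


def _contact_names(a: int, b: int) -> tuple[str, str]:
    # facing contacts for consecutive teeth in right-to-left order
    na = "mesial_contact" if a // 10 in (1, 4) else "distal_contact"
    nb = "distal_contact" if b // 10 in (1, 4) else "mesial_contact"
    return na, nb


def generate_dentition(
    profile: TraitProfile | TraitMeasurements,
    seed: int | np.random.Generator = 0,
) -> tuple[ArchLandmarks, ArchLandmarks, TraitMeasurements]:
    """Build a landmarked dentition encoding sampled (or given) true traits.

    Accepts either a :class:`TraitProfile` to sample from, or an explicit
    :class:`TraitMeasurements` truth to encode.  Returns the upper and lower
    :class:`~parscore.geometry.ArchLandmarks` plus the encoded truth; passing
    the arches through :func:`~parscore.geometry.extract_traits` recovers the
    truth to numerical precision (posterior sagittal/vertical categories are
    not encodable in landmarks and must be supplied back as rater input).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = profile if isinstance(profile, TraitMeasurements) else sample_traits(profile, rng)

    arches = {arch: _build_arch(arch) for arch in ("upper", "lower")}
    landmarks: dict[str, list[Landmark]] = {"upper": [], "lower": []}
    cz = _CONTACT_Z

    # contact points: shared boundaries, then displace the second tooth's
    # facing contact radially by the sampled pair displacement
    disp = {(cd.segment, cd.teeth): cd.value_mm for cd in truth.contact_displacements}
    for arch, seq, segment in (
        ("upper", UPPER_ANTERIOR_SEQUENCE, "upper_anterior"),
        ("lower", LOWER_ANTERIOR_SEQUENCE, "lower_anterior"),
    ):
        geo = arches[arch]["teeth"]
        curve = arches[arch]["curve"]
        placed = set()
        for a, b in zip(seq, seq[1:]):
            na, nb = _contact_names(a, b)
            boundary = geo[a]["mesial"] if na == "mesial_contact" else geo[a]["distal"]
            if (a, na) not in placed:
                landmarks[arch].append(Landmark(a, na, np.array([*boundary, cz[arch]])))
                placed.add((a, na))
            pos_b = boundary.copy()
            d = disp.get((segment, (a, b)), 0.0)
            if d:
                pos_b = pos_b - d * curve.radial(boundary)  # lingual offset
            landmarks[arch].append(Landmark(b, nb, np.array([*pos_b, cz[arch]])))
            placed.add((b, nb))
        # posterior contact points and the canines' outward (distal) contacts
        for fdi, g in geo.items():
            if fdi % 10 >= 4:
                for name, key in (("mesial_contact", "mesial"), ("distal_contact", "distal")):
                    landmarks[arch].append(Landmark(fdi, name, np.array([*g[key], cz[arch]])))
        for t in (seq[0], seq[-1]):  # distal is always away from the midline
            landmarks[arch].append(
                Landmark(t, "distal_contact", np.array([*geo[t]["distal"], cz[arch]]))
            )

    # posterior buccal cusps at z = 0 (these carry the occlusal plane)
    for arch in ("upper", "lower"):
        geo = arches[arch]["teeth"]
        for fdi, g in geo.items():
            digit = fdi % 10
            if digit < 3:
                continue
            xy = g["center"] + 1.5 * _ArchCurve.radial(g["center"])
            if arch == "upper" and digit in _POSTERIOR_ENCODE_DIGITS:
                side = "left" if g["side"] > 0 else "right"
                cat = truth.posterior[side].transverse
                if cat in (2, 3) and (cat == 3 or digit == _POSTERIOR_ENCODE_DIGITS[0]):
                    xy = xy - _XBITE_INWARD_MM * _ArchCurve.radial(g["center"])
                elif cat == 4:
                    xy = xy + _SCISSOR_OUTWARD_MM * _ArchCurve.radial(g["center"])
            landmarks[arch].append(Landmark(fdi, "buccal_cusp", np.array([*xy, 0.0])))

    # incisor landmarks: lower edges/labial surfaces on the ideal curve, upper
    # edges placed from the lower labial point + overjet/overbite/crossbite
    lower_geo = arches["lower"]["teeth"]
    cfg = GeometryConfig()
    # lateral-incisor pairs carry the reverse overjet, in this order
    cb_pairs = [(12, 42), (22, 32), (11, 41), (21, 31)][: truth.anterior_crossbite_teeth]
    labial = {}
    for fdi, g in lower_geo.items():
        if fdi % 10 > 2:
            continue
        edge = np.array([*g["center"], 0.0])
        lab = g["center"] + 0.5 * _ArchCurve.radial(g["center"])
        landmarks["lower"].append(Landmark(fdi, "incisal_edge", edge))
        landmarks["lower"].append(Landmark(fdi, "labial_surface", np.array([*lab, 0.0])))
        labial[fdi] = lab
    for fu, fl in cfg.incisor_pairs:
        lab = labial[fl]
        oj = -2.0 if (fu, fl) in cb_pairs else truth.overjet_mm
        edge = np.array([lab[0], lab[1] + oj, -truth.overbite_overlap_mm])
        landmarks["upper"].append(Landmark(fu, "incisal_edge", edge))

    # midline landmarks; upper midline offset transversely by the deviation
    dev = truth.centerline_fraction * cfg.lower_incisor_width_mm
    y_u = _ARCH_AXES["upper"][1]
    y_l = _ARCH_AXES["lower"][1]
    landmarks["upper"].append(Landmark(11, "midline", np.array([dev, y_u, 0.0])))
    landmarks["lower"].append(Landmark(41, "midline", np.array([0.0, y_l, 0.0])))

    flags: dict[str, dict[int, set[str]]] = {"upper": {}, "lower": {}}
    if truth.impacted_teeth.get("upper_anterior"):
        # impaction encoded as a case flag on tooth 13; an impacted tooth has no
        # landmarks and its contact pairs are unscoreable, so the truth drops them
        flags["upper"][13] = {"impacted"}
        landmarks["upper"] = [lm for lm in landmarks["upper"] if lm.tooth_id != 13]
        truth = replace(
            truth,
            contact_displacements=[
                cd for cd in truth.contact_displacements if 13 not in cd.teeth
            ],
        )

    upper = ArchLandmarks(
        "upper",
        landmarks["upper"],
        {lm.tooth_id for lm in landmarks["upper"]} | set(flags["upper"]),
        flags["upper"],
    )
    lower = ArchLandmarks(
        "lower",
        landmarks["lower"],
        {lm.tooth_id for lm in landmarks["lower"]} | set(flags["lower"]),
        flags["lower"],
    )
    return upper, lower, truth


# ---------------------------------------------------------------------------
# crossed-design rating simulation


def _perturb_traits(
    truth: TraitMeasurements, bias_mm: float, sd_mm: float, flip_p: float, rng: np.random.Generator
) -> TraitMeasurements:
    """One noisy re-measurement of the true traits (mm-level errors)."""

    def jitter(v, lo=None):
        x = v + bias_mm + rng.normal(0.0, sd_mm) if sd_mm or bias_mm else v
        return max(lo, x) if lo is not None else x

    cds = [replace(cd, value_mm=jitter(cd.value_mm, lo=0.0)) for cd in truth.contact_displacements]
    cfg = GeometryConfig()
    centerline_mm = truth.centerline_fraction * cfg.lower_incisor_width_mm
    posterior = {}
    for side, cats in truth.posterior.items():
        tr = cats.transverse
        if flip_p and rng.random() < flip_p:
            tr = max(0, min(4, tr + rng.choice((-1, 1))))
        posterior[side] = PosteriorCategories(cats.sagittal, cats.vertical, int(tr))
    return TraitMeasurements(
        contact_displacements=cds,
        impacted_teeth=dict(truth.impacted_teeth),
        overjet_mm=jitter(truth.overjet_mm, lo=0.0),
        anterior_crossbite_teeth=truth.anterior_crossbite_teeth,
        overbite_overlap_mm=jitter(truth.overbite_overlap_mm),
        centerline_fraction=abs(jitter(centerline_mm)) / cfg.lower_incisor_width_mm,
        posterior=posterior,
    )


#: rating-table trait labels: weighted components + both totals
TRAIT_LABELS = ("total",) + COMPONENT_FIELDS


def simulate_ratings(
    design: StudyDesign | None = None,
    noise: NoiseModel | None = None,
    profile: SeverityProfile | None = None,
    seed: int = 0,
    thresholds: ThresholdTable | None = None,
    scheme: WeightScheme = UK_WEIGHTS,
) -> pd.DataFrame:
    """Simulate the full crossed study and return the tidy rating table.

    Every measurement is ``truth + method offset + rater offset + session
    error`` at the mm trait level, scored through the PAR thresholds and
    weights.  Component values in the table are *weighted* (score x weight),
    the convention of published PAR reliability tables; ``total`` is the
    weighted total.
    """
    design = design or StudyDesign()
    noise = noise or NoiseModel()
    profile = profile or SeverityProfile()
    thresholds = thresholds or ThresholdTable()

    root = np.random.SeedSequence(seed)
    study_ss, *subject_ss = root.spawn(design.n_subjects + 1)
    study_rng = np.random.default_rng(study_ss)
    method_bias = {m: float(study_rng.normal(0.0, noise.sigma_method_mm)) for m in design.methods}
    rater_bias = {r: float(study_rng.normal(0.0, noise.sigma_rater_mm)) for r in design.raters}

    rows = []
    for s_idx, ss in enumerate(subject_ss):
        rng = np.random.default_rng(ss)
        subject = f"S{s_idx + 1:02d}"
        for tp in design.timepoints:
            truth = sample_traits(profile.for_timepoint(tp), rng)
            for method in design.methods:
                for rater in design.raters:
                    for session in range(1, design.n_sessions + 1):
                        noisy = _perturb_traits(
                            truth,
                            method_bias[method] + rater_bias[rater],
                            noise.session_sd(method),
                            noise.posterior_flip_prob,
                            rng,
                        )
                        par = score_traits(noisy, thresholds, scheme)
                        values = {"total": par.weighted_total, **par.weighted_components()}
                        for trait in TRAIT_LABELS:
                            rows.append(
                                (subject, tp, method, rater, session, trait, float(values[trait]))
                            )
    return pd.DataFrame(
        rows, columns=["subject", "timepoint", "method", "rater", "session", "trait", "value"]
    )


def simulate_icc_study(
    n_subjects: int,
    k: int = 2,
    target_icc: float = 0.8,
    sigma_subject: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Continuous two-way data with a known population ICC.

    Ratings are ``subject effect + residual`` with residual variance chosen so
    that sigma_s^2 / (sigma_s^2 + sigma_e^2) = ``target_icc``; there are no
    rater main effects, so the absolute-agreement single-measure ICC targets
    the same ratio.  Used for parameter-recovery checks.
    """
    if not 0 < target_icc < 1:
        raise DomainError("target ICC must be in (0, 1)")
    rng = np.random.default_rng(seed)
    sigma_e = sigma_subject * math.sqrt((1 - target_icc) / target_icc)
    subj = rng.normal(0.0, sigma_subject, size=(n_subjects, 1))
    return subj + rng.normal(0.0, sigma_e, size=(n_subjects, k))


def expected_icc(sigma_subject: float, sigma_error: float) -> float:
    """Closed-form population ICC for additive subject + error components."""
    return sigma_subject**2 / (sigma_subject**2 + sigma_error**2)
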